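"""Seeded synthetic-data generators.

Every downstream stage has a generator here that produces inputs with the
statistical structure the stage assumes, so the full pipeline is testable
without any external downloads:

* protein families sharing a planted spectral component at a known
  frequency, localized to a known sub-region (for consensus-spectrum and
  peptide-scan recovery tests);
* minimal two-chain atomic geometries realizing each nonbonded-contact
  type (for the contact classifier);
* PMF profiles with a bound well of known depth rising to a noisy plateau
  (for the binding-free-energy extraction).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .ism import CANONICAL_RESIDUES, EIIPTable
from .energetics import PMFProfile
from .structure import AtomRecord, ContactRuleSet, StructureModel


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantRecord:
    """Ground truth of a planted spectral component."""

    f0: float
    region: tuple[int, int]   # 1-based inclusive
    amplitude: float          # EIIP units
    seed: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.f0 <= 0.5):
            raise ValueError("f0 must be in (0, 0.5]")
        if self.region[0] < 1 or self.region[0] > self.region[1]:
            raise ValueError("malformed planted region")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PMFTruth:
    depth: float
    plateau_range: tuple[float, float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def random_sequence(length: int, seed: int,
                    composition: Optional[Sequence[float]] = None) -> str:
    """Random protein sequence over the 20 canonical residues."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if composition is not None:
        p = np.asarray(composition, dtype=float)
        if p.size != 20 or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("composition must be 20 nonnegative weights")
        p = p / p.sum()
    else:
        p = None
    letters = rng.choice(list(CANONICAL_RESIDUES), size=length, p=p)
    return "".join(letters)


def plant_periodic_family(n_seqs: int, length: int, f0: float,
                          region: tuple[int, int], amplitude: float,
                          seed: int, table: Optional[EIIPTable] = None
                          ) -> tuple[list[tuple[str, str]], PlantRecord]:
    """Family of sequences with a common spectral component planted at f0.

    Inside ``region`` (1-based inclusive) the residue at position n is the
    one whose EIIP value is nearest to mu + amplitude*cos(2*pi*f0*n + phi),
    with a member-specific random phase phi, so the family shares only the
    frequency, not the phase.  Outside the region residues are random.
    Large amplitudes clip to the nearest available EIIP value.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    start, end = region
    if not (1 <= start <= end <= length):
        raise ValueError(f"region {region} does not fit length {length}")
    table = table or EIIPTable.default()
    rng = np.random.default_rng(seed)
    residues = np.array(list(CANONICAL_RESIDUES))
    eiip = np.array([table[r] for r in residues])
    mu = eiip.mean()

    records: list[tuple[str, str]] = []
    for m in range(n_seqs):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        seq = list(rng.choice(residues, size=length))
        if amplitude > 0:
            for pos in range(start - 1, end):
                target = mu + amplitude * math.cos(
                    2.0 * math.pi * f0 * pos + phi)
                seq[pos] = residues[int(np.argmin(np.abs(eiip - target)))]
        records.append((f"planted_{m + 1}", "".join(seq)))

    truth = PlantRecord(f0=f0, region=(start, end), amplitude=amplitude,
                        seed=seed,
                        member_ids=tuple(r[0] for r in records))
    return records, truth


# ---------------------------------------------------------------------------
# Contact geometries
# ---------------------------------------------------------------------------

def _random_rigid_motion(rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR-based) and a random translation."""
    M = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return Q, t


def _atom(chain: str, resname: str, resnum: int, name: str, element: str,
          pos: Sequence[float]) -> AtomRecord:
    return AtomRecord(chain=chain, residue_name=resname,
                      residue_number=str(resnum), atom_name=name,
                      element=element, position=np.asarray(pos, float))


def _hexagon(chain: str, resname: str, resnum: int,
             names: Sequence[str], center: np.ndarray,
             radius: float = 1.39) -> list[AtomRecord]:
    """A planar six-membered ring in the z=const plane."""
    atoms = []
    for i, nm in enumerate(names):
        ang = 2.0 * math.pi * i / 6.0
        pos = center + np.array([radius * math.cos(ang),
                                 radius * math.sin(ang), 0.0])
        atoms.append(_atom(chain, resname, resnum, nm,
                           "N" if nm.startswith("N") else "C", pos))
    return atoms


CONTACT_CASES = ("Attractive Charge", "Salt Bridge",
                 "Conventional Hydrogen Bond", "Carbon Hydrogen Bond",
                 "Alkyl", "Pi-Alkyl", "Amide-Pi Stacked", "none")


def synthetic_pair_geometry(case: str,
                            rules: Optional[ContactRuleSet] = None,
                            seed: int = 0) -> StructureModel:
    """Minimal two-chain model whose single inter-chain interaction
    satisfies exactly the requested contact type (or none), placed with a
    random rigid motion."""
    rules = rules or ContactRuleSet()
    rng = np.random.default_rng(seed)
    A: list[AtomRecord] = []
    B: list[AtomRecord] = []

    if case == "Attractive Charge":
        d = rng.uniform(4.0, rules.attractive_charge_max - 0.1)
        A.append(_atom("A", "ARG", 1, "NH2", "N", [0, 0, 0]))
        B.append(_atom("B", "GLU", 1, "OE2", "O", [d, 0, 0]))
    elif case == "Salt Bridge":
        ha = rng.uniform(1.6, rules.hbond_HA_max - 0.1)
        A.append(_atom("A", "LYS", 1, "NZ", "N", [0, 0, 0]))
        A.append(_atom("A", "LYS", 1, "HZ1", "H", [1.0, 0, 0]))
        B.append(_atom("B", "ASP", 1, "OD1", "O", [1.0 + ha, 0, 0]))
    elif case == "Conventional Hydrogen Bond":
        ha = rng.uniform(1.6, rules.hbond_HA_max - 0.1)
        A.append(_atom("A", "SER", 1, "OG", "O", [0, 0, 0]))
        A.append(_atom("A", "SER", 1, "HG1", "H", [0.96, 0, 0]))
        B.append(_atom("B", "GLY", 1, "O", "O", [0.96 + ha, 0, 0]))
    elif case == "Carbon Hydrogen Bond":
        ha = rng.uniform(2.2, rules.carbon_hbond_HA_max - 0.1)
        A.append(_atom("A", "GLY", 1, "CA", "C", [0, 0, 0]))
        A.append(_atom("A", "GLY", 1, "HA2", "H", [1.09, 0, 0]))
        B.append(_atom("B", "GLY", 1, "O", "O", [1.09 + ha, 0, 0]))
    elif case == "Alkyl":
        d = rng.uniform(3.8, rules.hydrophobic_max - 0.1)
        A.append(_atom("A", "ALA", 1, "CB", "C", [0, 0, 0]))
        B.append(_atom("B", "ALA", 1, "CB", "C", [d, 0, 0]))
    elif case == "Pi-Alkyl":
        d = rng.uniform(3.5, rules.pi_max - 0.1)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        A.extend(_hexagon("A", "PHE", 1, names, np.zeros(3)))
        B.append(_atom("B", "ALA", 1, "CB", "C", [0, 0, d]))
    elif case == "Amide-Pi Stacked":
        # lower bound clears the heavy-atom carbon H-bond cutoff so the
        # amide O / ring C pairs cannot co-qualify
        d = rng.uniform(rules.carbon_hbond_DA_max + 0.3,
                        rules.amide_pi_max - 0.1)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        B.extend(_hexagon("B", "PHE", 1, names, np.zeros(3)))
        # planar C,O;N amide parallel to the ring, centroid d above it
        A.append(_atom("A", "GLY", 1, "C", "C", [0.66, -0.4, d]))
        A.append(_atom("A", "GLY", 1, "O", "O", [-0.57, 0.8, d]))
        A.append(_atom("A", "GLY", 2, "N", "N", [-0.09, -0.4, d]))
    elif case == "none":
        d = rng.uniform(rules.hydrophobic_max + 2.0,
                        rules.hydrophobic_max + 6.0)
        A.append(_atom("A", "ALA", 1, "CB", "C", [0, 0, 0]))
        B.append(_atom("B", "ALA", 1, "CB", "C", [d, 0, 0]))
    else:
        raise ValueError(f"unknown contact case {case!r}")

    Q, t = _random_rigid_motion(rng)
    model = StructureModel(id=f"synthetic_{case.replace(' ', '_')}",
                           atoms=A + B)
    return model.transformed(Q, t)


#: Residue templates for randomized toy interfaces: (resname, [(atom,
#: element, offset)]).  Offsets keep intra-residue geometry realistic.
_RANDOM_RESIDUE_TEMPLATES: list[tuple[str, list[tuple[str, str, tuple]]]] = [
    ("ARG", [("NH2", "N", (0, 0, 0))]),
    ("LYS", [("NZ", "N", (0, 0, 0)), ("HZ1", "H", (1.0, 0, 0))]),
    ("ASP", [("OD1", "O", (0, 0, 0)), ("OD2", "O", (1.2, 1.2, 0))]),
    ("GLU", [("OE2", "O", (0, 0, 0))]),
    ("SER", [("OG", "O", (0, 0, 0)), ("HG1", "H", (0.96, 0, 0))]),
    ("GLY", [("CA", "C", (0, 0, 0)), ("HA2", "H", (1.09, 0, 0)),
             ("O", "O", (0.5, 1.1, 0))]),
    ("ALA", [("CB", "C", (0, 0, 0))]),
    ("VAL", [("CB", "C", (0, 0, 0)), ("CG1", "C", (1.5, 0, 0))]),
    ("PHE", [("CG", "C", (1.39, 0, 0)), ("CD1", "C", (0.695, 1.2, 0)),
             ("CE1", "C", (-0.695, 1.2, 0)), ("CZ", "C", (-1.39, 0, 0)),
             ("CE2", "C", (-0.695, -1.2, 0)),
             ("CD2", "C", (0.695, -1.2, 0))]),
]


def random_two_chain_model(seed: int, n_residues: int = 4,
                           box: float = 9.0) -> StructureModel:
    """Randomized two-chain toy interface mixing charged, polar, alkyl and
    aromatic groups at random placements inside a box; used to exercise
    every branch of the contact classifier."""
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    for chain in ("A", "B"):
        k = int(rng.integers(1, n_residues + 1))
        for resnum in range(1, k + 1):
            tpl_idx = int(rng.integers(0, len(_RANDOM_RESIDUE_TEMPLATES)))
            resname, tpl = _RANDOM_RESIDUE_TEMPLATES[tpl_idx]
            origin = rng.uniform(0.0, box, size=3)
            Q, _ = _random_rigid_motion(rng)
            for name, element, off in tpl:
                pos = origin + Q @ np.asarray(off, float)
                atoms.append(_atom(chain, resname, resnum, name, element,
                                   pos))
    return StructureModel(id=f"random_pair_{seed}", atoms=atoms)


# ---------------------------------------------------------------------------
# PMF profiles
# ---------------------------------------------------------------------------

def synthetic_pmf(depth: float, bound_distance: float = 5.0,
                  plateau_range: tuple[float, float] = (20.0, 30.0),
                  noise_sd: float = 0.0, n_points: int = 200,
                  seed: int = 0) -> tuple[PMFProfile, PMFTruth]:
    """PMF with a bound well at ``bound_distance`` (energy 0) rising
    smoothly to a plateau of height ``depth`` over ``plateau_range``, plus
    i.i.d. Gaussian noise.  The first point is the bound state."""
    lo, hi = plateau_range
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if not (bound_distance < lo < hi):
        raise ValueError("plateau_range must lie beyond bound_distance")
    rng = np.random.default_rng(seed)
    d = np.linspace(bound_distance, hi, n_points)
    # smoothstep ramp from the well to the start of the plateau
    s = np.clip((d - bound_distance) / (lo - bound_distance), 0.0, 1.0)
    e = depth * (3.0 * s ** 2 - 2.0 * s ** 3)
    if noise_sd > 0:
        e = e + rng.normal(0.0, noise_sd, size=n_points)
    profile = PMFProfile(distances=d, energies=e)
    truth = PMFTruth(depth=depth, plateau_range=(lo, hi),
                     noise_sd=noise_sd, seed=seed)
    return profile, truth
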