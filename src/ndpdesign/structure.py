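"""Atomic-structure measurements and nonbonded-contact classification.

Parses PDB/mmCIF coordinates (first model), resolves Table-style atom
selectors (``A:ARG131:NH2``), measures distances and planar angles,
computes the TM3-TM6 activation-state metric of a GPCR, and classifies
receptor:peptide inter-chain contacts into a geometric taxonomy:

    Salt Bridge; Attractive Charge   (charged H-bond, category HB; ES)
    Attractive Charge                (charged heavy-atom pair, ES)
    Conventional Hydrogen Bond       (N/O/S donor)
    Carbon Hydrogen Bond             (C donor)
    Amide-Pi Stacked                 (backbone amide over an aromatic ring)
    Pi-Alkyl                         (ring centroid near an alkyl group)
    Alkyl                            (two alkyl groups)

Typing is chemistry-first: the type a pair may take is fixed by the atom
roles, and the rule-set cutoffs only gate whether a record is emitted.
Enlarging a cutoff therefore never removes a contact of its type.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import gemmi


# ---------------------------------------------------------------------------
# Model and parsing
# ---------------------------------------------------------------------------

#: Residue names dropped by the solvent/lipid/ion filter.
SOLVENT_RESNAMES = {
    "HOH", "WAT", "TIP3", "TIP", "SPC", "DOD",
    "NA", "CL", "K", "MG", "CA", "ZN", "SOD", "CLA", "POT",
    "POPC", "POPE", "POPS", "DPPC", "DMPC", "CHL1",
}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_name: str
    residue_number: str  # author numbering; insertion code appended
    atom_name: str
    element: str
    position: np.ndarray
    hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    @property
    def selector(self) -> str:
        return (f"{self.chain}:{self.residue_name}{self.residue_number}:"
                f"{self.atom_name}")

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain, self.residue_number)


@dataclass
class StructureModel:
    id: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        unique: list[AtomRecord] = []
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.atom_name)
            if key in seen:
                continue  # first occurrence wins (altloc duplicates)
            seen.add(key)
            unique.append(a)
        self.atoms = unique

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain]

    def residues(self, chain: str) -> dict[tuple[str, str], list[AtomRecord]]:
        """Atoms grouped by (chain, residue_number), insertion order kept."""
        out: dict[tuple[str, str], list[AtomRecord]] = {}
        for a in self.atoms:
            if a.chain == chain:
                out.setdefault(a.residue_key, []).append(a)
        return out

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        """Rigidly moved copy (rotation matrix + translation vector)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return StructureModel(id=self.id, atoms=atoms)


def load_structure(path: str | Path, format: str = "auto",
                   drop_solvent: bool = False) -> StructureModel:
    """Load the first model of a PDB or mmCIF file.

    ``drop_solvent`` removes waters, common lipids and monoatomic ions
    (crystallization/membrane components, not the complex itself).
    """
    path = Path(path)
    if format not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse structure {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"structure {path} contains no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if drop_solvent and res.name.upper() in SOLVENT_RESNAMES:
                continue
            num = str(res.seqid.num)
            if res.seqid.icode and res.seqid.icode != " ":
                num += res.seqid.icode.strip()
            het = res.het_flag == "H"
            for atom in res:
                atoms.append(AtomRecord(
                    chain=chain.name, residue_name=res.name.upper(),
                    residue_number=num, atom_name=atom.name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    hetero=het,
                ))
    if not atoms:
        raise ValueError(f"structure {path} contains no atoms")
    return StructureModel(id=path.stem, atoms=atoms)


# ---------------------------------------------------------------------------
# Selectors and measurements
# ---------------------------------------------------------------------------

_SELECTOR_RE = re.compile(
    r"^(?P<chain>[^:]+):(?P<resname>[A-Za-z]{1,3})(?P<resnum>-?\d+[A-Za-z]?)"
    r"(?::(?P<atom>[^:]+))?$")


@dataclass(frozen=True)
class AtomSelector:
    """``CHAIN:RESNAME+RESNUM[:ATOM]`` selector, e.g. ``A:ARG131:NH2``."""

    chain: str
    residue_name: str
    residue_number: str
    atom_name: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        m = _SELECTOR_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed atom selector {text!r}")
        return cls(chain=m["chain"], residue_name=m["resname"].upper(),
                   residue_number=m["resnum"], atom_name=m["atom"])

    def __str__(self) -> str:
        base = f"{self.chain}:{self.residue_name}{self.residue_number}"
        return f"{base}:{self.atom_name}" if self.atom_name else base


def select_atom(model: StructureModel,
                selector: AtomSelector | str) -> AtomRecord:
    """Resolve a selector to its unique atom.

    A residue found at the selector's number but with a different name is
    an error (guards against numbering drift between structures).
    """
    if isinstance(selector, str):
        selector = AtomSelector.parse(selector)
    if selector.atom_name is None:
        raise ValueError(f"selector {selector} does not name an atom")
    residue_atoms = [a for a in model.atoms
                     if a.chain == selector.chain
                     and a.residue_number == selector.residue_number]
    if not residue_atoms:
        raise KeyError(f"no residue matches selector {selector}")
    names = {a.residue_name for a in residue_atoms}
    if selector.residue_name not in names:
        raise ValueError(
            f"residue at {selector.chain}:{selector.residue_number} is "
            f"{sorted(names)}, not {selector.residue_name} "
            f"(selector {selector})")
    matches = [a for a in residue_atoms
               if a.atom_name == selector.atom_name
               and a.residue_name == selector.residue_name]
    if not matches:
        raise KeyError(f"no atom matches selector {selector}")
    if len(matches) > 1:
        raise ValueError(f"selector {selector} is ambiguous")
    return matches[0]


def atom_distance(model: StructureModel, sel1: AtomSelector | str,
                  sel2: AtomSelector | str) -> float:
    """Euclidean distance in A between two selected atoms."""
    a = select_atom(model, sel1)
    b = select_atom(model, sel2)
    return float(np.linalg.norm(a.position - b.position))


def planar_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 formed by p1-p2-p3, in degrees within [0, 180]."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("coincident atoms: angle undefined")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(math.degrees(math.acos(c)))


def angle_xda(model: StructureModel, X: AtomSelector | str,
              D: AtomSelector | str, A: AtomSelector | str) -> float:
    """Planar angle X-D-A at atom D (donor-geometry convention)."""
    px = select_atom(model, X).position
    pd = select_atom(model, D).position
    pa = select_atom(model, A).position
    return planar_angle(px, pd, pa)


# Reference TM3-TM6 backbone-carbon separations of the beta2-adrenergic
# receptor in the inactive (2RH1) and active (3P0G) crystal structures.
INACTIVE_REFERENCE_A = 10.766
ACTIVE_REFERENCE_A = 18.084


def activation_metric(model: StructureModel, res_tm3: tuple[str, int | str],
                      res_tm6: tuple[str, int | str],
                      atom: str = "CA") -> float:
    """Distance between the chosen backbone carbons of two helix residues."""
    def _find(chain: str, number: int | str) -> AtomRecord:
        number = str(number)
        matches = [a for a in model.atoms
                   if a.chain == chain and a.residue_number == number
                   and a.atom_name == atom]
        if not matches:
            raise KeyError(
                f"no atom {atom} in residue {chain}:{number}")
        return matches[0]

    a = _find(*res_tm3)
    b = _find(*res_tm6)
    return float(np.linalg.norm(a.position - b.position))


def classify_activation(distance: float,
                        inactive_ref: float = INACTIVE_REFERENCE_A,
                        active_ref: float = ACTIVE_REFERENCE_A) -> str:
    """Label a TM3-TM6 distance by its nearest reference value."""
    if abs(distance - active_ref) <= abs(distance - inactive_ref):
        return "active-like"
    return "inactive-like"


# ---------------------------------------------------------------------------
# Contact rule set
# ---------------------------------------------------------------------------

def _default_positive() -> dict[str, frozenset[str]]:
    return {"ARG": frozenset({"NE", "NH1", "NH2"}),
            "LYS": frozenset({"NZ"})}


def _default_negative() -> dict[str, frozenset[str]]:
    return {"ASP": frozenset({"OD1", "OD2"}),
            "GLU": frozenset({"OE1", "OE2"})}


def _default_alkyl() -> dict[str, frozenset[str]]:
    return {
        "ALA": frozenset({"CB"}),
        "VAL": frozenset({"CB", "CG1", "CG2"}),
        "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
        "ILE": frozenset({"CB", "CG1", "CG2", "CD1", "CD"}),
        "PRO": frozenset({"CB", "CG", "CD"}),
        "MET": frozenset({"CB", "CG", "SD", "CE"}),
        "LYS": frozenset({"CB", "CG", "CD"}),
        "ARG": frozenset({"CB", "CG", "CD"}),
        "THR": frozenset({"CG2"}),
        "CYS": frozenset({"CB", "SG"}),
    }


def _default_rings() -> dict[str, tuple[frozenset[str], ...]]:
    return {
        "PHE": (frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),),
        "TYR": (frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),),
        "TRP": (frozenset({"CG", "CD1", "CD2", "NE1", "CE2"}),
                frozenset({"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"})),
        "HIS": (frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),),
    }


def _default_donor_heavy() -> dict[str, frozenset[str]]:
    """Heavy atoms that carry a polar hydrogen (used when no H present)."""
    return {
        "*": frozenset({"N"}),  # backbone amide nitrogen, any residue
        "SER": frozenset({"OG"}),
        "THR": frozenset({"OG1"}),
        "TYR": frozenset({"OH"}),
        "TRP": frozenset({"NE1"}),
        "HIS": frozenset({"ND1", "NE2"}),
        "ASN": frozenset({"ND2"}),
        "GLN": frozenset({"NE2"}),
        "CYS": frozenset({"SG"}),
        "LYS": frozenset({"NZ"}),
        "ARG": frozenset({"NE", "NH1", "NH2"}),
    }


#: C-terminal carboxylate oxygens are negatively charged on any residue.
CTERM_OXYGENS = frozenset({"OXT", "OT1", "OT2"})


@dataclass(frozen=True)
class ContactRuleSet:
    """Distance/angle cutoffs plus the chemistry group definitions.

    Distances in A, angles in degrees.  Defaults chosen to admit the
    published contact tables of the beta2-AR:Nb80 crystal and the
    beta2-AR:P3 MD frame.
    """

    attractive_charge_max: float = 5.6
    hbond_HA_max: float = 2.5
    hbond_DA_max: float = 3.5
    hbond_angle_min: float = 90.0
    carbon_hbond_HA_max: float = 3.1
    carbon_hbond_DA_max: float = 3.8
    hydrophobic_max: float = 5.5
    pi_max: float = 5.5
    amide_pi_max: float = 5.5
    amide_pi_angle_max: float = 40.0
    positive_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=_default_positive)
    negative_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=_default_negative)
    alkyl_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=_default_alkyl)
    ring_atoms: Mapping[str, tuple[frozenset[str], ...]] = field(
        default_factory=_default_rings)
    donor_heavy_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=_default_donor_heavy)

    def __post_init__(self) -> None:
        for name in ("attractive_charge_max", "hbond_HA_max", "hbond_DA_max",
                     "carbon_hbond_HA_max", "carbon_hbond_DA_max",
                     "hydrophobic_max", "pi_max", "amide_pi_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_angle_min", "amide_pi_angle_max"):
            if not (0.0 <= getattr(self, name) <= 180.0):
                raise ValueError(f"{name} must be in [0, 180]")

    # -- role predicates ----------------------------------------------------

    def is_positive(self, a: AtomRecord) -> bool:
        return a.atom_name in self.positive_atoms.get(a.residue_name, ())

    def is_negative(self, a: AtomRecord) -> bool:
        if a.atom_name in CTERM_OXYGENS:
            return True
        return a.atom_name in self.negative_atoms.get(a.residue_name, ())

    def is_acceptor(self, a: AtomRecord) -> bool:
        return a.element == "O"

    def is_alkyl(self, a: AtomRecord) -> bool:
        return a.atom_name in self.alkyl_atoms.get(a.residue_name, ())

    def is_donor_heavy(self, a: AtomRecord) -> bool:
        if a.atom_name in self.donor_heavy_atoms.get("*", ()):
            return True
        return a.atom_name in self.donor_heavy_atoms.get(a.residue_name, ())


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

CATEGORY_ORDER = {
    "Hydrogen Bond; Electrostatic": 0,
    "Electrostatic": 1,
    "Hydrogen Bond": 2,
    "Hydrophobic": 3,
}


@dataclass(frozen=True)
class ContactRecord:
    from_selector: str
    to_selector: str
    distance: float
    category: str
    type: str
    from_chemistry: str = ""
    to_chemistry: str = ""
    angles: Mapping[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.from_selector}-{self.to_selector}"


def _attached_hydrogens(residue_atoms: Sequence[AtomRecord],
                        heavy: AtomRecord,
                        max_bond: float = 1.3) -> list[AtomRecord]:
    """Hydrogens of the same residue within covalent-bond range of ``heavy``.

    Parentage is by proximity: an H belongs to its nearest heavy atom.
    """
    heavies = [a for a in residue_atoms if a.element != "H"]
    out = []
    for h in residue_atoms:
        if h.element != "H":
            continue
        dists = {a.atom_name: np.linalg.norm(h.position - a.position)
                 for a in heavies}
        nearest = min(dists, key=dists.get)
        if nearest == heavy.atom_name and dists[nearest] <= max_bond:
            out.append(h)
    return out


def _hydrogen_parent(residue_atoms: Sequence[AtomRecord],
                     h: AtomRecord, max_bond: float = 1.3
                     ) -> Optional[AtomRecord]:
    heavies = [a for a in residue_atoms if a.element != "H"]
    if not heavies:
        return None
    nearest = min(heavies,
                  key=lambda a: np.linalg.norm(h.position - a.position))
    if np.linalg.norm(h.position - nearest.position) <= max_bond:
        return nearest
    return None


def _residue_selector(a: AtomRecord) -> str:
    return f"{a.chain}:{a.residue_name}{a.residue_number}"


def _ring_groups(residues: Mapping[tuple[str, str], list[AtomRecord]],
                 rules: ContactRuleSet
                 ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(residue selector, centroid, unit normal) for every complete ring."""
    out = []
    for atoms in residues.values():
        resname = atoms[0].residue_name
        for ring_names in rules.ring_atoms.get(resname, ()):
            ring = [a for a in atoms if a.atom_name in ring_names]
            if len(ring) != len(ring_names):
                continue
            pts = np.array([a.position for a in ring])
            centroid = pts.mean(axis=0)
            # normal from SVD of the centered ring coordinates
            _, _, vt = np.linalg.svd(pts - centroid)
            out.append((_residue_selector(ring[0]), centroid, vt[2]))
    return out


def _amide_groups(residues: Mapping[tuple[str, str], list[AtomRecord]]
                  ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(selector, centroid, unit normal) of backbone C,O;N amide planes."""
    keys = list(residues)
    out = []
    for i in range(len(keys) - 1):
        a_res, b_res = residues[keys[i]], residues[keys[i + 1]]
        c = next((a for a in a_res if a.atom_name == "C"), None)
        o = next((a for a in a_res if a.atom_name == "O"), None)
        n = next((a for a in b_res if a.atom_name == "N"), None)
        if c is None or o is None or n is None:
            continue
        if np.linalg.norm(c.position - n.position) > 2.0:  # chain break
            continue
        pts = np.array([c.position, o.position, n.position])
        centroid = pts.mean(axis=0)
        v1, v2 = pts[1] - pts[0], pts[2] - pts[0]
        normal = np.cross(v1, v2)
        nn = np.linalg.norm(normal)
        if nn == 0:
            continue
        sel = (f"{c.chain}:{c.residue_name}{c.residue_number}:C,O;"
               f"{n.residue_name}{n.residue_number}:N")
        out.append((sel, centroid, normal / nn))
    return out


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, degrees in [0, 90]."""
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return math.degrees(math.acos(c))


def detect_contacts(model: StructureModel, chain_a: str, chain_b: str,
                    rules: ContactRuleSet | None = None
                    ) -> list[ContactRecord]:
    """Classify every qualifying inter-chain nonbonded contact.

    Rules are evaluated in the order salt bridge, attractive charge,
    conventional H-bond, carbon H-bond, amide-pi, pi-alkyl, alkyl; output
    is sorted by category, then distance.  When the model carries no
    hydrogens, H-bond rules fall back to heavy-atom criteria and salt
    bridges degrade to attractive-charge records.
    """
    rules = rules or ContactRuleSet()
    if chain_a not in model.chains:
        raise KeyError(f"chain {chain_a!r} not in model")
    if chain_b not in model.chains:
        raise KeyError(f"chain {chain_b!r} not in model")

    res_a = model.residues(chain_a)
    res_b = model.residues(chain_b)
    has_h = any(a.element == "H" for a in model.atoms)

    records: list[ContactRecord] = []
    # oxygens already claimed by a salt bridge from a given positive N
    bridged: set[tuple[tuple[str, str, str], tuple[str, str, str]]] = set()

    def _akey(a: AtomRecord) -> tuple[str, str, str]:
        return (a.chain, a.residue_number, a.atom_name)

    sides = [(res_a, res_b), (res_b, res_a)]

    # -- salt bridges (needs hydrogens) -------------------------------------
    if has_h:
        for donor_res, acc_res in sides:
            for datoms in donor_res.values():
                for heavy in datoms:
                    if heavy.element == "H" or not rules.is_positive(heavy):
                        continue
                    for h in _attached_hydrogens(datoms, heavy):
                        for aatoms in acc_res.values():
                            for acc in aatoms:
                                if not rules.is_negative(acc) \
                                        or not rules.is_acceptor(acc):
                                    continue
                                d = float(np.linalg.norm(
                                    h.position - acc.position))
                                if d > rules.hbond_HA_max:
                                    continue
                                ang = planar_angle(heavy.position, h.position,
                                                   acc.position)
                                if ang < rules.hbond_angle_min:
                                    continue
                                bridged.add((_akey(heavy), _akey(acc)))
                                records.append(ContactRecord(
                                    from_selector=h.selector,
                                    to_selector=acc.selector,
                                    distance=d,
                                    category="Hydrogen Bond; Electrostatic",
                                    type="Salt Bridge; Attractive Charge",
                                    from_chemistry="H-Donor; Positive",
                                    to_chemistry="H-Acceptor; Negative",
                                    angles={"XDA": ang},
                                ))

    # -- attractive charge --------------------------------------------------
    for pos_res, neg_res in sides:
        for patoms in pos_res.values():
            for pos in patoms:
                if pos.element == "H" or not rules.is_positive(pos):
                    continue
                for natoms in neg_res.values():
                    for neg in natoms:
                        if neg.element == "H" or not rules.is_negative(neg):
                            continue
                        if (_akey(pos), _akey(neg)) in bridged:
                            continue
                        d = float(np.linalg.norm(
                            pos.position - neg.position))
                        if d > rules.attractive_charge_max:
                            continue
                        records.append(ContactRecord(
                            from_selector=pos.selector,
                            to_selector=neg.selector,
                            distance=d,
                            category="Electrostatic",
                            type="Attractive Charge",
                            from_chemistry="Positive",
                            to_chemistry="Negative",
                        ))

    # -- hydrogen bonds (conventional and carbon) ---------------------------
    for donor_res, acc_res in sides:
        for datoms in donor_res.values():
            if has_h:
                for h in datoms:
                    if h.element != "H":
                        continue
                    parent = _hydrogen_parent(datoms, h)
                    if parent is None:
                        continue
                    if parent.element == "C":
                        ha_max, ctype = rules.carbon_hbond_HA_max, \
                            "Carbon Hydrogen Bond"
                    elif parent.element in ("N", "O", "S"):
                        ha_max, ctype = rules.hbond_HA_max, \
                            "Conventional Hydrogen Bond"
                    else:
                        continue
                    for aatoms in acc_res.values():
                        for acc in aatoms:
                            if not rules.is_acceptor(acc):
                                continue
                            # charged-pair chemistry is salt-bridge territory
                            if rules.is_positive(parent) \
                                    and rules.is_negative(acc):
                                continue
                            d = float(np.linalg.norm(
                                h.position - acc.position))
                            if d > ha_max:
                                continue
                            ang = planar_angle(parent.position, h.position,
                                               acc.position)
                            if ang < rules.hbond_angle_min:
                                continue
                            records.append(ContactRecord(
                                from_selector=h.selector,
                                to_selector=acc.selector,
                                distance=d,
                                category="Hydrogen Bond",
                                type=ctype,
                                from_chemistry="H-Donor",
                                to_chemistry="H-Acceptor",
                                angles={"XDA": ang},
                            ))
            else:
                # heavy-atom criteria for hydrogen-free structures
                for heavy in datoms:
                    if heavy.element == "C":
                        da_max, ctype = rules.carbon_hbond_DA_max, \
                            "Carbon Hydrogen Bond"
                    elif rules.is_donor_heavy(heavy) \
                            and heavy.element in ("N", "O", "S"):
                        da_max, ctype = rules.hbond_DA_max, \
                            "Conventional Hydrogen Bond"
                    else:
                        continue
                    for aatoms in acc_res.values():
                        for acc in aatoms:
                            if not rules.is_acceptor(acc):
                                continue
                            if rules.is_positive(heavy) \
                                    and rules.is_negative(acc):
                                continue
                            d = float(np.linalg.norm(
                                heavy.position - acc.position))
                            if d > da_max:
                                continue
                            records.append(ContactRecord(
                                from_selector=heavy.selector,
                                to_selector=acc.selector,
                                distance=d,
                                category="Hydrogen Bond",
                                type=ctype,
                                from_chemistry="H-Donor",
                                to_chemistry="H-Acceptor",
                            ))

    # -- amide-pi stacking --------------------------------------------------
    for amide_res, ring_res in sides:
        for asel, acent, anorm in _amide_groups(amide_res):
            for rsel, rcent, rnorm in _ring_groups(ring_res, rules):
                d = float(np.linalg.norm(acent - rcent))
                if d > rules.amide_pi_max:
                    continue
                theta = _plane_angle(anorm, rnorm)
                if theta > rules.amide_pi_angle_max:
                    continue
                records.append(ContactRecord(
                    from_selector=asel, to_selector=rsel, distance=d,
                    category="Hydrophobic", type="Amide-Pi Stacked",
                    from_chemistry="Amide", to_chemistry="Pi-Orbitals",
                    angles={"theta": theta},
                ))

    # -- pi-alkyl -----------------------------------------------------------
    for ring_res, alkyl_res in sides:
        for rsel, rcent, _ in _ring_groups(ring_res, rules):
            for atoms in alkyl_res.values():
                alk = [a for a in atoms if rules.is_alkyl(a)]
                if not alk:
                    continue
                d = min(float(np.linalg.norm(rcent - a.position))
                        for a in alk)
                if d > rules.pi_max:
                    continue
                records.append(ContactRecord(
                    from_selector=rsel,
                    to_selector=_residue_selector(alk[0]),
                    distance=d,
                    category="Hydrophobic", type="Pi-Alkyl",
                    from_chemistry="Pi-Orbitals", to_chemistry="Alkyl",
                ))

    # -- alkyl (emitted once per residue pair) ------------------------------
    for atoms_a in res_a.values():
        alk_a = [a for a in atoms_a if rules.is_alkyl(a)]
        if not alk_a:
            continue
        for atoms_b in res_b.values():
            alk_b = [b for b in atoms_b if rules.is_alkyl(b)]
            if not alk_b:
                continue
            d = min(float(np.linalg.norm(a.position - b.position))
                    for a in alk_a for b in alk_b)
            if d > rules.hydrophobic_max:
                continue
            records.append(ContactRecord(
                from_selector=_residue_selector(alk_a[0]),
                to_selector=_residue_selector(alk_b[0]),
                distance=d,
                category="Hydrophobic", type="Alkyl",
                from_chemistry="Alkyl", to_chemistry="Alkyl",
            ))

    records.sort(key=lambda r: (CATEGORY_ORDER.get(r.category, 9),
                                r.distance, r.from_selector, r.to_selector))
    return records


# ---------------------------------------------------------------------------
# Report export
# ---------------------------------------------------------------------------

CONTACT_TSV_HEADER = ("Name\tDistance\tCategory\tType\tFrom\tFrom Chemistry"
                      "\tTo\tTo Chemistry\tAngles")


def contacts_to_tsv(records: Iterable[ContactRecord]) -> str:
    lines = [CONTACT_TSV_HEADER]
    for r in records:
        angles = ";".join(f"{k}={v:.3f}" for k, v in r.angles.items())
        lines.append(
            f"{r.name}\t{r.distance:.5f}\t{r.category}\t{r.type}\t"
            f"{r.from_selector}\t{r.from_chemistry}\t{r.to_selector}\t"
            f"{r.to_chemistry}\t{angles}")
    return "\n".join(lines) + "\n"


def contacts_to_json(records: Iterable[ContactRecord]) -> list[dict]:
    return [{
        "name": r.name, "distance": round(r.distance, 5),
        "category": r.category, "type": r.type,
        "from": r.from_selector, "from_chemistry": r.from_chemistry,
        "to": r.to_selector, "to_chemistry": r.to_chemistry,
        "angles": {k: round(v, 3) for k, v in r.angles.items()},
    } for r in records]
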