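"""Potential-of-mean-force post-processing and binding thermodynamics.

A metadynamics PMF profile (free energy vs. a receptor-peptide separation
collective variable) is reduced to a binding free energy by averaging the
stable unbound plateau and subtracting the bound-state reference:

    dG = -(plateau_mean - bound_value)

with the plateau standard error of the mean as the uncertainty, and the
dissociation constant from dG = RT ln(Kd / C0) at a 1 M standard state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872036e-3

#: Standard-state concentration, mol/L.
STANDARD_STATE_M = 1.0


@dataclass(frozen=True)
class PMFProfile:
    """Free energy (kcal/mol) as a function of separation (A)."""

    distances: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if d.size != e.size:
            raise ValueError("distances and energies differ in length")
        if d.size < 2:
            raise ValueError("a PMF profile needs at least 2 points")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(e))):
            raise ValueError("PMF values must be finite")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "energies", e)

    @property
    def n_points(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class PlateauSpec:
    """Distance window (A) over which the unbound PMF is averaged."""

    lower: float = 20.0
    upper: float = 30.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("plateau lower bound must be below upper bound")


@dataclass(frozen=True)
class BindingEstimate:
    delta_g: float      # kcal/mol, negative = favorable
    se: float           # kcal/mol
    temperature: float  # K
    kd: float           # mol/L
    n_points: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        expected = STANDARD_STATE_M * math.exp(
            self.delta_g / (R_KCAL * self.temperature))
        if not math.isclose(self.kd, expected, rel_tol=1e-9):
            raise ValueError("kd inconsistent with delta_g and temperature")

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


def load_pmf(path: str | Path, dialect: str = "two_column",
             columns: tuple[int, int] = (0, 1)) -> PMFProfile:
    """Read a PMF profile from whitespace-separated text.

    ``two_column`` expects distance/energy in the first two columns;
    ``colvars`` picks the columns given by ``columns`` from multi-column
    free-energy files.  '#' comment lines are skipped; rows are sorted by
    distance and duplicate distances resolved last-wins (with a warning).
    """
    if dialect not in ("two_column", "colvars"):
        raise ValueError(f"unknown PMF dialect {dialect!r}")
    ci, cj = (0, 1) if dialect == "two_column" else columns
    rows: list[tuple[float, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append((float(parts[ci]), float(parts[cj])))
    if len(rows) < 2:
        raise ValueError(f"PMF file {path} has fewer than 2 data points")
    dedup: dict[float, float] = {}
    for d, e in rows:
        if d in dedup:
            warnings.warn(f"duplicate distance {d} in {path}; keeping last")
        dedup[d] = e
    d_sorted = sorted(dedup)
    return PMFProfile(distances=np.array(d_sorted),
                      energies=np.array([dedup[d] for d in d_sorted]))


def write_pmf(path: str | Path, profile: PMFProfile) -> None:
    with open(path, "w") as fh:
        fh.write("# distance_A\tenergy_kcal_mol\n")
        for d, e in zip(profile.distances, profile.energies):
            fh.write(f"{d:.17g}\t{e:.17g}\n")


def plateau_average(profile: PMFProfile,
                    spec: PlateauSpec = PlateauSpec()
                    ) -> tuple[float, float, int]:
    """Mean, standard error of the mean and count over the plateau window."""
    mask = (profile.distances >= spec.lower) & (profile.distances <= spec.upper)
    vals = profile.energies[mask]
    if vals.size < 2:
        raise ValueError(
            f"fewer than 2 PMF points inside [{spec.lower}, {spec.upper}] A")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, se, int(vals.size)


def dg_to_kd(delta_g: float, temperature: float) -> float:
    """Kd (mol/L) from a binding free energy, 1 M standard state."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return STANDARD_STATE_M * math.exp(delta_g / (R_KCAL * temperature))


def kd_to_dg(kd: float, temperature: float) -> float:
    """Binding free energy (kcal/mol) from Kd; exact inverse of dg_to_kd."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    if kd <= 0:
        raise ValueError("kd must be positive (mol/L)")
    return R_KCAL * temperature * math.log(kd / STANDARD_STATE_M)


def binding_free_energy(profile: PMFProfile,
                        bound_reference: str = "first_point",
                        spec: PlateauSpec = PlateauSpec(),
                        temperature: float = 310.0) -> BindingEstimate:
    """Binding free energy from a PMF profile.

    ``bound_reference``: ``"first_point"`` uses the PMF value at the initial
    (bound) distance; ``"global_min"`` uses the profile minimum.  The bound
    reference is treated as exact, so the reported SE is the plateau SE.
    """
    if bound_reference not in ("first_point", "global_min"):
        raise ValueError(f"unknown bound reference {bound_reference!r}")
    mean, se, n = plateau_average(profile, spec)
    bound = float(profile.energies[0]) if bound_reference == "first_point" \
        else float(profile.energies.min())
    delta_g = -(mean - bound)
    return BindingEstimate(delta_g=delta_g, se=se, temperature=temperature,
                           kd=dg_to_kd(delta_g, temperature), n_points=n)
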