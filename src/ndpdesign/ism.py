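"""Informational spectrum method (ISM) core.

A protein sequence is mapped to a numerical series via the electron-ion
interaction potential (EIIP) of each residue, and the modulus of the
discrete Fourier transform of that (zero-padded, optionally mean-centered)
series is its *informational spectrum*.  Frequencies are expressed in
cycles per residue on the grid F_k = k / Npad for k = 1..floor(Npad/2),
so the grid covers (0, 0.5].  Peaks shared across a family of sequences
are exposed by the *consensus spectrum*, the element-wise product of the
member amplitude spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Frequencies are reported rounded to this many decimals ("F(0.216)" style).
FREQ_DECIMALS = 3

#: Default zero-padding length: a power of two comfortably above receptor-,
#: nanobody- and peptide-length sequences, giving a 1/512 frequency grid.
DEFAULT_PAD = 512


# ---------------------------------------------------------------------------
# EIIP table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EIIPTable:
    """Residue -> electron-ion interaction potential lookup.

    Values are dimensionless (Rydberg scale), one per canonical residue.
    """

    values: Mapping[str, float]
    name: str = "custom"
    source: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        expected = set(CANONICAL_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"EIIP table must cover exactly the 20 canonical residues; "
                f"missing={missing} extra={extra}"
            )
        vals = np.array([self.values[r] for r in CANONICAL_RESIDUES], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("EIIP values must be finite")
        if vals.min() < 0.0 or vals.max() > 0.2:
            raise ValueError("EIIP values must lie in [0, 0.2]")
        if np.unique(vals).size < 2:
            raise ValueError("EIIP scale is degenerate (all values equal)")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    @property
    def std(self) -> float:
        """Population standard deviation over the 20 residue values."""
        return float(np.std(list(self.values.values())))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None,
                  source: str = "") -> "EIIPTable":
        """Load a two-column ``residue<TAB>value`` text file ('#' comments)."""
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed EIIP table line: {line!r}")
            values[parts[0].upper()] = float(parts[1])
        return cls(values=values, name=name or Path(path).stem, source=source)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{r}\t{self.values[r]:.4f}" for r in CANONICAL_RESIDUES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def default(cls) -> "EIIPTable":
        """The Veljkovic EIIP scale shipped with the package."""
        ref = resources.files("ndpdesign.data") / "eiip_veljkovic.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(
                path,
                name="eiip_veljkovic",
                source="Veljkovic electron-ion interaction potential scale",
            )


# ---------------------------------------------------------------------------
# Sequence I/O and encoding
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Sequences are uppercased and gap characters ('-', '.') removed; record
    order is preserved.  An empty file or a record with an empty sequence
    is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


@dataclass(frozen=True)
class NumericalSeries:
    """An EIIP-encoded sequence: an ordered list of real values."""

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("series must be a non-empty 1-D array")

    @property
    def length(self) -> int:
        return int(self.values.size)


def encode_sequence(sequence: str, table: EIIPTable, *, id: str = "",
                    unknown: str = "strict") -> NumericalSeries:
    """Map a protein sequence to its EIIP numerical series.

    ``unknown`` policy for non-canonical residues: ``"strict"`` raises
    (naming position and character), ``"mean"`` substitutes the table mean.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if unknown not in ("strict", "mean"):
        raise ValueError(f"unknown-residue policy {unknown!r} not recognized")
    values = np.empty(len(sequence), dtype=float)
    mean = table.mean
    for i, ch in enumerate(sequence.upper()):
        try:
            values[i] = table[ch]
        except KeyError:
            if unknown == "mean":
                values[i] = mean
            else:
                raise ValueError(
                    f"unknown residue {ch!r} at position {i + 1}"
                ) from None
    return NumericalSeries(id=id or sequence[:12], values=values)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InformationalSpectrum:
    id: str
    pad_length: int
    frequencies: np.ndarray
    amplitudes: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies",
                           np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "amplitudes",
                           np.asarray(self.amplitudes, dtype=float))
        n_bins = self.pad_length // 2
        if self.frequencies.size != n_bins or self.amplitudes.size != n_bins:
            raise ValueError("spectrum must have floor(Npad/2) bins")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.source_length > self.pad_length:
            raise ValueError("source_length exceeds pad_length")


@dataclass(frozen=True)
class ConsensusSpectrum:
    member_ids: tuple[str, ...]
    pad_length: int
    frequencies: np.ndarray
    amplitudes: np.ndarray


@dataclass(frozen=True)
class SpectralPeak:
    frequency: float
    amplitude: float
    snr: float
    rank: int = 1

    @property
    def frequency_label(self) -> str:
        return f"F({round(self.frequency, FREQ_DECIMALS):.3f})"


def _centered(values: np.ndarray, mean_center: bool) -> np.ndarray:
    return values - values.mean() if mean_center else values


def informational_spectrum(series: NumericalSeries, pad_length: int = DEFAULT_PAD,
                           mean_center: bool = True) -> InformationalSpectrum:
    """Amplitude spectrum of the zero-padded EIIP series.

    Amplitudes are the moduli of the discrete Fourier transform at bins
    k = 1..floor(pad_length/2); the k = 0 (DC) bin is excluded.
    """
    if pad_length < series.length:
        raise ValueError(
            f"pad_length {pad_length} < series length {series.length}")
    x = _centered(series.values, mean_center)
    spec = np.fft.rfft(x, n=pad_length)
    n_bins = pad_length // 2
    amplitudes = np.abs(spec[1:n_bins + 1])
    frequencies = np.arange(1, n_bins + 1, dtype=float) / pad_length
    return InformationalSpectrum(
        id=series.id, pad_length=pad_length, frequencies=frequencies,
        amplitudes=amplitudes, source_length=series.length,
    )


def amplitude_at(series: NumericalSeries, F: float,
                 mean_center: bool = True) -> float:
    """Modulus of the discrete-time Fourier transform at an exact frequency.

    Agrees with :func:`informational_spectrum` at grid frequencies k/Npad;
    unlike the padded spectrum it is defined at any F in (0, 0.5].
    """
    if not (0.0 < F <= 0.5):
        raise ValueError(f"frequency {F} outside (0, 0.5]")
    x = _centered(series.values, mean_center)
    n = np.arange(x.size)
    return float(abs(np.sum(x * np.exp(-2j * math.pi * F * n))))


def cross_spectrum(spectra: Sequence[InformationalSpectrum]) -> ConsensusSpectrum:
    """Element-wise product of member amplitude spectra (consensus spectrum)."""
    if not spectra:
        raise ValueError("cross_spectrum requires at least one spectrum")
    pad = spectra[0].pad_length
    for s in spectra[1:]:
        if s.pad_length != pad:
            raise ValueError(
                f"mismatched pad lengths: {s.pad_length} vs {pad}")
    amplitudes = np.prod([s.amplitudes for s in spectra], axis=0)
    return ConsensusSpectrum(
        member_ids=tuple(s.id for s in spectra), pad_length=pad,
        frequencies=spectra[0].frequencies.copy(), amplitudes=amplitudes,
    )


def _bin_index(spectrum: InformationalSpectrum | ConsensusSpectrum,
               F: float) -> int:
    """Index of the grid bin matching F within half a grid step."""
    freqs = spectrum.frequencies
    idx = int(np.argmin(np.abs(freqs - F)))
    tol = 1.0 / (2 * spectrum.pad_length)
    if abs(freqs[idx] - F) > tol + 1e-12:
        raise ValueError(
            f"frequency {F} not on the spectrum grid (pad {spectrum.pad_length})")
    return idx


def signal_to_noise(spectrum: InformationalSpectrum | ConsensusSpectrum,
                    F: float) -> float:
    """Amplitude at F divided by the mean amplitude of the whole spectrum."""
    idx = _bin_index(spectrum, F)
    amp = float(spectrum.amplitudes[idx])
    mean = float(spectrum.amplitudes.mean())
    if mean == 0.0:
        if amp == 0.0:
            return 0.0
        raise ValueError("signal-to-noise undefined: zero mean amplitude")
    return amp / mean


def dominant_peak(spectrum: InformationalSpectrum | ConsensusSpectrum
                  ) -> SpectralPeak:
    """The rank-1 spectral peak; ties broken by the lowest frequency."""
    amps = spectrum.amplitudes
    if amps.size < 1:
        raise ValueError("empty spectrum")
    idx = int(np.argmax(amps))  # argmax returns the first (lowest-F) maximum
    mean = float(amps.mean())
    amp = float(amps[idx])
    snr = amp / mean if mean > 0 else 0.0
    return SpectralPeak(frequency=float(spectrum.frequencies[idx]),
                        amplitude=amp, snr=snr, rank=1)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_spectrum_tsv(path: str | Path,
                       spectrum: InformationalSpectrum | ConsensusSpectrum,
                       members: Sequence[InformationalSpectrum] = ()) -> None:
    """Tab-separated spectrum export: frequency, then one amplitude column
    per member (for a consensus) and the product/amplitude column."""
    with open(path, "w") as fh:
        if members:
            header = ["frequency", *[m.id for m in members], "product"]
            fh.write("\t".join(header) + "\n")
            for i, f in enumerate(spectrum.frequencies):
                row = [f"{f:.6f}"] + [f"{m.amplitudes[i]:.6g}" for m in members]
                row.append(f"{spectrum.amplitudes[i]:.6g}")
                fh.write("\t".join(row) + "\n")
        else:
            fh.write("frequency\tamplitude\n")
            for f, a in zip(spectrum.frequencies, spectrum.amplitudes):
                fh.write(f"{f:.6f}\t{a:.6g}\n")
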