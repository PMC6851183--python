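"""End-to-end design workflow.

family FASTA -> individual spectra -> consensus spectrum -> characteristic
frequency -> per-sequence peptide scan -> candidate nanobody-derived
peptide report.  Every stage is also exposed individually through the CLI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .ism import (DEFAULT_PAD, EIIPTable, FREQ_DECIMALS, cross_spectrum,
                  dominant_peak, encode_sequence, informational_spectrum,
                  load_fasta, signal_to_noise, write_spectrum_tsv)
from .scan import ScanConfig, scan, scan_report


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of a design run; round-trips through YAML."""

    eiip_table: Optional[str] = None       # path; None = built-in scale
    pad_length: int = DEFAULT_PAD
    mean_center: bool = True
    target_frequency: Optional[float] = None  # None = consensus peak
    min_window: int = 10
    max_window: int = 30
    step: int = 1
    score: str = "snr"
    seed: int = 0
    output_dir: Optional[str] = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def load_table(self) -> EIIPTable:
        if self.eiip_table:
            return EIIPTable.from_file(self.eiip_table)
        return EIIPTable.default()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def run_design(family_path: str | Path,
               config: PipelineConfig = PipelineConfig()) -> dict:
    """Run the full design workflow; returns the report as a JSON-able dict.

    Stages: load family -> EIIP-encode -> individual spectra -> consensus
    -> frequency selection (configured target or consensus dominant peak)
    -> scan each member -> extract the best peptide per member.
    Intermediates are written to ``config.output_dir`` when set.
    """
    table = config.load_table()

    try:
        family = load_fasta(family_path)
    except Exception as exc:
        raise StageError("load_family", str(exc)) from exc

    spectra = []
    for rid, seq in family:
        try:
            series = encode_sequence(seq, table, id=rid)
            spectra.append(informational_spectrum(
                series, config.pad_length, config.mean_center))
        except Exception as exc:
            raise StageError("spectrum", f"record {rid!r}: {exc}") from exc

    consensus = cross_spectrum(spectra)
    peak = dominant_peak(consensus)

    if config.target_frequency is not None:
        target = config.target_frequency
    else:
        target = peak.frequency  # full grid precision; rounded for display

    scan_cfg = ScanConfig(target_frequency=target,
                          min_window=config.min_window,
                          max_window=config.max_window, step=config.step,
                          score=config.score,
                          mean_center=config.mean_center)
    scans = []
    for rid, seq in family:
        try:
            result = scan(seq, table, scan_cfg, sequence_id=rid)
        except Exception as exc:
            raise StageError("scan", f"record {rid!r}: {exc}") from exc
        best = result.best
        scans.append({
            "sequence_id": rid,
            "best_region": [best.start, best.end],
            "best_length": best.length,
            "amplitude": best.amplitude,
            "snr": best.snr,
            "peptide": result.best_peptide,
        })

    report = {
        "tool_version": __version__,
        "config": asdict(config),
        "consensus_peak": {
            "frequency": round(peak.frequency, FREQ_DECIMALS),
            "frequency_exact": peak.frequency,
            "amplitude": peak.amplitude,
            "snr": peak.snr,
        },
        "target_frequency": target,
        "individual_peaks": [
            {"sequence_id": s.id,
             "frequency": round(dominant_peak(s).frequency, FREQ_DECIMALS),
             "amplitude": dominant_peak(s).amplitude,
             "snr": dominant_peak(s).snr}
            for s in spectra
        ],
        "designs": scans,
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in spectra:
            write_spectrum_tsv(outdir / f"spectrum_{s.id}.tsv", s)
        write_spectrum_tsv(outdir / "consensus.tsv", consensus,
                           members=spectra)
        for rid, seq in family:
            result = scan(seq, table, scan_cfg, sequence_id=rid)
            (outdir / f"scan_{rid}.tsv").write_text(scan_report(result, 25))
        (outdir / "design_report.json").write_text(
            json.dumps(report, indent=2))
        (outdir / "effective_config.yaml").write_text(config.to_yaml())

    return report
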