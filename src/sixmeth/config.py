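"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .methylation import DEFAULT_MIN_READS, DEFAULT_VALLEY
from .model import DEFAULT_DISPERSION_CUTOFF, DEFAULT_SMOOTHING_WINDOW


@dataclass
class RunConfig:
    """All knobs of the pipeline; defaults are the published constants."""

    cds_fasta: str = ""
    expression_tsv: str = ""
    methylation_tsv: str | None = None
    sites_tsv: str | None = None
    exons_tsv: str | None = None
    sixmer_table_tsv: str | None = None
    out_dir: str = "sixmeth_out"

    min_reads: int = DEFAULT_MIN_READS
    valley: float = DEFAULT_VALLEY
    dispersion_cutoff: float = DEFAULT_DISPERSION_CUTOFF
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    smoothing: str = "geometric"
    seed: int = 0
    preset: str = "fit"              # "fit" | "published"
    aggregation_set: str = "all"     # "all" | "methylated"
    calibration_set: str = "methylated"
    contexts: list[str] | None = None

    gradlm_max: float = 0.07
    gradmr_max: float = 0.2
    min_length_nt: float = 900.0
    best_fraction: float = 0.79

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
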