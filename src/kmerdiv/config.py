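"""Pipeline configuration: every published threshold in one place.

Defaults follow the analysis as published: 25-nt k-mers, a 20,000
combined-count HAKmer threshold (with optional rescaling to the
configured sequencing depth), 5% FDR with a two-fold minimum change,
a 10-count ceiling for genotype-specific calls, top-5% conserved
single-copy selection, the >1000-in-5 / <10-in-5 highly-variable
filter, and cnvQTL settings (1,000 permutations, 5% type I error,
minimum declared LOD of 4). Config files are flat ``key=value`` lines;
explicit keyword overrides take precedence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    k: int = 25
    min_count_filter: int = 2
    hakmer_min_total: int = 20_000
    scale_min_total_to_depth: bool = True
    combined_depth: float | None = None
    fdr: float = 0.05
    min_fold: float = 2.0
    specific_max_low: int = 10
    band_lo_frac: float = 0.55
    band_hi_frac: float = 1.35
    band_override_lo: int | None = None
    band_override_hi: int | None = None
    top_frac: float = 0.05
    hv_high: float = 1000.0
    hv_n_high: int = 5
    hv_low: float = 10.0
    hv_n_low: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    declare_min: float = 4.0
    min_peak_gap: float = 30.0
    max_peaks: int = 4
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hakmer_min_total", "n_perm", "specific_max_low",
                     "hv_n_high", "hv_n_low", "max_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fdr", "alpha", "top_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def seed_for(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the base seed."""
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        return (self.seed * 10_007 + sum(stage.encode())) % (2**31)

    def effective_min_total(self) -> int:
        """HAKmer threshold, depth-rescaled when configured for simulations."""
        if self.scale_min_total_to_depth and self.combined_depth:
            from .differential import scaled_min_total

            return scaled_min_total(self.combined_depth,
                                    base=self.hakmer_min_total)
        return self.hakmer_min_total

    def band_override(self) -> tuple[int, int] | None:
        if self.band_override_lo is not None and self.band_override_hi is not None:
            return (self.band_override_lo, self.band_override_hi)
        return None

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse flat key=value lines; keyword overrides win."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(val)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(val: str):
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        return val
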