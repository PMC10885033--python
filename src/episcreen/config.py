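"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Relaxed differential-methylation threshold for the low-stringency mode.
RELAXED_DMR_DELTA = 0.20


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline.

    Attributes
    ----------
    ratio_threshold
        Minimum fold ratio (inclusive) for a preferential-expression call.
    expression_floor
        Minimum expression (TPM/FPKM, inclusive) in the target context.
    dmr_delta
        Minimum absolute per-CpG methylation difference (inclusive) for a
        CpG to be a DMR candidate.  Standard 0.35; relaxed mode 0.20.
    min_cpgs
        Minimum number of member CpGs in a DMR.
    max_gap_bp
        Maximum genomic gap between consecutive member CpGs of a DMR or LMR.
    promoter_window_bp
        Half-width of the promoter window on each side of the TSS.
    lmr_min_run
        Minimum number of CpGs in a low-methylated region.
    lmr_cpg_ceiling
        Maximum methylation of every member CpG of an LMR.
    lmr_baseline_margin
        An LMR's mean methylation must be at least this far below the
        genome-wide mean of the same track.
    intergenic_horizon_bp
        Maximum TSS distance for the ``intergenic_near`` location class.
    brain_central_tendency
        Aggregator for the other-brain-regions denominator
        (``median`` or ``mean``).
    nonbrain_central_tendency
        Aggregator for the non-brain denominator (``mean`` or ``median``).
    min_coverage
        Per-CpG coverage floor applied where a coverage column exists.
    rng_seed
        Seed for every stochastic step.
    """

    ratio_threshold: float = 5.0
    expression_floor: float = 1.0
    dmr_delta: float = 0.35
    min_cpgs: int = 3
    max_gap_bp: int = 250
    promoter_window_bp: int = 2000
    lmr_min_run: int = 5
    lmr_cpg_ceiling: float = 0.5
    lmr_baseline_margin: float = 0.3
    intergenic_horizon_bp: int = 25_000
    brain_central_tendency: str = "median"
    nonbrain_central_tendency: str = "mean"
    min_coverage: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise ValueError("ratio_threshold must be > 1")
        if not (0 < self.dmr_delta <= 1):
            raise ValueError("dmr_delta must be in (0, 1]")
        if self.promoter_window_bp < 0:
            raise ValueError("promoter_window_bp must be >= 0")
        if self.brain_central_tendency not in ("median", "mean"):
            raise ValueError("brain_central_tendency must be 'median' or 'mean'")
        if self.nonbrain_central_tendency not in ("median", "mean"):
            raise ValueError("nonbrain_central_tendency must be 'mean' or 'median'")
        if self.min_cpgs < 1 or self.lmr_min_run < 1:
            raise ValueError("min_cpgs and lmr_min_run must be >= 1")

    def relaxed(self) -> "RunConfig":
        """Copy of this config with the relaxed DMR threshold."""
        return dataclasses.replace(self, dmr_delta=RELAXED_DMR_DELTA)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
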