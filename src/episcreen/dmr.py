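"""DMR and LMR calling over per-CpG methylation tracks.

A DMR is a maximal run of sign-consistent candidate CpGs (|delta| at or
above the threshold, inclusive) in which consecutive members are at most
``max_gap_bp`` apart; any intervening evaluated CpG of opposite sign or
sub-threshold |delta| breaks the run.  An LMR is a maximal run of CpGs at
or below a ceiling whose mean sits well below the genome-wide mean of the
same track.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_formats import DMR, LMR, MethylomeTrack


def per_cpg_delta(
    target_tracks: list[MethylomeTrack],
    panel_tracks: list[MethylomeTrack],
    min_coverage: int = 0,
) -> pd.DataFrame:
    """Per-CpG difference: mean(target) - mean(panel).

    Only CpGs present in every track survive; where a track has a coverage
    column, its CpGs below ``min_coverage`` are dropped first (tracks
    without coverage are exempt).  Returns a DataFrame with columns
    chrom, pos, delta sorted by (chrom, pos).
    """
    if not target_tracks or not panel_tracks:
        raise ValueError("need at least one target and one panel track")

    def usable(track: MethylomeTrack, tag: str) -> pd.DataFrame:
        r = track.records
        if min_coverage > 0 and track.has_coverage:
            r = r[r["coverage"] >= min_coverage]
        return r[["chrom", "pos", "meth"]].rename(
            columns={"meth": f"{tag}_{track.sample_id}"})

    frames = [usable(t, "t") for t in target_tracks]
    frames += [usable(p, "p") for p in panel_tracks]
    merged = reduce(lambda a, b: a.merge(b, on=["chrom", "pos"], how="inner"),
                    frames)
    if merged.empty:
        raise ValueError("no common CpGs across tracks")
    t_cols = [c for c in merged.columns if c.startswith("t_")]
    p_cols = [c for c in merged.columns if c.startswith("p_")]
    out = merged[["chrom", "pos"]].copy()
    out["delta"] = merged[t_cols].mean(axis=1) - merged[p_cols].mean(axis=1)
    return out.sort_values(["chrom", "pos"], kind="mergesort",
                           ignore_index=True)


def call_dmrs(delta_series: pd.DataFrame,
              config: RunConfig | None = None) -> list[DMR]:
    """Segment a per-CpG delta series into DMRs (see module docstring)."""
    config = config or RunConfig()
    threshold = config.dmr_delta
    dmrs: list[DMR] = []

    for chrom, sub in delta_series.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        run_pos: list[int] = []
        run_delta: list[float] = []
        run_sign = 0

        def flush() -> None:
            if len(run_pos) >= config.min_cpgs:
                mean_delta = float(np.mean(run_delta))
                dmrs.append(DMR(
                    chrom=chrom, start=int(run_pos[0]), end=int(run_pos[-1]) + 1,
                    direction="hyper" if run_sign > 0 else "hypo",
                    n_cpgs=len(run_pos), mean_delta=mean_delta))

        for p, d in zip(pos, delta):
            sign = 1 if d > 0 else -1
            candidate = abs(d) >= threshold
            extends = (candidate and run_pos and sign == run_sign
                       and p - run_pos[-1] <= config.max_gap_bp)
            if extends:
                run_pos.append(int(p))
                run_delta.append(float(d))
                continue
            flush()
            if candidate:
                run_pos, run_delta, run_sign = [int(p)], [float(d)], sign
            else:
                run_pos, run_delta, run_sign = [], [], 0
        flush()
    return dmrs


def call_lmrs(track: MethylomeTrack,
              config: RunConfig | None = None) -> list[LMR]:
    """Low-methylated regions relative to the track's genome-wide mean.

    This is a deterministic threshold proxy (ceiling + margin below the
    baseline), not a statistical segmentation.
    """
    config = config or RunConfig()
    if len(track) == 0:
        raise ValueError("empty methylome track")
    baseline = float(track.records["meth"].mean())
    cutoff = baseline - config.lmr_baseline_margin
    lmrs: list[LMR] = []

    for chrom, sub in track.records.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        run_pos: list[int] = []
        run_meth: list[float] = []

        def flush() -> None:
            if len(run_pos) >= config.lmr_min_run:
                mean_meth = float(np.mean(run_meth))
                if mean_meth <= cutoff:
                    lmrs.append(LMR(
                        chrom=chrom, start=int(run_pos[0]),
                        end=int(run_pos[-1]) + 1, n_cpgs=len(run_pos),
                        mean_meth=mean_meth, genome_baseline=baseline))

        for p, m in zip(pos, meth):
            low = m <= config.lmr_cpg_ceiling
            extends = (low and run_pos
                       and p - run_pos[-1] <= config.max_gap_bp)
            if extends:
                run_pos.append(int(p))
                run_meth.append(float(m))
                continue
            flush()
            run_pos, run_meth = ([int(p)], [float(m)]) if low else ([], [])
        flush()
    return lmrs
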