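"""Headline summary numbers and formatted report tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RunConfig
from .integrate import GeneEpigeneticSummary, count_genes_with_dmrs


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``.

    Half-up (not banker's) rounding so printed percentages match hand
    arithmetic: 4.739 -> 5 at zero decimals.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ScreenReport:
    """Assembled counts, percentages and gene lists for one run."""

    universe_size: int
    set_sizes: dict[str, int]
    set_percentages: dict[str, float]  # vs universe, one decimal
    dual_size: int
    dual_pct_of_target: float  # vs target-culture set, nearest integer
    gene_lists: dict[str, list[str]]
    overlap: pd.DataFrame | None = None
    n_genes_with_dmrs: int | None = None
    n_genes_summarized: int | None = None


def build_report(
    universe: Sequence[str],
    context_sets: dict[str, set[str]],
    target_context: str,
    dual_genes: Sequence[str],
    overlap: pd.DataFrame | None = None,
    summaries: Sequence[GeneEpigeneticSummary] | None = None,
    config: RunConfig | None = None,
) -> ScreenReport:
    """Assemble a deterministic report from one run's outputs."""
    universe_set = set(universe)
    for context, genes in context_sets.items():
        stray = genes - universe_set
        if stray:
            raise ValueError(
                f"genes outside the universe in context {context!r}: "
                f"{sorted(stray)[:5]}")
    if target_context not in context_sets:
        raise ValueError(f"target context {target_context!r} missing")

    sizes = {c: len(g) for c, g in sorted(context_sets.items())}
    pcts = {c: percent(n, len(universe_set), 1) if universe_set else 0.0
            for c, n in sizes.items()}
    target_n = sizes[target_context]
    dual_pct = percent(len(dual_genes), target_n, 0) if target_n else 0.0
    return ScreenReport(
        universe_size=len(universe_set),
        set_sizes=sizes,
        set_percentages=pcts,
        dual_size=len(dual_genes),
        dual_pct_of_target=dual_pct,
        gene_lists={c: sorted(g) for c, g in sorted(context_sets.items())},
        overlap=overlap,
        n_genes_with_dmrs=(count_genes_with_dmrs(summaries)
                           if summaries is not None else None),
        n_genes_summarized=len(summaries) if summaries is not None else None,
    )


def report_to_frame(report: ScreenReport) -> pd.DataFrame:
    """Flatten the headline numbers into a two-column key/value table."""
    rows = [("universe_size", report.universe_size)]
    for context in report.set_sizes:
        rows.append((f"n_{context}", report.set_sizes[context]))
        rows.append((f"pct_{context}", report.set_percentages[context]))
    rows.append(("n_dual", report.dual_size))
    rows.append(("pct_dual_of_target", report.dual_pct_of_target))
    if report.n_genes_with_dmrs is not None:
        rows.append(("n_dual_genes_with_dmrs", report.n_genes_with_dmrs))
        rows.append(("n_genes_summarized", report.n_genes_summarized))
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_report(report: ScreenReport, out_dir: str | Path) -> None:
    """Write the key/value TSV, gene lists, overlap table and a markdown
    summary; output is byte-identical across reruns on the same inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_to_frame(report).to_csv(out_dir / "report.tsv", sep="\t", index=False)
    for context, genes in report.gene_lists.items():
        (out_dir / f"genes_{context}.txt").write_text(
            "".join(f"{g}\n" for g in genes))
    if report.overlap is not None:
        report.overlap.to_csv(out_dir / "overlap_matrix.tsv", sep="\t",
                              index=False)
    lines = ["# Screen summary", ""]
    lines.append(f"- gene universe: {report.universe_size}")
    for context in report.set_sizes:
        lines.append(f"- {context}: {report.set_sizes[context]} genes "
                     f"({report.set_percentages[context]}% of universe)")
    lines.append(f"- dual-preferential: {report.dual_size} genes "
                 f"({report.dual_pct_of_target}% of the target-culture set)")
    if report.n_genes_with_dmrs is not None:
        lines.append(f"- genes with >=1 DMR: {report.n_genes_with_dmrs} "
                     f"of {report.n_genes_summarized}")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
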