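"""TSS-relative DMR classification and per-gene epigenetic summaries.

Signed distances are measured in the direction of transcription: positive
downstream of the TSS, negative upstream, zero when a region overlaps the
TSS.  Each DMR-gene pair receives exactly one location class (or none when
the DMR lies beyond the intergenic horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import RunConfig
from .io_formats import DMR, LMR, GeneAnnotation

LOCATION_CLASSES = ("promoter_upstream", "promoter_downstream",
                    "intragenic", "intergenic_near")


@dataclass
class GeneEpigeneticSummary:
    """Per-gene tallies of assigned DMRs by direction and location class."""

    gene_id: str
    n_hypo: int = 0
    n_hyper: int = 0
    location_counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in LOCATION_CLASSES})
    has_promoter_hypom: bool = False
    has_promoter_hyperm: bool = False
    n_promoter_lmrs: int = 0


def _directional_interval(dmr_start: int, dmr_end: int,
                          gene: GeneAnnotation) -> tuple[int, int]:
    """Map a genomic half-open interval into transcription-direction
    coordinates with the TSS at 0."""
    tss = gene.tss
    if gene.strand == "+":
        return dmr_start - tss, dmr_end - tss
    return tss - dmr_end + 1, tss - dmr_start + 1


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def classify_dmr_location(dmr: DMR, gene: GeneAnnotation,
                          config: RunConfig | None = None
                          ) -> tuple[str | None, int]:
    """Location class and signed TSS distance of a DMR relative to one gene.

    Distance is from the TSS to the nearest DMR edge (0 when overlapping the
    TSS).  Precedence: promoter_downstream > promoter_upstream > intragenic
    > intergenic_near; beyond the horizon the class is None.
    """
    config = config or RunConfig()
    if dmr.chrom != gene.chrom:
        raise ValueError(
            f"DMR on {dmr.chrom} vs gene {gene.gene_id} on {gene.chrom}")
    a, b = _directional_interval(dmr.start, dmr.end, gene)
    if a <= 0 < b:
        distance = 0
    elif a > 0:
        distance = a
    else:
        distance = b

    W = config.promoter_window_bp
    body_len = gene.end - gene.start  # body is [0, body_len) in TSS coords
    if _overlaps((a, b), (0, W)):
        cls = "promoter_downstream"
    elif _overlaps((a, b), (-W, 0)):
        cls = "promoter_upstream"
    elif _overlaps((a, b), (W, body_len)):
        cls = "intragenic"
    elif abs(distance) <= config.intergenic_horizon_bp:
        cls = "intergenic_near"
    else:
        cls = None
    return cls, distance


def assign_dmrs_to_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneAnnotation],
    config: RunConfig | None = None,
) -> dict[str, list[DMR]]:
    """Assign each DMR to its nearest gene by absolute TSS distance.

    Ties break on lexicographic gene id; DMRs on chromosomes with no genes
    are left unassigned.
    """
    config = config or RunConfig()
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: dict[str, list[DMR]] = {g.gene_id: [] for g in genes}
    for dmr in dmrs:
        candidates = by_chrom.get(dmr.chrom, [])
        if not candidates:
            continue
        best = min(candidates,
                   key=lambda g: (abs(classify_dmr_location(dmr, g, config)[1]),
                                  g.gene_id))
        assigned[best.gene_id].append(dmr)
    return assigned


def summarize_gene_epigenetics(
    gene: GeneAnnotation,
    dmrs: Sequence[DMR],
    lmrs: Sequence[LMR] = (),
    config: RunConfig | None = None,
) -> GeneEpigeneticSummary:
    """Tally the gene's assigned DMRs by direction and location class.

    DMRs beyond the intergenic horizon are ignored so that the direction
    totals always equal the sum over location classes.  LMRs touching the
    promoter window are counted separately and do not affect the DMR flags.
    """
    config = config or RunConfig()
    summary = GeneEpigeneticSummary(gene_id=gene.gene_id)
    W = config.promoter_window_bp
    for dmr in dmrs:
        cls, _ = classify_dmr_location(dmr, gene, config)
        if cls is None:
            continue
        summary.location_counts[cls] += 1
        if dmr.direction == "hypo":
            summary.n_hypo += 1
        else:
            summary.n_hyper += 1
        if cls in ("promoter_upstream", "promoter_downstream"):
            if dmr.direction == "hypo":
                summary.has_promoter_hypom = True
            else:
                summary.has_promoter_hyperm = True
    for lmr in lmrs:
        if lmr.chrom != gene.chrom:
            continue
        a, b = _directional_interval(lmr.start, lmr.end, gene)
        if _overlaps((a, b), (-W, W)):
            summary.n_promoter_lmrs += 1
    return summary


def summarize_all_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneAnnotation],
    lmrs: Sequence[LMR] = (),
    config: RunConfig | None = None,
) -> list[GeneEpigeneticSummary]:
    """Nearest-gene assignment followed by per-gene summaries, gene order
    preserved."""
    config = config or RunConfig()
    assigned = assign_dmrs_to_genes(dmrs, genes, config)
    return [summarize_gene_epigenetics(g, assigned[g.gene_id], lmrs, config)
            for g in genes]


def count_genes_with_dmrs(summaries: Sequence[GeneEpigeneticSummary]) -> int:
    """Number of genes carrying at least one assigned DMR."""
    return sum(1 for s in summaries if s.n_hypo + s.n_hyper >= 1)


def overlap_intervals(
    queries: Sequence[tuple[str, int, int]],
    track: Sequence[tuple[str, int, int]],
) -> list[list[tuple[str, int, int]]]:
    """For each query interval, the track intervals it overlaps.

    Any-overlap under half-open semantics: [a, b) and [c, d) overlap iff
    max(a, c) < min(b, d).
    """
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for iv in track:
        by_chrom.setdefault(iv[0], []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: (iv[1], iv[2]))
    out = []
    for chrom, qs, qe in queries:
        hits = [iv for iv in by_chrom.get(chrom, ())
                if max(qs, iv[1]) < min(qe, iv[2])]
        out.append(hits)
    return out
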