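"""Simulators with planted ground truth.

Expression values are drawn as ``planted_mean * exp(N(0, noise_sd^2))``
(multiplicative log-normal noise, truncated at zero by construction);
per-CpG methylation fractions are Beta-distributed around planted region
means.  Planted effect sizes sit far from the decision thresholds so that
noisy recovery is testable, while the boundary class sits exactly at the
ratio threshold to pin comparator semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneAnnotation, MethylomeTrack

# sample layout mirrored from the data sources the screen assumes:
# one cerebellum column, 10 other brain regions, 41 non-brain tissues,
# and six cell cultures of which myoblast is the target.
CEREBELLUM = "cerebellum"
BRAIN_OTHER_SAMPLES = tuple(f"brain_other_{i:02d}" for i in range(1, 11))
NON_BRAIN_SAMPLES = tuple(f"non_brain_{i:02d}" for i in range(1, 42))
TISSUE_SAMPLES = (CEREBELLUM,) + BRAIN_OTHER_SAMPLES + NON_BRAIN_SAMPLES

TARGET_CULTURE = "myoblast"
OTHER_CULTURES = ("ESC", "LCL", "NHEK", "HUVEC", "NHLF")
CULTURE_SAMPLES = (TARGET_CULTURE,) + OTHER_CULTURES

TISSUE_GROUP_MAP = {CEREBELLUM: "cerebellum",
                    **{s: "brain_other" for s in BRAIN_OTHER_SAMPLES},
                    **{s: "non_brain" for s in NON_BRAIN_SAMPLES}}
CULTURE_GROUP_MAP = {s: s for s in CULTURE_SAMPLES}

# planted mean expression levels
_HIGH, _MID, _LOW, _SILENT = 50.0, 20.0, 2.0, 0.1

GENE_CLASSES = ("dual_specific", "myob_only", "cbl_only", "broadly_expressed",
                "silent", "zero_denominator_rescue", "boundary_ratio")

REGION_TYPES = ("hypo_dmr", "hyper_dmr", "lmr", "background")
_REGION_DEFAULT_MEANS = {"hypo_dmr": (0.10, 0.85),
                         "hyper_dmr": (0.90, 0.15),
                         "lmr": (0.05, 0.05)}


@dataclass
class GroundTruthManifest:
    """Planted gene classes and planted methylation regions.

    ``genes`` columns: gene_id, planted_class.
    ``regions`` columns: chrom, start, end, region_type, target_mean,
    panel_mean.
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "planted_class"]))
    regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "region_type",
                 "target_mean", "panel_mean"]))
    background_mean: float | None = None

    def genes_of_class(self, planted_class: str) -> set[str]:
        g = self.genes
        return set(g.loc[g["planted_class"] == planted_class, "gene_id"])

    def regions_of_type(self, region_type: str) -> pd.DataFrame:
        r = self.regions
        return r.loc[r["region_type"] == region_type].reset_index(drop=True)


@dataclass(frozen=True)
class PlantedRegion:
    """A methylation region to plant: interval plus per-class means."""

    chrom: str
    start: int
    end: int
    region_type: str
    target_mean: float | None = None
    panel_mean: float | None = None

    def resolved_means(self) -> tuple[float, float]:
        dflt = _REGION_DEFAULT_MEANS.get(self.region_type, (None, None))
        t = self.target_mean if self.target_mean is not None else dflt[0]
        p = self.panel_mean if self.panel_mean is not None else dflt[1]
        if t is None or p is None:
            raise ValueError(f"no means for region type {self.region_type!r}")
        if not (0 <= t <= 1 and 0 <= p <= 1):
            raise ValueError("planted region means must be in [0, 1]")
        return t, p


def _class_means(planted_class: str, ratio_threshold: float,
                 expression_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean expression for one planted class."""
    tissue = np.full(len(TISSUE_SAMPLES), _MID)
    culture = np.full(len(CULTURE_SAMPLES), _MID)
    n_brain, n_nonbrain = len(BRAIN_OTHER_SAMPLES), len(NON_BRAIN_SAMPLES)

    def cbl_specific(level: float, nonbrain: float = _LOW) -> None:
        tissue[0] = level
        tissue[1:1 + n_brain] = _LOW
        tissue[1 + n_brain:] = nonbrain

    def myob_specific(level: float) -> None:
        culture[0] = level
        culture[1:] = _LOW

    if planted_class == "dual_specific":
        myob_specific(_HIGH)
        cbl_specific(_HIGH)
    elif planted_class == "myob_only":
        myob_specific(_HIGH)
    elif planted_class == "cbl_only":
        cbl_specific(_HIGH)
    elif planted_class == "broadly_expressed":
        pass
    elif planted_class == "silent":
        tissue[:] = _SILENT
        culture[:] = _SILENT
    elif planted_class == "zero_denominator_rescue":
        cbl_specific(30.0, nonbrain=0.0)
    elif planted_class == "boundary_ratio":
        # noise-free ratio sits exactly at the threshold in every context
        level = max(ratio_threshold * _LOW, expression_floor)
        myob_specific(level)
        cbl_specific(level)
    elif (planted_class.startswith("culture_")
          and planted_class.endswith("_specific")):
        name = planted_class[len("culture_"):-len("_specific")]
        if name not in CULTURE_SAMPLES:
            raise ValueError(f"unknown culture {name!r}")
        idx = CULTURE_SAMPLES.index(name)
        culture[:] = _LOW
        culture[idx] = _HIGH
    else:
        raise ValueError(f"unknown planted class {planted_class!r}")
    return tissue, culture


def simulate_expression(
    n_genes: int,
    class_counts: dict[str, int],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    ratio_threshold: float = 5.0,
    expression_floor: float = 1.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruthManifest]:
    """Simulate a 52-sample tissue matrix and a 6-sample culture matrix.

    Genes not covered by ``class_counts`` are filled as broadly expressed.
    Identical seeds give identical outputs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    total = sum(class_counts.values())
    if total > n_genes:
        raise ValueError("class_counts exceed n_genes")

    rng = np.random.default_rng(rng_seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    classes = np.array(["broadly_expressed"] * n_genes, dtype=object)
    slots = rng.permutation(n_genes)
    cursor = 0
    for cls, count in sorted(class_counts.items()):
        classes[slots[cursor:cursor + count]] = cls
        cursor += count

    tissue_means = np.empty((n_genes, len(TISSUE_SAMPLES)))
    culture_means = np.empty((n_genes, len(CULTURE_SAMPLES)))
    mean_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, cls in enumerate(classes):
        if cls not in mean_cache:
            mean_cache[cls] = _class_means(cls, ratio_threshold, expression_floor)
        tissue_means[i], culture_means[i] = mean_cache[cls]

    def noisy(means: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return means.copy()
        return means * np.exp(rng.normal(0.0, noise_sd, size=means.shape))

    tissue_mat = ExpressionMatrix(
        values=pd.DataFrame(noisy(tissue_means), index=gene_ids,
                            columns=list(TISSUE_SAMPLES)),
        unit_tag="TPM", group_map=dict(TISSUE_GROUP_MAP))
    culture_mat = ExpressionMatrix(
        values=pd.DataFrame(noisy(culture_means), index=gene_ids,
                            columns=list(CULTURE_SAMPLES)),
        unit_tag="FPKM", group_map=dict(CULTURE_GROUP_MAP))
    manifest = GroundTruthManifest(
        genes=pd.DataFrame({"gene_id": gene_ids, "planted_class": classes}))
    return tissue_mat, culture_mat, manifest


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def simulate_annotation(n_genes: int, chrom_sizes: dict[str, int],
                        rng_seed: int = 0,
                        biotypes: Sequence[str] | None = None,
                        ) -> list[GeneAnnotation]:
    """Place non-overlapping genes; both strands and all biotypes appear.

    ``biotypes`` overrides the random biotype mix (one entry per gene),
    e.g. all ``protein_coding`` when the caller needs the universe filter
    to keep every planted gene.
    """
    rng = np.random.default_rng(rng_seed)
    chroms = list(chrom_sizes)
    total_size = sum(chrom_sizes.values())
    counts = {c: int(round(n_genes * chrom_sizes[c] / total_size)) for c in chroms}
    # fix rounding drift on the largest chromosome
    largest = max(chroms, key=lambda c: chrom_sizes[c])
    counts[largest] += n_genes - sum(counts.values())

    strands = rng.choice(["+", "-"], size=n_genes)
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "+" if strands[0] == "-" else "-"
    if biotypes is not None:
        if len(biotypes) != n_genes:
            raise ValueError("biotypes must have one entry per gene")
        biotypes = np.asarray(biotypes, dtype=object)
    else:
        biotypes = rng.choice(["protein_coding", "ncRNA", "mito", "other"],
                              size=n_genes, p=[0.85, 0.09, 0.03, 0.03])
        if n_genes >= 3:  # guarantee the biotypes the universe filter needs
            biotypes[0] = "protein_coding"
            biotypes[1] = "ncRNA"
            biotypes[2] = "mito"

    genes: list[GeneAnnotation] = []
    i = 0
    for chrom in chroms:
        n = counts[chrom]
        if n == 0:
            continue
        lengths = rng.integers(1_000, 10_001, size=n)
        gaps = rng.integers(500, 3_001, size=n)
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
        ends = starts + lengths
        if ends[-1] > chrom_sizes[chrom]:
            raise ValueError(f"insufficient length on {chrom} for {n} genes")
        for s, e in zip(starts, ends):
            genes.append(GeneAnnotation(
                gene_id=f"g{i:05d}", chrom=chrom, start=int(s), end=int(e),
                strand=str(strands[i]), biotype=str(biotypes[i])))
            i += 1
    return genes


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def _as_planted_region(r) -> PlantedRegion:
    if isinstance(r, PlantedRegion):
        return r
    return PlantedRegion(*r)


def simulate_methylomes(
    annotation: Sequence[GeneAnnotation],
    planted_regions: Iterable[PlantedRegion | tuple],
    n_target_reps: int = 3,
    n_panel: int = 6,
    cpg_spacing: int = 20,
    background_spacing: int = 200,
    beta_concentration: float = math.inf,
    background_mean: float = 0.75,
    coverage_mean: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
    rng_seed: int = 0,
) -> tuple[list[MethylomeTrack], list[MethylomeTrack], GroundTruthManifest]:
    """Simulate replicated target and panel methylomes with planted regions.

    CpG positions are laid down on a dense grid inside planted regions and a
    sparse grid elsewhere; every sample shares the same positions.  With
    ``beta_concentration`` infinite each CpG equals its planted mean exactly
    (noise-free mode); otherwise fractions are Beta-distributed with that
    mean and concentration.
    """
    if beta_concentration <= 0:
        raise ValueError("beta_concentration must be > 0")
    regions = [_as_planted_region(r) for r in planted_regions]
    for r in regions:
        r.resolved_means()  # validates means

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in annotation:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
        for r in regions:
            if r.chrom in chrom_sizes:
                chrom_sizes[r.chrom] = max(chrom_sizes[r.chrom], r.end)
        chrom_sizes = {c: s + 10_000 for c, s in chrom_sizes.items()}

    by_chrom: dict[str, list[PlantedRegion]] = {}
    for r in regions:
        if r.chrom not in chrom_sizes or r.end > chrom_sizes[r.chrom]:
            raise ValueError(f"planted region outside any chromosome: {r}")
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping planted regions on {chrom}")

    # shared CpG grid with per-position planted means
    chrom_col: list[str] = []
    pos_col: list[np.ndarray] = []
    target_mean_col: list[np.ndarray] = []
    panel_mean_col: list[np.ndarray] = []
    for chrom in sorted(chrom_sizes):
        pos = set(range(0, chrom_sizes[chrom], background_spacing))
        for r in by_chrom.get(chrom, []):
            pos.update(range(r.start, r.end, cpg_spacing))
        pos = np.array(sorted(pos), dtype=int)
        t_mean = np.full(len(pos), background_mean)
        p_mean = np.full(len(pos), background_mean)
        for r in by_chrom.get(chrom, []):
            t, p = r.resolved_means()
            inside = (pos >= r.start) & (pos < r.end)
            t_mean[inside] = t
            p_mean[inside] = p
        chrom_col.extend([chrom] * len(pos))
        pos_col.append(pos)
        target_mean_col.append(t_mean)
        panel_mean_col.append(p_mean)
    positions = np.concatenate(pos_col) if pos_col else np.array([], dtype=int)
    target_means = np.concatenate(target_mean_col) if pos_col else np.array([])
    panel_means = np.concatenate(panel_mean_col) if pos_col else np.array([])

    rng = np.random.default_rng(rng_seed)

    def draw(means: np.ndarray) -> np.ndarray:
        if math.isinf(beta_concentration):
            return means.copy()
        m = np.clip(means, 1e-9, 1 - 1e-9)
        return rng.beta(m * beta_concentration, (1 - m) * beta_concentration)

    def make_track(sample_id: str, means: np.ndarray) -> MethylomeTrack:
        coverage = (rng.poisson(coverage_mean, size=len(positions)).astype(float)
                    if coverage_mean is not None else np.nan)
        records = pd.DataFrame({"chrom": chrom_col, "pos": positions,
                                "meth": draw(means), "coverage": coverage})
        return MethylomeTrack(sample_id=sample_id, records=records)

    targets = [make_track(f"target_rep{i + 1}", target_means)
               for i in range(n_target_reps)]
    panel = [make_track(f"panel_{i + 1:02d}", panel_means)
             for i in range(n_panel)]

    manifest = GroundTruthManifest(
        regions=pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end,
              "region_type": r.region_type,
              "target_mean": r.resolved_means()[0],
              "panel_mean": r.resolved_means()[1]} for r in regions],
            columns=["chrom", "start", "end", "region_type",
                     "target_mean", "panel_mean"]),
        background_mean=background_mean)
    return targets, panel, manifest
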