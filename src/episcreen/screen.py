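"""Preferential-expression screen.

A gene is preferentially expressed in a context when its expression there
is at least ``ratio_threshold`` times the central tendency of the reference
contexts and at least ``expression_floor`` in absolute terms.  Both
comparators are inclusive.  For the cerebellum call, a zero denominator is
rescued when cerebellum is the strict tissue-wide maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_formats import ExpressionMatrix, GeneAnnotation

N_BRAIN_OTHER = 10
N_NON_BRAIN = 41
N_CULTURES = 6


@dataclass(frozen=True)
class SpecificityCall:
    """Outcome of one gene x context preferential-expression test."""

    gene_id: str
    context: str
    numerator: float
    denominators: dict[str, float]
    ratio: float | None  # None == undefined (zero denominator)
    passed: bool
    rescue_applied: bool = False


def _central(values: np.ndarray, how: str) -> float:
    return float(np.median(values) if how == "median" else np.mean(values))


def filter_gene_universe(
    tissue_mat: ExpressionMatrix,
    culture_mat: ExpressionMatrix,
    annotation: list[GeneAnnotation],
    config: RunConfig | None = None,
    whitelist: set[str] | None = None,
) -> list[str]:
    """Gene universe for the screen, in tissue-matrix row order.

    Keeps genes that are present in both matrices and the annotation, are
    protein coding (unless whitelisted), are not mitochondrial, and clear
    the expression floor in at least one tissue and one culture.
    """
    config = config or RunConfig()
    whitelist = whitelist or set()
    floor = config.expression_floor
    biotype = {g.gene_id: g.biotype for g in annotation}
    culture_genes = set(culture_mat.gene_ids)
    if not culture_genes & set(tissue_mat.gene_ids):
        raise ValueError("no genes shared between the two matrices")

    kept = []
    for gene in tissue_mat.gene_ids:
        if gene not in culture_genes or gene not in biotype:
            continue
        if biotype[gene] == "mito":
            continue
        if biotype[gene] != "protein_coding" and gene not in whitelist:
            continue
        if tissue_mat.values.loc[gene].max() < floor:
            continue
        if culture_mat.values.loc[gene].max() < floor:
            continue
        kept.append(gene)
    return kept


def call_culture_preferential(
    culture_mat: ExpressionMatrix,
    target_culture: str,
    config: RunConfig | None = None,
    genes: list[str] | None = None,
) -> tuple[set[str], dict[str, SpecificityCall]]:
    """Target culture vs the unweighted mean of the other five cultures."""
    config = config or RunConfig()
    if target_culture not in culture_mat.sample_ids:
        raise ValueError(f"target culture {target_culture!r} absent")
    if len(culture_mat.sample_ids) != N_CULTURES:
        raise ValueError(f"expected exactly {N_CULTURES} culture samples")
    others = [s for s in culture_mat.sample_ids if s != target_culture]
    R, E = config.ratio_threshold, config.expression_floor

    calls: dict[str, SpecificityCall] = {}
    passed_set: set[str] = set()
    for gene in genes if genes is not None else culture_mat.gene_ids:
        num = float(culture_mat.values.at[gene, target_culture])
        denom = float(culture_mat.values.loc[gene, others].mean())
        if denom == 0:
            ratio = math.inf if num > 0 else None
            ok = num > 0 and num >= E  # zero denominator: floor alone decides
        else:
            ratio = num / denom
            ok = ratio >= R and num >= E
        calls[gene] = SpecificityCall(
            gene_id=gene, context=target_culture, numerator=num,
            denominators={"other_cultures_mean": denom}, ratio=ratio,
            passed=ok)
        if ok:
            passed_set.add(gene)
    return passed_set, calls


def call_cerebellum_preferential(
    tissue_mat: ExpressionMatrix,
    config: RunConfig | None = None,
    genes: list[str] | None = None,
) -> tuple[set[str], dict[str, SpecificityCall]]:
    """Cerebellum vs other brain regions and vs non-brain tissues.

    Criteria (all inclusive): cerebellum >= floor; cerebellum over the
    configured central tendency of the 10 other brain regions >= R; and
    cerebellum over the mean of the 41 non-brain tissues >= R.  A ratio
    criterion with a zero denominator passes only if cerebellum is positive
    and the strict maximum over all 52 tissues (the rescue rule).
    """
    config = config or RunConfig()
    cbl = tissue_mat.samples_in_group("cerebellum")
    brain = tissue_mat.samples_in_group("brain_other")
    nonbrain = tissue_mat.samples_in_group("non_brain")
    if len(cbl) != 1 or len(brain) != N_BRAIN_OTHER or len(nonbrain) != N_NON_BRAIN:
        raise ValueError(
            f"group cardinalities must be 1/{N_BRAIN_OTHER}/{N_NON_BRAIN}, got "
            f"{len(cbl)}/{len(brain)}/{len(nonbrain)}")
    cbl_sample = cbl[0]
    R, E = config.ratio_threshold, config.expression_floor

    calls: dict[str, SpecificityCall] = {}
    passed_set: set[str] = set()
    for gene in genes if genes is not None else tissue_mat.gene_ids:
        row = tissue_mat.values.loc[gene]
        num = float(row[cbl_sample])
        denom_brain = _central(row[brain].to_numpy(), config.brain_central_tendency)
        denom_nonbrain = _central(row[nonbrain].to_numpy(),
                                  config.nonbrain_central_tendency)
        others_max = float(row.drop(cbl_sample).max())
        is_strict_max = num > 0 and num > others_max
        rescue = False

        def ratio_criterion(denom: float) -> bool:
            nonlocal rescue
            if denom == 0:
                if is_strict_max:
                    rescue = True
                    return True
                return False
            return num / denom >= R

        ok = num >= E and ratio_criterion(denom_brain) \
            and ratio_criterion(denom_nonbrain)
        ratio = num / denom_nonbrain if denom_nonbrain > 0 else None
        calls[gene] = SpecificityCall(
            gene_id=gene, context="cerebellum", numerator=num,
            denominators={"brain_other": denom_brain,
                          "non_brain": denom_nonbrain},
            ratio=ratio, passed=ok, rescue_applied=rescue and ok)
        if ok:
            passed_set.add(gene)
    return passed_set, calls


def intersect_dual(set_a: set[str], set_b: set[str]) -> list[str]:
    """Ordered (by gene id) intersection of two preferential sets."""
    return sorted(set_a & set_b)


def overlap_matrix(
    culture_mat: ExpressionMatrix,
    cbl_set: set[str],
    config: RunConfig | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-culture preferential sets and their overlap with the cerebellum set.

    Each culture is screened against the other five (myoblasts included).
    """
    config = config or RunConfig()
    rows = []
    for culture in culture_mat.sample_ids:
        pref, _ = call_culture_preferential(culture_mat, culture, config,
                                            genes=genes)
        shared = intersect_dual(pref, cbl_set)
        rows.append({"culture": culture, "n_preferential": len(pref),
                     "n_overlap_cbl": len(shared),
                     "overlap_genes": ",".join(shared)})
    return pd.DataFrame(rows, columns=["culture", "n_preferential",
                                       "n_overlap_cbl", "overlap_genes"])
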