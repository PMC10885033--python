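"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive each result from first principles (per-gene
arithmetic, exhaustive run enumeration, quadratic scans) and share no code
with the implementation they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# --- expression screen ------------------------------------------------------

def brute_universe(tissue_mat, culture_mat, annotation, floor=1.0,
                   whitelist=frozenset()):
    biotype = {g.gene_id: g.biotype for g in annotation}
    kept = []
    for gene in tissue_mat.gene_ids:
        if gene not in culture_mat.gene_ids or gene not in biotype:
            continue
        if biotype[gene] == "mito":
            continue
        if biotype[gene] != "protein_coding" and gene not in whitelist:
            continue
        if not any(v >= floor for v in tissue_mat.values.loc[gene]):
            continue
        if not any(v >= floor for v in culture_mat.values.loc[gene]):
            continue
        kept.append(gene)
    return kept


def brute_culture_pass(row, target, others, R=5.0, E=1.0):
    num = row[target]
    denom = sum(row[o] for o in others) / len(others)
    if denom == 0:
        return num > 0 and num >= E
    return num / denom >= R and num >= E


def brute_cerebellum_pass(row, cbl, brain, nonbrain, R=5.0, E=1.0,
                          brain_ct="median", nonbrain_ct="mean"):
    num = row[cbl]
    all_others = [s for s in row.index if s != cbl]
    strict_max = num > 0 and num > max(row[s] for s in all_others)

    def agg(samples, how):
        vals = sorted(row[s] for s in samples)
        if how == "mean":
            return sum(vals) / len(vals)
        mid = len(vals) // 2
        return (vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2)

    def criterion(denom):
        if denom == 0:
            return strict_max
        return num / denom >= R

    return (num >= E and criterion(agg(brain, brain_ct))
            and criterion(agg(nonbrain, nonbrain_ct)))


# --- DMR / LMR segmentation -------------------------------------------------

def brute_dmrs(pos, delta, threshold, min_cpgs, max_gap):
    """Enumerate all maximal qualifying runs by extension from each start."""
    pos, delta = list(pos), list(delta)
    n = len(pos)

    def qualifies(i, j):  # inclusive index range
        ds = delta[i:j + 1]
        if any(abs(d) < threshold for d in ds):
            return False
        if len({d > 0 for d in ds}) != 1:
            return False
        return all(pos[k + 1] - pos[k] <= max_gap for k in range(i, j))

    out = []
    for i in range(n):
        if not qualifies(i, i):
            continue
        if i > 0 and qualifies(i - 1, i):
            continue  # not a maximal start
        j = i
        while j + 1 < n and qualifies(i, j + 1):
            j += 1
        if j - i + 1 >= min_cpgs:
            out.append((pos[i], pos[j] + 1,
                        "hyper" if delta[i] > 0 else "hypo", j - i + 1,
                        sum(delta[i:j + 1]) / (j - i + 1)))
    return out


def brute_lmrs(pos, meth, baseline, ceiling, margin, min_run, max_gap):
    pos, meth = list(pos), list(meth)
    n = len(pos)

    def qualifies(i, j):
        if any(m > ceiling for m in meth[i:j + 1]):
            return False
        return all(pos[k + 1] - pos[k] <= max_gap for k in range(i, j))

    out = []
    for i in range(n):
        if not qualifies(i, i):
            continue
        if i > 0 and qualifies(i - 1, i):
            continue
        j = i
        while j + 1 < n and qualifies(i, j + 1):
            j += 1
        run = meth[i:j + 1]
        mean = sum(run) / len(run)
        if len(run) >= min_run and mean <= baseline - margin:
            out.append((pos[i], pos[j] + 1, len(run), mean))
    return out


def brute_delta(target_tracks, panel_tracks, min_coverage=0):
    """Per-position dict-based recomputation of the delta series."""
    def as_dict(track):
        out = {}
        for row in track.records.itertuples():
            cov_ok = (not track.has_coverage or min_coverage <= 0
                      or row.coverage >= min_coverage)
            if cov_ok:
                out[(row.chrom, row.pos)] = row.meth
        return out

    t_dicts = [as_dict(t) for t in target_tracks]
    p_dicts = [as_dict(p) for p in panel_tracks]
    common = set(t_dicts[0])
    for d in t_dicts[1:] + p_dicts:
        common &= set(d)
    return {key: (sum(d[key] for d in t_dicts) / len(t_dicts)
                  - sum(d[key] for d in p_dicts) / len(p_dicts))
            for key in common}


# --- intervals and percentages ---------------------------------------------

def brute_overlaps(queries, track):
    return [[iv for iv in track
             if iv[0] == q[0] and max(q[1], iv[1]) < min(q[2], iv[2])]
            for q in queries]


def brute_percent(num, den, decimals):
    """Round-half-up percentage via exact rational arithmetic."""
    scaled = Fraction(100 * num, den) * 10 ** decimals
    return float(math.floor(scaled + Fraction(1, 2))) / 10 ** decimals
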