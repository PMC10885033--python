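"""Domain types and file formats.

All genomic coordinates are 0-based half-open throughout the package.  The
single place where another convention enters is the GTF reader, which
converts 1-based closed intervals on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("TPM", "FPKM")
VALID_BIOTYPES = ("protein_coding", "ncRNA", "mito", "other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    Every sample must carry exactly one group label in ``group_map``.
    """

    values: pd.DataFrame
    unit_tag: str
    group_map: dict[str, str]

    def __post_init__(self) -> None:
        if self.unit_tag not in VALID_UNITS:
            raise ValueError(f"unit_tag must be one of {VALID_UNITS}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("missing expression values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.group_map)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_map[s] == group]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: half-open body interval, strand, biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"end <= start for {self.gene_id}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        """0-based transcription start: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MethylomeTrack:
    """Per-CpG methylation for one sample, ordered by (chrom, position).

    ``records`` columns: chrom, pos, meth, coverage.  Coverage is NaN when
    the source had no coverage column; coverage filtering is then disabled
    for this sample.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        expected = ["chrom", "pos", "meth", "coverage"]
        if list(r.columns) != expected:
            raise ValueError(f"records columns must be {expected}")
        if ((r["meth"] < 0) | (r["meth"] > 1)).any():
            raise ValueError("methylation fraction outside [0, 1]")
        for _, sub in r.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("positions not strictly increasing within chrom")

    @property
    def has_coverage(self) -> bool:
        return bool(self.records["coverage"].notna().all()) and len(self.records) > 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DMR:
    """Differentially methylated region: run of same-direction candidate CpGs."""

    chrom: str
    start: int
    end: int
    direction: str  # "hypo" | "hyper"
    n_cpgs: int
    mean_delta: float

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.end <= self.start:
            raise ValueError("end <= start")


@dataclass(frozen=True)
class LMR:
    """Low-methylated region relative to the genome-wide mean of one track."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_meth: float
    genome_baseline: float


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------

def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in group map")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in group_map.items():
            fh.write(f"{sample}\t{group}\n")


def read_expression_matrix(path: str | Path, unit_tag: str,
                           group_map_path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV plus its sample group map."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    values = df.astype(float)
    return ExpressionMatrix(values=values, unit_tag=unit_tag,
                            group_map=read_group_map(group_map_path))


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path,
                            group_map_path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene_id")
    write_group_map(mat.group_map, group_map_path)


# ---------------------------------------------------------------------------
# methylome I/O (bedGraph, 4-5 columns, one record per CpG cytosine)
# ---------------------------------------------------------------------------

def read_bedgraph_methylome(path: str | Path, sample_id: str) -> MethylomeTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] not in (4, 5):
        raise ValueError("bedGraph must have 4 or 5 columns")
    df.columns = ["chrom", "start", "end", "meth", "coverage"][: df.shape[1]]
    if (df["end"] != df["start"] + 1).any():
        raise ValueError("each bedGraph record must span a single CpG cytosine")
    records = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["start"].astype(int),
        "meth": df["meth"].astype(float),
        "coverage": df["coverage"].astype(float) if "coverage" in df else np.nan,
    })
    return MethylomeTrack(sample_id=sample_id, records=records)


def write_bedgraph_methylome(track: MethylomeTrack, path: str | Path) -> None:
    r = track.records
    out = pd.DataFrame({
        "chrom": r["chrom"],
        "start": r["pos"],
        "end": r["pos"] + 1,
        "meth": r["meth"],
    })
    if track.has_coverage:
        out["coverage"] = r["coverage"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read BED12 or minimal GTF gene annotation.

    GTF intervals (1-based closed) are converted to 0-based half-open here;
    this is the only conversion site in the package.  BED12 names may carry
    the biotype as ``gene_id|biotype``.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[3].isdigit():  # GTF
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                genes.append(GeneAnnotation(
                    gene_id=attrs["gene_id"],
                    chrom=fields[0],
                    start=int(fields[3]) - 1,   # 1-based closed -> 0-based half-open
                    end=int(fields[4]),
                    strand=fields[6],
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                ))
            elif len(fields) >= 6:  # BED6/BED12
                name, _, biotype = fields[3].partition("|")
                genes.append(GeneAnnotation(
                    gene_id=name,
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    biotype=biotype or "protein_coding",
                ))
            else:
                raise ValueError(f"unrecognized annotation line: {line!r}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in annotation")
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as minimal GTF (round-trips all fields)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write("\t".join([
                g.chrom, "episcreen", "gene",
                str(g.start + 1), str(g.end),  # back to 1-based closed
                ".", g.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# DMR / LMR / interval I/O
# ---------------------------------------------------------------------------

def write_dmrs_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """BED6 + n_cpgs, mean_delta, direction extra columns."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            score = min(1000, int(round(abs(d.mean_delta) * 1000)))
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), f"{d.direction}_{i}",
                str(score), ".", str(d.n_cpgs), f"{d.mean_delta:.6g}",
                d.direction,
            ]) + "\n")


def read_dmrs_bed(path: str | Path) -> list[DMR]:
    dmrs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            dmrs.append(DMR(chrom=f[0], start=int(f[1]), end=int(f[2]),
                            direction=f[8], n_cpgs=int(f[6]),
                            mean_delta=float(f[7])))
    return dmrs


def write_lmrs_bed(lmrs: Sequence[LMR], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(lmrs):
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), f"lmr_{i}",
                str(int(round(r.mean_meth * 1000))), ".",
                str(r.n_cpgs), f"{r.mean_meth:.6g}", f"{r.genome_baseline:.6g}",
            ]) + "\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Generic BED3+ reader for external overlap tracks."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Uniform TSV writer for report and call tables."""
    df.to_csv(path, sep="\t", index=index)
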