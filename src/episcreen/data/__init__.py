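"""Bundled example tables."""

from importlib import resources

import pandas as pd

from ..integrate import GeneEpigeneticSummary


def load_dual_gene_dmr_counts() -> pd.DataFrame:
    """Per-gene hypo/hyper DMR counts for the 20 dual-preferential example
    genes shipped with the package."""
    with resources.files(__package__).joinpath(
            "dual_gene_dmr_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def dual_gene_summaries() -> list[GeneEpigeneticSummary]:
    """The bundled counts as minimal summaries (no location information)."""
    df = load_dual_gene_dmr_counts()
    return [GeneEpigeneticSummary(gene_id=r.gene_id, n_hypo=int(r.n_hypo),
                                  n_hyper=int(r.n_hyper))
            for r in df.itertuples()]
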