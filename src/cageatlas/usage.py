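"""Alternate-promoter usage statistics and cell-type signature genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import atlas as catlas
from . import io as cio
from .enrichment import fisher_two_sided


@dataclass
class UsageSummary:
    """Atlas-wide TSS-per-gene distribution plus the >=k gene list."""

    per_gene: pd.Series  # gene_id -> number of TSS clusters
    mean_tss_per_gene: float
    genes_at_least_k: list[str]
    k: int
    histogram: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.histogram is None:
            self.histogram = self.per_gene.value_counts().sort_index()


def tss_per_gene(atlas_obj: catlas.Atlas, k: int = 10) -> UsageSummary:
    """TSS-count histogram over genes on an annotated, filtered atlas.

    Only promoter- and intragenic-class clusters carry a gene; every counted
    gene therefore has n_tss >= 1.
    """
    c = atlas_obj.clusters
    assigned = c[c["annotation_class"].isin(["promoter", "intragenic"])]
    per_gene = assigned.groupby("gene_id").size().sort_index()
    mean = float(per_gene.mean()) if len(per_gene) else 0.0
    ge_k = sorted(per_gene.index[per_gene >= k])
    return UsageSummary(
        per_gene=per_gene, mean_tss_per_gene=mean, genes_at_least_k=ge_k, k=k
    )


def usage_fisher(
    n_tss_sample: int, n_gene_sample: int, n_tss_atlas: int, n_gene_atlas: int
) -> float:
    """Two-sided Fisher p contrasting per-sample vs atlas TSS:gene counts.

    The 2x2 table is [[n_tss_sample, n_gene_sample],
    [n_tss_atlas - n_tss_sample, n_gene_atlas - n_gene_sample]]; sample
    counts must not exceed atlas counts.
    """
    for v in (n_tss_sample, n_gene_sample, n_tss_atlas, n_gene_atlas):
        if v <= 0:
            raise ValueError("all counts must be > 0")
    rest_tss = n_tss_atlas - n_tss_sample
    rest_gene = n_gene_atlas - n_gene_sample
    if rest_tss < 0 or rest_gene < 0:
        raise ValueError("sample counts exceed atlas counts")
    return fisher_two_sided([[n_tss_sample, n_gene_sample], [rest_tss, rest_gene]])


def per_sample_usage(atlas_obj: catlas.Atlas, min_tpm: float = 5.0) -> pd.DataFrame:
    """Per-sample expressed TSS/gene counts with the atlas-contrast Fisher p."""
    summary = tss_per_gene(atlas_obj)
    n_tss_atlas = int(summary.per_gene.sum())
    n_gene_atlas = int(len(summary.per_gene))
    table = catlas.per_sample_expressed(atlas_obj, min_tpm=min_tpm)
    ps = []
    for row in table.itertuples():
        if row.n_tss > 0 and row.n_genes > 0:
            ps.append(usage_fisher(row.n_tss, row.n_genes, n_tss_atlas, n_gene_atlas))
        else:
            ps.append(None)
    table = table.copy()
    table["fisher_p"] = ps
    return table


def gene_matrix(atlas_obj: catlas.Atlas) -> cio.ExpressionMatrix:
    """Gene-level TPM: sum of each gene's TSS-cluster TPMs."""
    if atlas_obj.tpm is None:
        raise ValueError("atlas needs TPM")
    c = atlas_obj.clusters
    assigned = c["annotation_class"].isin(["promoter", "intragenic"])
    gm = atlas_obj.tpm[assigned].groupby(c.loc[assigned, "gene_id"]).sum()
    return cio.ExpressionMatrix(values=gm, units="tpm")


def signature_genes(
    matrix: cio.ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    fold: float = 4.0,
    min_tpm: float = 5.0,
) -> dict[str, dict[str, list[str]]]:
    """Per cell type, genes specifically up- or down-regulated.

    up in T: mean(T) >= fold * mean(rest) and mean(T) >= min_tpm;
    down in T: mean(T) <= mean(rest) / fold and mean(rest) >= min_tpm.
    Means are over that cell type's replicate samples.  fold > 1 guarantees a
    gene is never both up and down in the same type.
    """
    if matrix.units != "tpm":
        raise ValueError("signature calling expects a TPM matrix")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    values = matrix.values
    out: dict[str, dict[str, list[str]]] = {}
    for cell_type, grp in sample_sheet.groupby("cell_type"):
        samples = [s for s in grp["sample_id"] if s in values.columns]
        if len(samples) < 2:
            warnings.warn(f"cell type {cell_type!r} has < 2 replicates")
        rest = [s for s in values.columns if s not in samples]
        mean_t = values[samples].mean(axis=1)
        mean_rest = values[rest].mean(axis=1)
        up = values.index[(mean_t >= fold * mean_rest) & (mean_t >= min_tpm)]
        down = values.index[(mean_t <= mean_rest / fold) & (mean_rest >= min_tpm)]
        out[cell_type] = {"up": sorted(up), "down": sorted(down)}
    return out
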