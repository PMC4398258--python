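"""Multi-sample TSS atlas: tag clustering, TPM normalisation, filtering and
annotation against gene models.

Tag clustering is single-linkage over pooled tag positions per (chromosome,
strand): two positions join the same cluster iff their coordinate gap is at
most ``max_gap``.  This is a deliberate, documented substitution for
decomposition-based peak calling — it is deterministic and directly testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import io as cio

PROMOTER_WINDOW = 500  # bp around a transcript 5' end

CLUSTER_COLUMNS = [
    "chrom", "start", "end", "strand", "summit",
    "annotation_class", "gene_id", "distance_to_5p",
]


@dataclass
class Atlas:
    """TSS regions with per-sample expression.

    ``clusters`` is indexed by cluster id with the columns in
    :data:`CLUSTER_COLUMNS`; ``counts`` and ``tpm`` are cluster x sample
    frames sharing that index.
    """

    clusters: pd.DataFrame
    counts: pd.DataFrame
    tpm: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __len__(self) -> int:
        return len(self.clusters)

    def subset(self, ids) -> "Atlas":
        ids = list(ids)
        return Atlas(
            clusters=self.clusters.loc[ids],
            counts=self.counts.loc[ids],
            tpm=None if self.tpm is None else self.tpm.loc[ids],
            library_sizes=self.library_sizes,
        )


def cluster_tags(tracks: list[cio.CtssTrack], max_gap: int = 20) -> Atlas:
    """Single-linkage clustering of pooled tag positions.

    Clusters never span strands or chromosomes; per-sample counts are summed
    within a cluster; the summit is the position with the highest pooled
    count (smallest coordinate on ties).  Empty input yields an empty atlas.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not tracks:
        return Atlas(
            clusters=pd.DataFrame(columns=CLUSTER_COLUMNS),
            counts=pd.DataFrame(),
        )
    frames = []
    for track in tracks:
        df = track.data.copy()
        df["sample"] = track.sample_id
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    sample_ids = [t.sample_id for t in tracks]

    cluster_rows = []
    count_blocks = []
    cid = 0
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        per_pos = grp.groupby("pos")["count"].sum().sort_index()
        positions = per_pos.index.to_numpy()
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        segments = np.split(np.arange(len(positions)), breaks)
        pos_to_cluster = np.empty(len(positions), dtype=int)
        seg_meta = []
        for seg in segments:
            seg_pos = positions[seg]
            seg_counts = per_pos.to_numpy()[seg]
            summit = int(seg_pos[int(np.argmax(seg_counts))])
            seg_meta.append((int(seg_pos[0]), int(seg_pos[-1]) + 1, summit))
            pos_to_cluster[seg] = len(seg_meta) - 1
        pos_index = pd.Series(pos_to_cluster, index=positions)
        grp = grp.assign(_seg=pos_index.loc[grp["pos"]].to_numpy())
        mat = (
            grp.pivot_table(index="_seg", columns="sample", values="count",
                            aggfunc="sum", fill_value=0)
            .reindex(index=range(len(seg_meta)), columns=sample_ids, fill_value=0)
        )
        for i, (start, end, summit) in enumerate(seg_meta):
            cluster_rows.append(
                {"cluster_id": f"TC{cid:06d}", "chrom": chrom, "start": start,
                 "end": end, "strand": strand, "summit": summit,
                 "annotation_class": None, "gene_id": None, "distance_to_5p": None}
            )
            cid += 1
        count_blocks.append(mat.to_numpy())
    clusters = pd.DataFrame(cluster_rows).set_index("cluster_id")
    counts = pd.DataFrame(
        np.vstack(count_blocks), index=clusters.index, columns=sample_ids
    )
    # stable genome order
    order = clusters.sort_values(["chrom", "start", "strand"], kind="mergesort").index
    return Atlas(clusters=clusters.loc[order], counts=counts.loc[order])


def normalize_tpm(atlas: Atlas, library_sizes) -> Atlas:
    """Attach TPM = count * 1e6 / library_size.

    ``library_sizes`` maps sample id to the *full-track* mapped-tag total,
    not the within-atlas total.  Zero library sizes are an error.
    """
    sizes = pd.Series(library_sizes, dtype=float).reindex(atlas.sample_ids)
    if sizes.isna().any():
        missing = sizes[sizes.isna()].index.tolist()
        raise ValueError(f"missing library sizes for samples {missing}")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    tpm = atlas.counts * 1e6 / sizes
    return replace(atlas, tpm=tpm, library_sizes=sizes)


def filter_expressed(atlas: Atlas, min_tpm: float = 5.0) -> Atlas:
    """Keep clusters whose maximum TPM over samples is >= min_tpm (inclusive)."""
    if atlas.tpm is None:
        raise ValueError("TPM not computed; call normalize_tpm first")
    keep = atlas.tpm.max(axis=1) >= min_tpm
    return atlas.subset(atlas.clusters.index[keep])


def annotate_tss(atlas: Atlas, models: cio.GeneModels) -> Atlas:
    """Assign each cluster exactly one class: promoter, intragenic, intergenic.

    promoter: summit within 500 bp of a same-strand transcript 5' end
    (nearest wins, ties to the lexicographically smaller gene_id);
    intragenic: summit inside a same-strand gene body; else intergenic.
    The signed distance is positive downstream of the 5' end.
    """
    tx = models.transcripts
    genes = models.genes
    cls_out, gene_out, dist_out = [], [], []
    tx_by = {k: g for k, g in tx.groupby(["chrom", "strand"], sort=False)}
    genes_by = {k: g for k, g in genes.groupby(["chrom", "strand"], sort=False)}
    for row in atlas.clusters.itertuples():
        summit, strand, chrom = row.summit, row.strand, row.chrom
        best = None  # (abs_dist, gene_id, signed_dist)
        cand = tx_by.get((chrom, strand))
        if cand is not None:
            d = summit - cand["tss5p"].to_numpy()
            if strand == "-":
                d = -d
            absd = np.abs(d)
            within = absd <= PROMOTER_WINDOW
            if within.any():
                sub = cand[within]
                order = sorted(
                    zip(absd[within], sub["gene_id"], d[within]),
                    key=lambda t: (t[0], t[1]),
                )
                best = order[0]
        if best is not None:
            cls_out.append("promoter")
            gene_out.append(best[1])
            dist_out.append(int(best[2]))
            continue
        body = genes_by.get((chrom, strand))
        hit = None
        if body is not None:
            inside = (body["start"] <= summit) & (summit < body["end"])
            if inside.any():
                hit = sorted(body.loc[inside, "gene_id"])[0]
        if hit is not None:
            cls_out.append("intragenic")
            gene_out.append(hit)
            dist_out.append(None)
        else:
            cls_out.append("intergenic")
            gene_out.append(None)
            dist_out.append(None)
    clusters = atlas.clusters.copy()
    clusters["annotation_class"] = cls_out
    clusters["gene_id"] = gene_out
    clusters["distance_to_5p"] = dist_out
    return replace(atlas, clusters=clusters)


def per_sample_expressed(atlas: Atlas, min_tpm: float = 5.0) -> pd.DataFrame:
    """Per-sample expressed gene-assigned TSS and gene counts with their ratio.

    Counts clusters of class promoter/intragenic at >= min_tpm in the sample
    and the distinct genes among them; ratio is None when no genes are
    expressed.
    """
    if atlas.tpm is None:
        raise ValueError("TPM not computed")
    gene_assigned = atlas.clusters["annotation_class"].isin(["promoter", "intragenic"])
    rows = []
    for sample in atlas.sample_ids:
        expressed = (atlas.tpm[sample] >= min_tpm) & gene_assigned
        n_tss = int(expressed.sum())
        n_genes = atlas.clusters.loc[expressed, "gene_id"].nunique()
        ratio = (n_tss / n_genes) if n_genes else None
        rows.append({"sample_id": sample, "n_tss": n_tss, "n_genes": n_genes, "ratio": ratio})
    return pd.DataFrame(rows).set_index("sample_id")


def overlap_noncoding(atlas: Atlas, noncoding: pd.DataFrame) -> Atlas:
    """Intergenic-class clusters overlapping >= 1 bp of any noncoding interval.

    Strand-agnostic; ``noncoding`` is a BED frame as from :func:`io.read_bed`.
    """
    intergenic = atlas.clusters[atlas.clusters["annotation_class"] == "intergenic"]
    if len(intergenic) == 0 or len(noncoding) == 0:
        return atlas.subset([])
    keep = []
    by_chrom = {c: g for c, g in noncoding.groupby("chrom", sort=False)}
    for row in intergenic.itertuples():
        ivs = by_chrom.get(row.chrom)
        if ivs is None:
            continue
        if ((ivs["start"] < row.end) & (row.start < ivs["end"])).any():
            keep.append(row.Index)
    return atlas.subset(keep)


def lookup(atlas: Atlas, chrom: str, pos: int, strand: str) -> str | None:
    """Cluster id whose interval covers (chrom, pos, strand), or None."""
    c = atlas.clusters
    hit = c[(c["chrom"] == chrom) & (c["strand"] == strand)
            & (c["start"] <= pos) & (pos < c["end"])]
    if len(hit) == 0:
        return None
    return hit.index[0]


def match_positions(atlas: Atlas, catalog: dict[str, tuple[str, int, str]]) -> dict[str, str | None]:
    """Map ids of known (chrom, summit, strand) positions to atlas clusters.

    Vectorised variant of :func:`lookup` for truth-table style catalogs.
    """
    out: dict[str, str | None] = {}
    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, grp in atlas.clusters.groupby(["chrom", "strand"], sort=False):
        grp = grp.sort_values("start", kind="mergesort")
        by_key[key] = (
            grp["start"].to_numpy(), grp["end"].to_numpy(), grp.index.to_numpy()
        )
    for tss_id, (chrom, summit, strand) in catalog.items():
        entry = by_key.get((chrom, strand))
        if entry is None:
            out[tss_id] = None
            continue
        starts, ends, ids = entry
        i = np.searchsorted(starts, summit, side="right") - 1
        if i >= 0 and summit < ends[i]:
            out[tss_id] = ids[i]
        else:
            out[tss_id] = None
    return out


# ---------------------------------------------------------------------------
# serialisation


def write_atlas(atlas: Atlas, path) -> None:
    """One TSV: cluster columns plus count:<sample> and tpm:<sample> columns.

    Library sizes travel in a ``#library_sizes=`` header comment so the file
    round-trips through :func:`read_atlas`.
    """
    df = atlas.clusters.copy()
    for s in atlas.sample_ids:
        df[f"count:{s}"] = atlas.counts[s]
    if atlas.tpm is not None:
        for s in atlas.sample_ids:
            df[f"tpm:{s}"] = atlas.tpm[s]
    with open(path, "w") as fh:
        if atlas.library_sizes is not None:
            sizes = {k: int(v) for k, v in atlas.library_sizes.items()}
            fh.write(f"#library_sizes={json.dumps(sizes, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index_label="cluster_id")


def read_atlas(path) -> Atlas:
    library_sizes = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#library_sizes="):
            library_sizes = pd.Series(json.loads(first.split("=", 1)[1]), dtype=float)
            df = pd.read_csv(fh, sep="\t", index_col="cluster_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="cluster_id")
    count_cols = [c for c in df.columns if c.startswith("count:")]
    tpm_cols = [c for c in df.columns if c.startswith("tpm:")]
    clusters = df[CLUSTER_COLUMNS].copy()
    clusters["gene_id"] = clusters["gene_id"].where(clusters["gene_id"].notna(), None)
    counts = df[count_cols].rename(columns=lambda c: c.split(":", 1)[1])
    tpm = None
    if tpm_cols:
        tpm = df[tpm_cols].rename(columns=lambda c: c.split(":", 1)[1])
    return Atlas(clusters=clusters, counts=counts, tpm=tpm, library_sizes=library_sizes)


def cluster_bed(atlas: Atlas) -> pd.DataFrame:
    """BED6 frame of cluster intervals (score = pooled tag count)."""
    c = atlas.clusters
    return pd.DataFrame(
        {
            "chrom": c["chrom"],
            "start": c["start"],
            "end": c["end"],
            "name": c.index,
            "score": atlas.counts.sum(axis=1).astype(int),
            "strand": c["strand"],
        }
    )
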