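"""Bidirectional-transcription enhancer calling, cell-type restriction and
coexpression-based gene linking.

A candidate is a divergent pair: a reverse-strand cluster whose summit lies
left of a forward-strand cluster summit, separated by at most
``pair_window`` bp.  The pooled directionality score D = (F - R) / (F + R)
over all samples must satisfy |D| <= ``balance`` (inclusive), the pair must
be expressed at >= ``min_tpm`` pooled TPM in at least one sample, and the
spanned region may touch neither a gene body nor a promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas as catlas
from . import io as cio

PROMOTER_WINDOW = catlas.PROMOTER_WINDOW


@dataclass
class EnhancerCall:
    region: cio.GenomicInterval
    center: int
    fwd_cluster: str
    rev_cluster: str
    directionality: float
    per_sample_tpm: pd.Series
    restricted_to: str | None = None
    linked_genes: list[tuple[str, float]] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.region.chrom}:{self.region.start}-{self.region.end}"


def _genic_exclusion_mask(models: cio.GeneModels):
    """Per-chromosome arrays of forbidden intervals (bodies + promoter pads)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in models.genes.itertuples():
        spans.setdefault(g.chrom, []).append((g.start, g.end))
    for t in models.transcripts.itertuples():
        spans.setdefault(t.chrom, []).append(
            (max(0, t.tss5p - PROMOTER_WINDOW), t.tss5p + PROMOTER_WINDOW + 1)
        )
    out = {}
    for chrom, ivs in spans.items():
        arr = np.array(sorted(ivs))
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def call_enhancers(
    atlas_obj: catlas.Atlas,
    models: cio.GeneModels,
    pair_window: int = 400,
    balance: float = 0.8,
    min_tpm: float = 2.0,
) -> list[EnhancerCall]:
    """Call balanced divergent cluster pairs at non-genic loci.

    Overlapping candidates are resolved greedily in favour of the pair with
    the highest total pooled TPM; output order follows genomic coordinates
    and is invariant to sample and chromosome processing order.
    """
    if atlas_obj.tpm is None:
        raise ValueError("atlas needs TPM; call normalize_tpm first")
    clusters = atlas_obj.clusters
    forbidden = _genic_exclusion_mask(models)
    pooled = atlas_obj.counts.sum(axis=1)

    candidates = []
    for chrom in sorted(clusters["chrom"].unique()):
        sub = clusters[clusters["chrom"] == chrom]
        minus = sub[sub["strand"] == "-"].sort_values("summit", kind="mergesort")
        plus = sub[sub["strand"] == "+"].sort_values("summit", kind="mergesort")
        if len(minus) == 0 or len(plus) == 0:
            continue
        plus_summits = plus["summit"].to_numpy()
        chrom_forbidden = forbidden.get(chrom)
        for rev in minus.itertuples():
            lo = np.searchsorted(plus_summits, rev.summit, side="right")
            hi = np.searchsorted(plus_summits, rev.summit + pair_window, side="right")
            for j in range(lo, hi):
                fwd = plus.iloc[j]
                start = min(rev.start, int(fwd["start"]))
                end = max(rev.end, int(fwd["end"]))
                if chrom_forbidden is not None:
                    starts, ends = chrom_forbidden
                    if bool(((starts < end) & (start < ends)).any()):
                        continue
                F = float(pooled[fwd.name])
                R = float(pooled[rev.Index])
                if F + R == 0:
                    continue
                D = (F - R) / (F + R)
                if abs(D) > balance + 1e-12:
                    continue
                tpm = atlas_obj.tpm.loc[fwd.name] + atlas_obj.tpm.loc[rev.Index]
                if tpm.max() < min_tpm:
                    continue
                candidates.append(
                    EnhancerCall(
                        region=cio.GenomicInterval(chrom, start, end, "."),
                        center=(rev.summit + int(fwd["summit"])) // 2,
                        fwd_cluster=fwd.name,
                        rev_cluster=rev.Index,
                        directionality=D,
                        per_sample_tpm=tpm,
                    )
                )

    # greedy overlap resolution: highest pooled expression wins
    candidates.sort(
        key=lambda c: (-float(c.per_sample_tpm.sum()), c.region.chrom, c.region.start)
    )
    kept: list[EnhancerCall] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    used_clusters: set[str] = set()
    for cand in candidates:
        if cand.fwd_cluster in used_clusters or cand.rev_cluster in used_clusters:
            continue
        spans = occupied.setdefault(cand.region.chrom, [])
        if any(s < cand.region.end and cand.region.start < e for s, e in spans):
            continue
        spans.append((cand.region.start, cand.region.end))
        used_clusters.update((cand.fwd_cluster, cand.rev_cluster))
        kept.append(cand)
    kept.sort(key=lambda c: (c.region.chrom, c.region.start))
    return kept


def restriction_call(
    per_sample_tpm: pd.Series,
    sample_sheet: pd.DataFrame,
    on_tpm: float = 5.0,
    off_tpm: float = 1.0,
) -> str | None:
    """Cell type the expression is restricted to, or None.

    Restricted to T iff the replicate-mean TPM in T is >= on_tpm and the
    mean in every other cell type is < off_tpm; None when zero or multiple
    types qualify.
    """
    means = {}
    for cell_type, grp in sample_sheet.groupby("cell_type"):
        samples = [s for s in grp["sample_id"] if s in per_sample_tpm.index]
        means[cell_type] = float(per_sample_tpm[samples].mean()) if samples else 0.0
    qualifying = [
        t for t, m in means.items()
        if m >= on_tpm and all(o < off_tpm for u, o in means.items() if u != t)
    ]
    return qualifying[0] if len(qualifying) == 1 else None


def link_genes(
    call: EnhancerCall,
    atlas_obj: catlas.Atlas,
    max_dist: int = 500_000,
    min_r: float = 0.7,
) -> list[tuple[str, float]]:
    """Link promoter TSSs within ``max_dist`` of the enhancer by coexpression.

    Pearson r between log2(TPM+1) profiles; zero-variance profiles are
    skipped.  Returns (gene_id, r) sorted by r descending; at most one entry
    per gene (its best-correlated promoter).
    """
    if atlas_obj.tpm is None:
        raise ValueError("atlas needs TPM")
    if atlas_obj.tpm.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    enh_profile = np.log2(call.per_sample_tpm.to_numpy(dtype=float) + 1.0)
    if enh_profile.std() == 0:
        return []
    c = atlas_obj.clusters
    promoters = c[
        (c["annotation_class"] == "promoter")
        & (c["chrom"] == call.region.chrom)
        & ((c["summit"] - call.center).abs() <= max_dist)
    ]
    best: dict[str, float] = {}
    for cid, row in promoters.iterrows():
        profile = np.log2(atlas_obj.tpm.loc[cid].to_numpy(dtype=float) + 1.0)
        if profile.std() == 0:
            continue
        r = float(np.corrcoef(enh_profile, profile)[0, 1])
        if r >= min_r:
            gene = row["gene_id"]
            if gene not in best or r > best[gene]:
                best[gene] = r
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def annotate_calls(
    calls: list[EnhancerCall],
    atlas_obj: catlas.Atlas,
    sample_sheet: pd.DataFrame,
    on_tpm: float = 5.0,
    off_tpm: float = 1.0,
    max_dist: int = 500_000,
    min_r: float = 0.7,
) -> list[EnhancerCall]:
    """Fill restriction and linked-gene fields on each call, in place."""
    for call in calls:
        call.restricted_to = restriction_call(
            call.per_sample_tpm, sample_sheet, on_tpm=on_tpm, off_tpm=off_tpm
        )
        call.linked_genes = link_genes(call, atlas_obj, max_dist=max_dist, min_r=min_r)
    return calls


def calls_frame(calls: list[EnhancerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "center": c.center,
                "fwd_cluster": c.fwd_cluster,
                "rev_cluster": c.rev_cluster,
                "directionality": c.directionality,
                "mean_tpm": float(c.per_sample_tpm.mean()),
                "restricted_to": c.restricted_to or ".",
                "linked_genes": ";".join(f"{g}:{r:.3f}" for g, r in c.linked_genes) or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "center", "fwd_cluster", "rev_cluster",
            "directionality", "mean_tpm", "restricted_to", "linked_genes",
        ],
    )


def calls_bed(calls: list[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.region.chrom for c in calls],
            "start": [c.region.start for c in calls],
            "end": [c.region.end for c in calls],
            "name": [c.name for c in calls],
            "score": [round(float(c.per_sample_tpm.mean()), 3) for c in calls],
            "strand": ["." for c in calls],
        }
    )
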