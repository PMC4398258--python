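"""Cis-regulatory motif scanning and hypergeometric enrichment with FDR.

The PWM scanner computes log2-odds scores on both strands and calls a hit
when the score reaches ``score_fraction`` of the maximum attainable score.
Enrichment of a TSS set against the filtered atlas background uses the
upper-tail hypergeometric test with Benjamini-Hochberg correction across the
terms tested in one call.

Numerical note: the upper tail is computed by summing pmf terms rather than
as ``1 - cdf`` so that very small p-values keep full relative precision; the
two-sided Fisher test in :mod:`cageatlas.usage` shares this machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import atlas as catlas
from . import io as cio

#: relative tolerance when comparing pmf values for the two-sided Fisher
#: tie rule (same convention as R's fisher.test)
FISHER_TIE_RTOL = 1e-7

_CODE = np.full(256, 4, dtype=np.int8)  # 4 = N / anything else
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


@dataclass
class EnrichmentResult:
    term: str
    k: int  # foreground hits
    n: int  # foreground size
    K: int  # background hits
    N: int  # background size
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"inconsistent counts k={self.k}, n={self.n}, K={self.K}")
        if not (self.n <= self.N and self.K <= self.N):
            raise ValueError("foreground/term larger than background")


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _score_profile(codes: np.ndarray, pwm: cio.Pwm) -> np.ndarray:
    """Log2-odds score at every offset; N bases contribute 0."""
    L = pwm.width
    if len(codes) < L:
        return np.zeros(0)
    lo = np.vstack([pwm.log_odds(), np.zeros(pwm.width)])  # 5th row for N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def scan_pwm(
    sequence: str, pwm: cio.Pwm, score_fraction: float = 0.8
) -> list[tuple[int, str, float]]:
    """All (position, strand, score) hits of ``pwm`` in ``sequence``.

    A hit requires score >= score_fraction * max attainable score.  Reverse
    strand hits score the reverse complement and are reported at the forward
    coordinate of the motif's left edge.  Sequences shorter than the motif
    yield no hits.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    codes = encode_sequence(sequence)
    threshold = score_fraction * pwm.max_score()
    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _score_profile(codes, mat)
        for i in np.flatnonzero(scores >= threshold - 1e-12):
            hits.append((int(i), strand, float(scores[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# hypergeometric machinery


def hypergeom_pvals_all_k(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """Upper-tail p for every feasible k at fixed (N, K, n).

    Returns (k_min, p_array) with p_array[j] = P(X >= k_min + j).  Summation
    is over pmf terms (not 1 - cdf) for relative accuracy at tiny p.
    """
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, N, K, n)
    tails = np.cumsum(pmf[::-1])[::-1]
    return k_min, np.minimum(tails, 1.0)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    k_min, tails = hypergeom_pvals_all_k(N, K, n)
    idx = max(k - k_min, 0)
    if idx >= len(tails):
        return 0.0
    return float(tails[idx])


def fisher_pvals_all_k(N: int, K: int, n: int, rtol: float = FISHER_TIE_RTOL) -> tuple[int, np.ndarray]:
    """Two-sided Fisher p for every feasible top-left cell at fixed margins.

    p(k) sums hypergeometric probabilities of all tables no more probable
    than the observed one, with a relative tie tolerance on the comparison.
    """
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, N, K, n)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # rank of each pmf value among sorted values, inclusive of near-ties
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + rtol), side="right")
    pvals = np.minimum(csum[np.maximum(idx - 1, 0)], 1.0)
    pvals[idx == 0] = 0.0  # cannot happen: own pmf always included
    return k_min, pvals


def fisher_two_sided(table, rtol: float = FISHER_TIE_RTOL) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]]."""
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    K = a + b  # row-1 margin
    n = a + c  # col-1 margin
    k_min, pvals = fisher_pvals_all_k(N, K, n, rtol=rtol)
    return float(pvals[a - k_min])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def hypergeom_enrich(
    foreground: set, background: set, term_sets: dict[str, set]
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the foreground.

    Terms are intersected with the background; q-values are BH-adjusted over
    all terms tested in this call.  An empty foreground is an error.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    N = len(background)
    n = len(foreground)
    results = []
    for term, ids in sorted(term_sets.items()):
        marked = set(ids) & background
        K = len(marked)
        k = len(marked & foreground)
        p = hypergeom_tail(k, N, K, n)
        results.append(EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p=p))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# atlas-level wrappers


def summit_window_sequence(
    atlas_obj: catlas.Atlas, genome: dict[str, str], cluster_id: str, window: int = 300
) -> str:
    """Genomic sequence of summit +/- window, truncated at chromosome edges."""
    row = atlas_obj.clusters.loc[cluster_id]
    seq = genome[row["chrom"]]
    lo = max(0, int(row["summit"]) - window)
    hi = min(len(seq), int(row["summit"]) + window + 1)
    return seq[lo:hi]


def scan_atlas(
    atlas_obj: catlas.Atlas,
    genome: dict[str, str],
    pwms: list[cio.Pwm],
    window: int = 300,
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Boolean cluster x motif table: does the summit window contain a hit."""
    out = np.zeros((len(atlas_obj.clusters), len(pwms)), dtype=bool)
    for i, cid in enumerate(atlas_obj.clusters.index):
        seq = summit_window_sequence(atlas_obj, genome, cid, window=window)
        for j, pwm in enumerate(pwms):
            out[i, j] = bool(scan_pwm(seq, pwm, score_fraction=score_fraction))
    return pd.DataFrame(out, index=atlas_obj.clusters.index, columns=[p.id for p in pwms])


def motif_enrich(
    cluster: set,
    atlas_obj: catlas.Atlas,
    genome: dict[str, str],
    pwms: list[cio.Pwm],
    window: int = 300,
    score_fraction: float = 0.8,
    hit_table: pd.DataFrame | None = None,
) -> list[EnrichmentResult]:
    """Motif enrichment of a TSS cluster against the whole-atlas background.

    A TSS is in a motif's term set iff its summit +/- window sequence has at
    least one hit.  ``hit_table`` may carry a precomputed :func:`scan_atlas`
    result to amortise scanning across many clusters.
    """
    if hit_table is None:
        hit_table = scan_atlas(atlas_obj, genome, pwms, window=window,
                               score_fraction=score_fraction)
    background = set(hit_table.index)
    term_sets = {m: set(hit_table.index[hit_table[m]]) for m in hit_table.columns}
    return hypergeom_enrich(set(cluster), background, term_sets)


def overlap_enrich(
    cluster: set,
    atlas_obj: catlas.Atlas,
    peak_sets: dict[str, pd.DataFrame],
    window: int = 300,
) -> list[EnrichmentResult]:
    """Peak-overlap enrichment: summit +/- window vs each factor's intervals."""
    c = atlas_obj.clusters
    term_sets: dict[str, set] = {}
    for factor, peaks in sorted(peak_sets.items()):
        members = set()
        by_chrom = {ch: g for ch, g in peaks.groupby("chrom", sort=False)}
        for cid, row in c.iterrows():
            ivs = by_chrom.get(row["chrom"])
            if ivs is None:
                continue
            lo, hi = row["summit"] - window, row["summit"] + window + 1
            if ((ivs["start"] < hi) & (lo < ivs["end"])).any():
                members.add(cid)
        term_sets[factor] = members
    return hypergeom_enrich(set(cluster), set(c.index), term_sets)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q}
            for r in results
        ]
    )
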