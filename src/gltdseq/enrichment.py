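"""Pi-value gene ranking and permutation gene-set enrichment analysis.

Genes are ranked by the pi-value, log2(fold change) x -log10(adjusted p),
which retains both effect direction and significance.  Enrichment of a
gene set in the ranked list is the weighted Kolmogorov-Smirnov running-sum
statistic: walking down the list, set members ("hits") increment the sum
by |score|^w normalized over hits, non-members decrement by 1/(N - N_hits);
the enrichment score (ES) is the signed extremum of the running sum.  The
null is gene-label permutation: random same-size subsets of the ranked
universe.  The permutation p-value is one-tailed against same-sign null
scores with a plus-one correction, the normalized ES divides by the mean
|null ES| of the same sign, and Benjamini-Hochberg correction is applied
across the retained sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .diffexpr import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "pi_value",
    "rank_genes",
    "enrichment_score",
    "gsea",
]

PADJ_FLOOR = 1e-300


def pi_value(log2fc, padj, floor: float = PADJ_FLOOR, clamp: bool = True):
    """pi = log2fc x -log10(padj).  Sign follows the fold change.

    Adjusted p-values of exactly 0 (which occur in exported DE tables)
    are clamped to ``floor`` unless ``clamp`` is disabled, in which case
    they are rejected.
    """
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(padj, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("padj must lie in [0, 1]")
    if clamp:
        p = np.maximum(p, floor)
    elif np.any(p <= 0):
        raise ValueError("padj of 0 with clamping disabled")
    out = lfc * (-np.log10(p))
    return out if out.ndim else float(out)


def rank_genes(de: pd.DataFrame) -> pd.DataFrame:
    """Rank all genes by pi-value, descending; ties broken by gene id.

    Returns a DataFrame with gene_id, pi_value and rank (1 = largest).
    """
    if de["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in DE table")
    pi = pi_value(de["log2fc"].to_numpy(), de["padj"].to_numpy())
    ranked = pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "pi_value": pi})
    order = np.lexsort((ranked["gene_id"].to_numpy(), -ranked["pi_value"].to_numpy()))
    ranked = ranked.iloc[order].reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float):
    """Full running-sum profile over the ranked list (O(N))."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must be a nonempty proper subset of the universe")
    w = np.abs(scores) ** weight_exponent
    hit_total = w[hit_mask].sum()
    if hit_total == 0:
        # all hit scores are zero: fall back to unweighted increments
        steps = np.where(hit_mask, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        steps = np.where(hit_mask, w / hit_total, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Signed extremum of the running sum, with the full profile.

    ``scores`` must already be in ranked (descending) order; ``hit_mask``
    flags the set members.  Ties between the positive and negative
    extremum break toward the positive deviation.
    """
    profile = _running_sum(np.asarray(scores, float), np.asarray(hit_mask, bool),
                           weight_exponent)
    return _signed_extremum(profile.max(), profile.min()), profile


_TIE_TOL = 1e-12


def _signed_extremum(hi: float, lo: float) -> float:
    """Extremum with larger |value|; exact ties break toward the positive."""
    if hi - (-lo) < -_TIE_TOL:
        return float(lo)
    return float(hi)


def _es_from_positions(
    positions: np.ndarray, w_all: np.ndarray, n: int, weight_exponent: float
) -> float:
    """ES from sorted hit positions only (O(k)); w_all = |score|^w per rank."""
    k = positions.size
    w = w_all[positions]
    total = w.sum()
    miss = 1.0 / (n - k)
    if total == 0:
        inc = np.full(k, 1.0 / k)
    else:
        inc = w / total
    cum_hit = np.cumsum(inc)
    # running sum just after hit i (0-based): cum_hit[i] - (pos_i - i) * miss
    misses_before = positions - np.arange(k)
    after = cum_hit - misses_before * miss
    before = np.concatenate(([0.0], cum_hit[:-1])) - misses_before * miss
    return _signed_extremum(after.max(), before.min())


def gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    min_size: int = 1,
    max_size: int = 5000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of every retained gene set against a ranked list.

    Sets are intersected with the ranked universe and kept when the
    intersection size lies in [min_size, max_size].  The null for a set of
    size k is the ES of ``n_perm`` uniformly drawn k-subsets of the
    universe.  p = (1 + #{same-sign null with |ES| >= |ES_obs|}) /
    (1 + #{same-sign null}); NES = ES / mean(|same-sign null ES|); BH
    correction across retained sets.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gene_ids = ranked["gene_id"].to_numpy()
    scores = ranked["pi_value"].to_numpy(dtype=float)
    n = gene_ids.size
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    w_all = np.abs(scores) ** weight_exponent
    retained: list[tuple[str, np.ndarray]] = []
    for name, members in sets:
        positions = np.array(sorted(pos_of[g] for g in members if g in pos_of), dtype=int)
        if positions.size == 0:
            import warnings

            warnings.warn(f"gene set {name!r} does not intersect the ranked universe")
            continue
        if positions.size >= n:
            raise ValueError(f"gene set {name!r} covers the whole universe")
        if min_size <= positions.size <= max_size:
            retained.append((name, positions))
    if not retained:
        raise ValueError("no gene sets retained after the size filter")
    rng = substream(seed, "gsea")
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, positions in sorted(retained, key=lambda t: t[0]):
        k = positions.size
        es, profile = enrichment_score(scores, _mask(n, positions), weight_exponent)
        if k not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                perm = np.sort(rng.choice(n, size=k, replace=False))
                null[i] = _es_from_positions(perm, w_all, n, weight_exponent)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pvalue = (1 + extreme) / (1 + n_same)
        mean_same = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / mean_same if n_same else np.nan
        extremum = int(np.argmax(profile) if es >= 0 else np.argmin(profile))
        leading = [gene_ids[p] for p in positions if p <= extremum]
        rows.append(
            {
                "set_name": name,
                "set_size_used": k,
                "es": es,
                "nes": nes,
                "pvalue": pvalue,
                "leading_edge": leading,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = np.maximum(bh_adjust(out["pvalue"].to_numpy()), out["pvalue"])
    return out[["set_name", "set_size_used", "es", "nes", "pvalue", "padj", "leading_edge"]]


def _mask(n: int, positions: np.ndarray) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[positions] = True
    return m
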