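"""Cross-cohort comparability: profile correlations, directionality, overlap.

These metrics quantify how well two independently processed cohorts
agree: pairwise Pearson correlations of log-normalized expression
profiles within and between cohorts, the fraction of genes whose fold
changes point the same way in both cohorts (with an exact binomial test
against the chance level of 0.5), and the inclusion-exclusion overlap of
differentially-expressed-gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix
from .normalize import median_of_ratios

__all__ = [
    "CorrelationSummary",
    "profile_correlations",
    "directionality_consistency",
    "overlap_analysis",
]


@dataclass
class CorrelationSummary:
    within_a_mean: float
    within_a_sd: float
    within_b_mean: float
    within_b_sd: float
    between_mean: float
    between_sd: float
    pct_difference: float
    shared_variance: float
    n_genes: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _pairwise(corr: np.ndarray, idx_a, idx_b=None):
    """Pairwise correlations within one index set or between two."""
    if idx_b is None:
        vals = [corr[i, j] for i, j in combinations(idx_a, 2)]
    else:
        vals = [corr[i, j] for i in idx_a for j in idx_b]
    return np.asarray(vals)


def profile_correlations(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    sample_filter=None,
    transform: str = "log2p1_normalized",
) -> CorrelationSummary:
    """Within- vs between-cohort Pearson correlation of expression profiles.

    Each cohort is normalized by median-of-ratios on its own samples,
    restricted to the shared gene universe, and transformed to
    log2(normalized + 1).  ``sample_filter`` is an optional predicate on
    metadata rows (e.g. ``lambda m: m.condition == "control"``).
    """
    if transform != "log2p1_normalized":
        raise ValueError("only the log2p1_normalized transform is implemented")

    def prep(cm: CountMatrix) -> pd.DataFrame:
        if sample_filter is not None:
            keep = [s for s in cm.sample_ids if sample_filter(cm.sample_meta.loc[s])]
            if len(keep) < 2:
                raise ValueError("need >= 2 samples per cohort after filtering")
            cm = cm.subset_samples(keep)
        _, norm = median_of_ratios(cm)
        return norm

    norm_a, norm_b = prep(counts_a), prep(counts_b)
    shared = norm_a.index.intersection(norm_b.index)
    if len(shared) < 100:
        raise ValueError(f"shared gene universe too small ({len(shared)} genes)")
    mat = np.log2(
        pd.concat([norm_a.loc[shared], norm_b.loc[shared]], axis=1).to_numpy() + 1.0
    )
    corr = np.corrcoef(mat, rowvar=False)
    na = norm_a.shape[1]
    idx_a = list(range(na))
    idx_b = list(range(na, na + norm_b.shape[1]))
    wa = _pairwise(corr, idx_a)
    wb = _pairwise(corr, idx_b)
    bt = _pairwise(corr, idx_a, idx_b)
    within_mean = np.concatenate([wa, wb]).mean()
    between_mean = bt.mean()
    return CorrelationSummary(
        within_a_mean=float(wa.mean()),
        within_a_sd=float(wa.std(ddof=1)) if wa.size > 1 else 0.0,
        within_b_mean=float(wb.mean()),
        within_b_sd=float(wb.std(ddof=1)) if wb.size > 1 else 0.0,
        between_mean=float(between_mean),
        between_sd=float(bt.std(ddof=1)) if bt.size > 1 else 0.0,
        pct_difference=float((within_mean - between_mean) / within_mean * 100.0),
        shared_variance=float(between_mean**2),
        n_genes=int(len(shared)),
    )


def directionality_consistency(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    selection: str = "degs_of_a",
    alpha: float = 0.05,
) -> dict:
    """Fraction of genes with the same fold-change sign in both cohorts.

    ``selection='degs_of_a'`` evaluates the significant genes of the
    reference cohort A; ``'all_shared'`` evaluates every shared gene.
    Genes with a zero fold change in either table are excluded (and
    counted).  The p-value is an exact two-sided binomial test against
    0.5.
    """
    if selection not in ("degs_of_a", "all_shared"):
        raise ValueError("selection must be 'degs_of_a' or 'all_shared'")
    a = de_a.set_index("gene_id")
    b = de_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared genes between the two DE tables")
    if selection == "degs_of_a":
        if "significant" in a.columns:
            sel = a.loc[shared].index[a.loc[shared, "significant"].astype(bool)]
        else:
            sel = a.loc[shared].index[a.loc[shared, "padj"] < alpha]
        if sel.empty:
            raise ValueError("reference cohort has no significant genes among shared")
    else:
        sel = shared
    sign_a = np.sign(a.loc[sel, "log2fc"].to_numpy(dtype=float))
    sign_b = np.sign(b.loc[sel, "log2fc"].to_numpy(dtype=float))
    nonzero = (sign_a != 0) & (sign_b != 0)
    n_zero = int((~nonzero).sum())
    if not nonzero.any():
        raise ValueError("all selected genes have a zero fold change in one cohort")
    consistent = sign_a[nonzero] == sign_b[nonzero]
    n, k = int(nonzero.sum()), int(consistent.sum())
    test = stats.binomtest(k, n, p=0.5, alternative="two-sided")
    return {
        "fraction_consistent": k / n,
        "n_consistent": k,
        "n_evaluated": n,
        "n_zero_excluded": n_zero,
        "pvalue": float(test.pvalue),
    }


def overlap_analysis(
    deg_sets: dict[str, set[str]], pooled_name: str | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Counts for every region of the inclusion-exclusion partition.

    Returns ``(regions, lost_by_pooling)``: one row per nonempty
    membership pattern (which sets contain the region) with its exclusive
    gene count, and — when ``pooled_name`` names one of the sets — the
    sorted genes present in some other set but absent from the pooled
    one.
    """
    if len(deg_sets) < 2:
        raise ValueError("overlap analysis needs >= 2 named sets")
    names = list(deg_sets)
    union = set().union(*deg_sets.values())
    patterns: dict[tuple[bool, ...], list[str]] = {}
    for gene in union:
        key = tuple(gene in deg_sets[n] for n in names)
        patterns.setdefault(key, []).append(gene)
    rows = []
    for key in sorted(patterns, reverse=True):
        rows.append(
            {
                "region": "&".join(n for n, inside in zip(names, key) if inside),
                **{f"in_{n}": inside for n, inside in zip(names, key)},
                "n_genes": len(patterns[key]),
            }
        )
    regions = pd.DataFrame(rows)
    lost: list[str] = []
    if pooled_name is not None:
        if pooled_name not in deg_sets:
            raise ValueError(f"pooled set {pooled_name!r} not among the named sets")
        others = set().union(
            *(s for n, s in deg_sets.items() if n != pooled_name)
        )
        lost = sorted(others - deg_sets[pooled_name])
    return regions, lost
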