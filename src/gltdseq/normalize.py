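"""Between-sample normalization and expression filtering.

Two schemes are implemented independently, matching common practice in
bulk RNA-seq:

* **median-of-ratios** size factors: per-gene pseudo-reference = geometric
  mean across samples (genes with any zero excluded); a sample's size
  factor is the median over genes of count / pseudo-reference; normalized
  counts = counts / size factor.
* **TMM** (trimmed mean of M-values): per-sample scaling factor
  2^(precision-weighted mean of library-size-adjusted log2 ratios against
  a reference sample, after symmetric trimming of extreme M and A
  values), rescaled to geometric mean 1 across samples.

The expression filter retains a gene when at least one group has enough
replicates with normalized counts strictly above a threshold; the TMM
abundance filter selects the gene universe for the gene-length analysis
by mean TMM-normalized counts-per-million.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "median_of_ratios",
    "tmm_factors",
    "expression_filter",
    "tmm_abundance_filter",
    "tmm_cpm",
]


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def median_of_ratios(counts) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    Returns ``(size_factors, normalized)``.  Genes containing a zero in
    any sample are excluded from the pseudo-reference; at least one
    all-nonzero gene is required.
    """
    frame = _as_frame(counts)
    x = frame.to_numpy(dtype=float)
    nonzero = (x > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter low-count genes first"
        )
    logs = np.log(x[nonzero])
    ref = np.exp(logs.mean(axis=1))  # geometric mean per gene
    factors = np.median(x[nonzero] / ref[:, None], axis=0)
    size_factors = pd.Series(factors, index=frame.columns, name="size_factor")
    normalized = frame / size_factors
    return size_factors, normalized


def tmm_factors(
    counts,
    reference: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factors (geometric mean 1 across samples).

    ``reference='auto'`` picks the sample whose upper-quartile of
    library-scaled counts is closest to the mean upper-quartile.  M
    values are trimmed symmetrically by ``trim_m`` (default 30%) and A
    values by ``trim_a`` (default 5%); the remaining M values are
    averaged with inverse asymptotic-variance (precision) weights.
    """
    frame = _as_frame(counts)
    x = frame.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("a sample has zero library size")
    if reference == "auto":
        uq = np.array(
            [np.quantile(x[x[:, j] > 0, j] / lib[j], 0.75) if (x[:, j] > 0).any() else 0.0
             for j in range(x.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in frame.columns:
            raise ValueError(f"reference sample {reference!r} not in matrix")
        ref_idx = frame.columns.get_loc(reference)
    ref = x[:, ref_idx]
    n_ref = lib[ref_idx]
    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        obs = x[:, j]
        n_obs = lib[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValueError("no genes shared between sample and reference")
        po, pr = obs[keep] / n_obs, ref[keep] / n_ref
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a = m[finite], a[finite]
        o, r = obs[keep][finite], ref[keep][finite]
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep2.any():
            raise ValueError("all genes trimmed; relax trim fractions")
        # delta-method asymptotic variance of M
        w = (n_obs - o[keep2]) / (n_obs * o[keep2]) + (n_ref - r[keep2]) / (
            n_ref * r[keep2]
        )
        log_factors[j] = np.sum(m[keep2] / w) / np.sum(1.0 / w)
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="tmm_factor")


def expression_filter(
    normalized: pd.DataFrame,
    groups: dict[str, list[str]],
    min_replicates: int,
    min_count: float = 20.0,
) -> pd.Index:
    """Genes with >= ``min_replicates`` samples strictly above ``min_count``
    in at least one group (on the normalized scale)."""
    if not groups:
        raise ValueError("empty sample grouping")
    smallest = min(len(s) for s in groups.values())
    if min_replicates > smallest:
        raise ValueError(
            f"min_replicates={min_replicates} exceeds smallest group size {smallest}"
        )
    keep = np.zeros(len(normalized), dtype=bool)
    for samples in groups.values():
        above = (normalized[list(samples)].to_numpy() > min_count).sum(axis=1)
        keep |= above >= min_replicates
    return normalized.index[keep]


def tmm_cpm(counts, factors: pd.Series) -> pd.DataFrame:
    """Counts per million on TMM-adjusted effective library sizes."""
    frame = _as_frame(counts)
    lib = frame.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.loc[frame.columns].to_numpy(dtype=float)
    return frame / eff * 1e6


def tmm_abundance_filter(
    counts,
    factors: pd.Series,
    threshold: float = 1.0,
    aggregate: str = "mean",
) -> pd.Index:
    """Gene universe for the gene-length analysis: mean TMM-CPM > threshold.

    ``aggregate='all'`` instead requires every sample to exceed the
    threshold.
    """
    cpm = tmm_cpm(counts, factors)
    if aggregate == "mean":
        stat = cpm.mean(axis=1)
    elif aggregate == "all":
        stat = cpm.min(axis=1)
    else:
        raise ValueError("aggregate must be 'mean' or 'all'")
    return cpm.index[stat.to_numpy() > threshold]
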