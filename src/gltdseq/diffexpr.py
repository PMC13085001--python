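"""Per-gene two-group differential expression and cross-cohort meta-analysis.

The internal caller is a deliberately simple negative-binomial Wald test:
per-gene group means on the normalized scale, a pooled method-of-moments
dispersion, a delta-method standard error for the log2 fold change and a
two-sided normal p-value, with Benjamini-Hochberg correction.  It has no
dispersion shrinkage across genes, no outlier replacement and no
independent filtering; externally produced DE tables are first-class
inputs everywhere downstream.

The model/results API follows the statsmodels idiom::

    model = NBWaldModel(counts, contrast=("ELS", "control"))
    res = model.fit()
    res.summary()
    res.table          # gene_id, base_mean, log2fc, se, pvalue, padj, significant
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .normalize import median_of_ratios

__all__ = [
    "bh_adjust",
    "nb_wald_test",
    "NBWaldModel",
    "DEResults",
    "interaction_contrast",
    "meta_analyze",
]

LN2 = np.log(2.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    contrast: tuple[str, str] = ("ELS", "control"),
    condition_col: str = "condition",
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """NB Wald test of *contrast* = (treatment-level, control-level).

    log2fc is the treatment-vs-control log2 ratio of group means (with a
    stabilizing pseudo-count); its standard error comes from the delta
    method on NB variances with a pooled within-group method-of-moments
    dispersion.  Returns the standard DE table.
    """
    treat_label, ctrl_label = contrast
    groups = counts.groups(condition_col)
    for label in contrast:
        if label not in groups:
            raise ValueError(f"group {label!r} not present in metadata")
        if len(groups[label]) < 2:
            raise ValueError(f"group {label!r} has <2 samples; cannot estimate dispersion")
    if factors is None:
        factors, _ = median_of_ratios(counts)
    normalized = counts.counts / factors
    t = normalized[groups[treat_label]].to_numpy(dtype=float)
    c = normalized[groups[ctrl_label]].to_numpy(dtype=float)
    n_t, n_c = t.shape[1], c.shape[1]
    m_t, m_c = t.mean(axis=1), c.mean(axis=1)
    s2_t, s2_c = t.var(axis=1, ddof=1), c.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion: var = mu + alpha mu^2 per group
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = np.where(m_t > 0, (s2_t - m_t) / np.square(m_t), 0.0)
        a_c = np.where(m_c > 0, (s2_c - m_c) / np.square(m_c), 0.0)
    disp = ((n_t - 1) * a_t + (n_c - 1) * a_c) / (n_t + n_c - 2)
    disp = np.maximum(disp, dispersion_floor)
    v_t = m_t + disp * np.square(m_t)
    v_c = m_c + disp * np.square(m_c)
    pc = pseudocount
    lfc = np.log2(m_t + pc) - np.log2(m_c + pc)
    se = (
        np.sqrt(v_t / (n_t * np.square(m_t + pc)) + v_c / (n_c * np.square(m_c + pc)))
        / LN2
    )
    expressed = (m_t + m_c) > 0
    se = np.where(expressed, se, np.inf)
    z = np.where(se > 0, lfc / se, 0.0)
    # t reference with the pooled dispersion df: the variance behind the
    # Wald statistic is estimated from n_t + n_c - 2 residual df, and a
    # normal reference is anti-conservative at the study's group sizes
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=n_t + n_c - 2)
    pvalue = np.where(expressed, pvalue, 1.0)
    padj = bh_adjust(pvalue)
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids.to_numpy(),
            "base_mean": normalized.mean(axis=1).to_numpy(),
            "log2fc": lfc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "df": n_t + n_c - 2,
        }
    )
    table["significant"] = table["padj"] < alpha
    return table


class NBWaldModel:
    """Two-group NB Wald differential-expression model.

    Parameters
    ----------
    counts
        :class:`~gltdseq.io.CountMatrix` (pre-filtered to expressed genes).
    contrast
        ``(treatment_level, control_level)`` of ``condition_col``.
    factors
        Optional per-sample size factors; median-of-ratios by default.
    """

    def __init__(
        self,
        counts: CountMatrix,
        contrast: tuple[str, str] = ("ELS", "control"),
        condition_col: str = "condition",
        factors: pd.Series | None = None,
        alpha: float = 0.05,
        pseudocount: float = 0.5,
    ) -> None:
        self.counts = counts
        self.contrast = contrast
        self.condition_col = condition_col
        self.factors = factors
        self.alpha = alpha
        self.pseudocount = pseudocount

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, sample_meta: pd.DataFrame, **kwargs
    ) -> "NBWaldModel":
        return cls(CountMatrix(counts, sample_meta), **kwargs)

    def fit(self) -> "DEResults":
        table = nb_wald_test(
            self.counts,
            factors=self.factors,
            contrast=self.contrast,
            condition_col=self.condition_col,
            alpha=self.alpha,
            pseudocount=self.pseudocount,
        )
        return DEResults(table, self.contrast, self.alpha)


@dataclass
class DEResults:
    """Fitted differential-expression results (one row per gene)."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        t = self.table
        up = int(((t["log2fc"] > 0) & t["significant"]).sum())
        down = int(((t["log2fc"] < 0) & t["significant"]).sum())
        de = t[t["significant"]]
        mean_abs = float(de["log2fc"].abs().mean()) if len(de) else float("nan")
        lines = [
            "NB Wald differential expression",
            f"  contrast: {self.contrast[0]} vs {self.contrast[1]}",
            f"  genes tested: {len(t)}",
            f"  significant (padj < {self.alpha:g}): {self.n_significant}"
            f" ({up} up, {down} down)",
            f"  mean |log2FC| of significant genes: {mean_abs:.3f}",
        ]
        return "\n".join(lines)


def interaction_contrast(
    de_vehicle: pd.DataFrame, de_ru486: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Condition x treatment interaction as a contrast of contrasts.

    Per gene: delta = log2fc under the second treatment minus under the
    first; se_delta = sqrt(se1^2 + se2^2); two-sided normal p; BH padj.
    """
    a = de_vehicle.set_index("gene_id")
    b = de_ru486.set_index("gene_id")
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("the two DE tables cover different gene sets")
    b = b.loc[a.index]
    for t, name in ((a, "first"), (b, "second")):
        if "se" not in t.columns or not np.all(np.isfinite(t["se"]) | (t["se"] > 0)):
            raise ValueError(f"{name} DE table lacks usable standard errors")
    delta = b["log2fc"].to_numpy() - a["log2fc"].to_numpy()
    se = np.sqrt(np.square(a["se"].to_numpy()) + np.square(b["se"].to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    if "df" in a.columns and "df" in b.columns:
        # each arm's variance is estimated; sum the residual df for the reference
        df = a["df"].to_numpy(dtype=float) + b["df"].to_numpy(dtype=float)
        pvalue = np.where(np.isfinite(z), 2.0 * stats.t.sf(np.abs(z), df=df), 1.0)
    else:
        # external tables without df: large-sample normal reference
        pvalue = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    padj = bh_adjust(pvalue)
    out = pd.DataFrame(
        {
            "gene_id": a.index.to_numpy(),
            "delta_log2fc": delta,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
        }
    )
    out["significant"] = out["padj"] < alpha
    return out


def meta_analyze(per_cohort: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect meta-analysis of per-gene effects across >= 2 cohorts.

    Each input table needs ``gene_id``, ``log2fc`` and ``se`` columns.
    Inverse-variance: beta_iv = sum(b/se^2)/sum(1/se^2),
    se_iv = 1/sqrt(sum(1/se^2)).  Equal-weight: arithmetic mean of b with
    se = sqrt(sum(se^2))/k.  Two-sided normal p for each.
    """
    if len(per_cohort) < 2:
        raise ValueError("meta-analysis requires >= 2 cohorts")
    tables = [t.set_index("gene_id") for t in per_cohort]
    genes = tables[0].index
    for t in tables[1:]:
        genes = genes.intersection(t.index)
    if genes.empty:
        raise ValueError("no shared genes across cohorts")
    betas = np.column_stack([t.loc[genes, "log2fc"].to_numpy(dtype=float) for t in tables])
    ses = np.column_stack([t.loc[genes, "se"].to_numpy(dtype=float) for t in tables])
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    k = betas.shape[1]
    w = 1.0 / np.square(ses)
    beta_iv = (betas * w).sum(axis=1) / w.sum(axis=1)
    se_iv = 1.0 / np.sqrt(w.sum(axis=1))
    beta_eq = betas.mean(axis=1)
    se_eq = np.sqrt(np.square(ses).sum(axis=1)) / k
    p_iv = 2.0 * stats.norm.sf(np.abs(beta_iv / se_iv))
    p_eq = 2.0 * stats.norm.sf(np.abs(beta_eq / se_eq))
    return pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "beta_iv": beta_iv,
            "se_iv": se_iv,
            "p_iv": p_iv,
            "beta_eq": beta_eq,
            "se_eq": se_eq,
            "p_eq": p_eq,
        }
    )
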