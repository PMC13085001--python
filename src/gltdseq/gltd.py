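"""Gene-length-dependent transcriptional decline (GLTD) statistics.

The core statistic of the package.  Genes in the analyzed universe are
sorted by genomic length and grouped into consecutive bins of a fixed
size (default 500), anchored so the bin with the longest genes is
complete; the incomplete bin of shortest genes is discarded.  Per bin,
the *up-ratio* is the fraction of direction-called genes that are
upregulated, n_up / (n_up + n_down).  The GLTD trend is the ordinary
least-squares regression of up-ratio on log10(mean bin length): a
negative slope means long genes are preferentially downregulated —
the signature of length-dependent transcriptional decline seen in
aging and stressed tissue.

Model/results API::

    model = GeneLengthTrendModel(de_table, lengths, bin_size=500)
    res = model.fit()
    print(res.summary())
    res.bins       # per-bin table
    res.slope, res.pearson_r, res.pvalue
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthBinTable",
    "bin_by_length",
    "bin_direction_ratio",
    "GLTDFit",
    "length_ratio_regression",
    "GeneLengthTrendModel",
    "GeneLengthTrendResults",
    "CohortComparison",
    "cohort_interaction_regression",
    "deg_length_shift_test",
]


@dataclass
class LengthBinTable:
    """Ordered equal-size gene-length bins (bin 0 = longest genes).

    ``table`` has one row per bin: bin_index, mean_length_bp, n_total and
    (after :func:`bin_direction_ratio`) n_up, n_down, up_ratio.
    ``assignments`` maps each retained gene id to its bin index;
    ``discarded`` lists the shortest genes that did not fill a bin.
    """

    table: pd.DataFrame
    assignments: pd.Series
    discarded: list[str] = field(default_factory=list)
    bin_size: int = 500

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def members(self, bin_index: int) -> list[str]:
        return self.assignments.index[self.assignments == bin_index].tolist()


def bin_by_length(lengths: pd.Series, bin_size: int = 500) -> LengthBinTable:
    """Partition genes into consecutive length bins of exactly ``bin_size``.

    Genes are sorted by descending length (ties broken by ascending gene
    id); complete bins are taken from the longest end and the trailing
    incomplete bin of shortest genes is discarded.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    n = len(lengths)
    if n < bin_size:
        raise ValueError(f"universe of {n} genes is smaller than one bin ({bin_size})")
    frame = lengths.rename("length_bp").to_frame()
    # descending length; ties broken by ascending gene id for reproducibility
    order = np.lexsort((frame.index.to_numpy(), -frame["length_bp"].to_numpy(dtype=float)))
    frame = frame.iloc[order]
    n_bins = n // bin_size
    kept = frame.iloc[: n_bins * bin_size]
    discarded = frame.index[n_bins * bin_size :].tolist()
    bin_idx = np.repeat(np.arange(n_bins), bin_size)
    assignments = pd.Series(bin_idx, index=kept.index, name="bin_index")
    table = pd.DataFrame(
        {
            "bin_index": np.arange(n_bins),
            "mean_length_bp": kept["length_bp"].to_numpy(dtype=float)
            .reshape(n_bins, bin_size)
            .mean(axis=1),
            "n_total": bin_size,
        }
    )
    return LengthBinTable(table, assignments, discarded, bin_size)


def bin_direction_ratio(
    bins: LengthBinTable,
    de: pd.DataFrame,
    mode: str = "all_genes",
    alpha: float = 0.05,
    ratio: str = "proportion",
) -> LengthBinTable:
    """Per-bin direction counts and up-ratio.

    ``mode='all_genes'`` calls direction from the sign of every gene's
    log2 fold change (genes with log2fc exactly 0 count in neither
    direction); ``mode='deg_only'`` restricts to significant genes
    (padj < alpha).  ``ratio='proportion'`` (default) reports
    n_up/(n_up+n_down); ``ratio='odds'`` reports n_up/n_down instead.
    Bins with no direction-called genes get an undefined (NaN) ratio and
    are excluded from downstream regression.
    """
    if mode not in ("all_genes", "deg_only"):
        raise ValueError("mode must be 'all_genes' or 'deg_only'")
    if ratio not in ("proportion", "odds"):
        raise ValueError("ratio must be 'proportion' or 'odds'")
    de_idx = de.set_index("gene_id")
    missing = bins.assignments.index.difference(de_idx.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} binned gene(s) missing from the DE table, "
            f"e.g. {missing[:3].tolist()}"
        )
    sub = de_idx.loc[bins.assignments.index]
    lfc = sub["log2fc"].to_numpy(dtype=float)
    if mode == "deg_only":
        if "significant" in sub.columns:
            called = sub["significant"].to_numpy(dtype=bool)
        else:
            called = sub["padj"].to_numpy(dtype=float) < alpha
    else:
        called = np.ones(len(sub), dtype=bool)
    bin_idx = bins.assignments.to_numpy()
    n_bins = bins.n_bins
    up = np.bincount(bin_idx[called & (lfc > 0)], minlength=n_bins)
    down = np.bincount(bin_idx[called & (lfc < 0)], minlength=n_bins)
    table = bins.table.copy()
    table["n_up"] = up
    table["n_down"] = down
    denom = up + down
    with np.errstate(divide="ignore", invalid="ignore"):
        if ratio == "proportion":
            table["up_ratio"] = np.where(denom > 0, up / denom, np.nan)
        else:
            table["up_ratio"] = np.where(down > 0, up / down, np.nan)
    return LengthBinTable(table, bins.assignments, bins.discarded, bins.bin_size)


@dataclass
class GLTDFit:
    """OLS fit of up-ratio on log10(mean bin length)."""

    slope: float
    intercept: float
    pearson_r: float
    t_stat: float
    df: int
    pvalue: float
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "t_stat": self.t_stat,
            "df": self.df,
            "pvalue": self.pvalue,
            "n_bins": self.n_bins,
        }


def length_ratio_regression(bins: LengthBinTable) -> GLTDFit:
    """Regress per-bin up-ratio on log10(mean bin length) by OLS.

    Reports slope, intercept, Pearson r, t = r*sqrt(df/(1-r^2)) with
    df = n_bins - 2, and the two-sided p.  Bins with undefined ratio are
    dropped; at least 3 usable bins are required, with nonzero variance
    in both axes.
    """
    usable = bins.table.dropna(subset=["up_ratio"])
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable bins; need >= 3 for regression")
    x = np.log10(usable["mean_length_bp"].to_numpy(dtype=float))
    y = usable["up_ratio"].to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0) or np.allclose(x.var(), 0.0):
        raise ValueError("zero variance in ratios or lengths; correlation undefined")
    fit = stats.linregress(x, y)
    df = len(usable) - 2
    r = fit.rvalue
    t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    return GLTDFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(r),
        t_stat=float(t),
        df=df,
        pvalue=float(fit.pvalue),
        n_bins=len(usable),
    )


class GeneLengthTrendModel:
    """Gene-length trend model: bin genes by length, regress up-ratio on log10 L.

    Parameters
    ----------
    de
        DE table (gene_id, log2fc, padj, ...) covering the universe.
    lengths
        Per-gene genomic lengths (bp), restricted to the analyzed universe
        (conventionally: genes with mean TMM-CPM > 1).
    bin_size
        Genes per bin; the longest-gene bin is complete and the trailing
        incomplete shortest bin is discarded.
    mode
        'all_genes' (direction from the sign of every fold change) or
        'deg_only' (significant genes only).
    """

    def __init__(
        self,
        de: pd.DataFrame,
        lengths: pd.Series,
        bin_size: int = 500,
        mode: str = "all_genes",
        alpha: float = 0.05,
        ratio: str = "proportion",
    ) -> None:
        self.de = de
        self.lengths = lengths
        self.bin_size = bin_size
        self.mode = mode
        self.alpha = alpha
        self.ratio = ratio

    def fit(self) -> "GeneLengthTrendResults":
        bins = bin_by_length(self.lengths, self.bin_size)
        bins = bin_direction_ratio(bins, self.de, self.mode, self.alpha, self.ratio)
        fit = length_ratio_regression(bins)
        return GeneLengthTrendResults(bins, fit, self.mode)


@dataclass
class GeneLengthTrendResults:
    """Fitted gene-length trend: per-bin table plus the OLS fit."""

    bin_table: LengthBinTable
    fit: GLTDFit
    mode: str = "all_genes"

    @property
    def bins(self) -> pd.DataFrame:
        return self.bin_table.table

    slope = property(lambda self: self.fit.slope)
    intercept = property(lambda self: self.fit.intercept)
    pearson_r = property(lambda self: self.fit.pearson_r)
    t_stat = property(lambda self: self.fit.t_stat)
    df = property(lambda self: self.fit.df)
    pvalue = property(lambda self: self.fit.pvalue)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Gene-length trend (up-ratio vs log10 length)",
            f"  bins used: {f.n_bins} x {self.bin_table.bin_size} genes"
            f" ({len(self.bin_table.discarded)} shortest discarded)",
            f"  direction mode: {self.mode}",
            f"  slope: {f.slope:+.4f} per log10(bp)   intercept: {f.intercept:.4f}",
            f"  Pearson r = {f.pearson_r:+.3f}, t({f.df}) = {f.t_stat:+.2f},"
            f" p = {f.pvalue:.3g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Up-ratio vs log10 mean bin length with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.bins.dropna(subset=["up_ratio"])
        x = np.log10(t["mean_length_bp"])
        ax.scatter(x, t["up_ratio"], s=18)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.fit.intercept + self.fit.slope * grid, color="C3")
        ax.axhline(0.5, ls=":", color="grey", lw=0.8)
        ax.set_xlabel("log10 mean bin gene length (bp)")
        ax.set_ylabel("up-ratio  n_up/(n_up+n_down)")
        return ax


@dataclass
class CohortComparison:
    """ANOVA comparison of length trends between two cohorts."""

    f_stat: float
    df_num: int
    df_den: int
    pvalue: float
    pooled_slope: float
    pooled_slope_se: float
    pooled_slope_t: float
    pooled_slope_p: float
    cohort_effect: float
    cohort_effect_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def cohort_interaction_regression(
    bins_a: LengthBinTable, bins_b: LengthBinTable
) -> CohortComparison:
    """Test whether the length slope differs between cohorts.

    Fits up_ratio ~ log10L + cohort + log10L:cohort and compares it
    against the no-interaction model by ANOVA (F on residual sums of
    squares).  Also reports the pooled fixed-effects model's common slope
    and cohort main effect.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frames = []
    for label, bins in (("a", bins_a), ("b", bins_b)):
        usable = bins.table.dropna(subset=["up_ratio"])
        if len(usable) < 3:
            raise ValueError(f"cohort {label!r} has <3 usable bins")
        frames.append(
            pd.DataFrame(
                {
                    "log10_length": np.log10(usable["mean_length_bp"]),
                    "up_ratio": usable["up_ratio"],
                    "cohort": label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    reduced = smf.ols("up_ratio ~ log10_length + C(cohort)", data=data).fit()
    full = smf.ols("up_ratio ~ log10_length * C(cohort)", data=data).fit()
    comparison = anova_lm(reduced, full)
    f_stat = float(comparison["F"].iloc[1])
    df_num = int(comparison["df_diff"].iloc[1])
    df_den = int(full.df_resid)
    pvalue = float(comparison["Pr(>F)"].iloc[1])
    slope_name = "log10_length"
    cohort_name = [n for n in reduced.params.index if n.startswith("C(cohort)")][0]
    return CohortComparison(
        f_stat=f_stat,
        df_num=df_num,
        df_den=df_den,
        pvalue=pvalue,
        pooled_slope=float(reduced.params[slope_name]),
        pooled_slope_se=float(reduced.bse[slope_name]),
        pooled_slope_t=float(reduced.tvalues[slope_name]),
        pooled_slope_p=float(reduced.pvalues[slope_name]),
        cohort_effect=float(reduced.params[cohort_name]),
        cohort_effect_p=float(reduced.pvalues[cohort_name]),
    )


def deg_length_shift_test(
    de: pd.DataFrame, lengths: pd.Series, alpha: float = 0.05
) -> dict:
    """Mann-Whitney U comparing genomic lengths of up- vs down-regulated DEGs.

    Uses the exact null distribution when both groups have <= 8 genes and
    the tie-corrected normal approximation otherwise.  Returns U (for the
    up-regulated group), group sizes and the two-sided p.
    """
    if "significant" in de.columns:
        sig = de[de["significant"]]
    else:
        sig = de[de["padj"] < alpha]
    up_ids = sig.loc[sig["log2fc"] > 0, "gene_id"]
    down_ids = sig.loc[sig["log2fc"] < 0, "gene_id"]
    if len(up_ids) == 0 or len(down_ids) == 0:
        raise ValueError(
            "Mann-Whitney length-shift test undefined: need >= 1 significant gene "
            f"in each direction (got {len(up_ids)} up, {len(down_ids)} down)"
        )
    up = lengths.loc[up_ids].to_numpy(dtype=float)
    down = lengths.loc[down_ids].to_numpy(dtype=float)
    method = "exact" if (len(up) <= 8 and len(down) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(up, down, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "pvalue": float(res.pvalue),
        "method": method,
        "median_length_up": float(np.median(up)),
        "median_length_down": float(np.median(down)),
    }
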