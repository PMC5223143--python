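"""Negative-binomial differential testing of count matrices.

Implements the standard RNA-seq/ChIP-seq count-testing recipe from scratch
for two-group contrasts: median-of-ratios size factors, per-feature
method-of-moments dispersion with shrinkage toward a fitted mean-dispersion
trend, a Wald test on log2 group means with a delta-method standard error
under the NB variance model ``var = mu + alpha * mu**2``, and
Benjamini-Hochberg FDR correction.

The design is deliberately restricted to pairwise group comparisons (no
multi-factor GLM, no fold-change shrinkage, no outlier handling): the
analyses this package supports are all two-group contrasts of a four-group
feeding design, and the simple estimator is transparent and directly
testable against simulations with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("Chow", "HFD", "ChowChow", "HFDChow")

DISPERSION_FLOOR = 1e-8
#: weight given to the per-feature moment estimate when shrinking toward
#: the fitted mean-dispersion trend; the moment estimate is very noisy at
#: 2-3 replicates per group, and heavier weights leak that noise into the
#: Wald tail (and correlate contrasts that share the dispersion estimate)
SHRINKAGE_WEIGHT = 0.25
#: pseudocount added to normalized group means before taking log2
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Features x samples integer counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``meta`` is indexed by sample id with columns ``group`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("feature ids must be unique")
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("counts columns must match meta sample ids")
        if "group" not in self.meta.columns:
            raise ValueError("meta must have a 'group' column")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.meta.index[self.meta["group"] == group])

    def to_tsv(self, counts_path: str, meta_path: str | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        if meta_path:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str, meta_path: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(counts, meta.loc[counts.columns])


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``group_b`` (test) versus ``group_a`` (reference)."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @property
    def label(self) -> str:
        return f"{self.group_b}_vs_{self.group_a}"


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios sequencing-depth factors, one per sample.

    Features with a zero in any sample are excluded from the median.
    Raises if no feature has all-positive counts.
    """
    x = cm.counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("cannot normalize: no feature with all-positive counts")
    logx = np.log(x[allpos])
    log_geomean = logx.mean(axis=1)
    ratios = logx - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def estimate_dispersion(cm: CountMatrix, sf: pd.Series) -> pd.Series:
    """Per-feature NB dispersion, moment estimate shrunk toward a trend.

    The raw estimate pools within-group variances of size-factor-normalized
    counts: ``alpha_hat = max(0, (var - mu) / mu**2)``.  A mean-dispersion
    trend ``a0 + a1/mu`` is fitted by least squares over features with
    ``mu > 5`` and the final value is a fixed-weight blend of the raw
    estimate and the trend, floored at 1e-8.  Requires >= 2 replicates in
    every group present in the matrix.
    """
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    groups = cm.meta["group"]
    group_labels = groups.unique()
    n_feat = norm.shape[0]

    ss = np.zeros(n_feat)  # pooled within-group sum of squares
    df = 0
    group_means = []
    for g in group_labels:
        idx = np.flatnonzero((groups == g).to_numpy())
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        df += idx.size - 1
        group_means.append(m)
    var = ss / df
    mu = norm.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    alpha_hat = np.maximum(alpha_hat, 0.0)

    # mean-dispersion trend alpha = a0 + a1/mu over moderately expressed features
    fit_mask = mu > 5
    if fit_mask.sum() >= 2:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_hat[fit_mask], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
        trend = np.clip(trend, 0.0, None)
    else:
        trend = np.full(n_feat, np.median(alpha_hat))

    alpha = SHRINKAGE_WEIGHT * alpha_hat + (1.0 - SHRINKAGE_WEIGHT) * trend
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=cm.counts.index, name="dispersion")


def nb_wald_test(
    cm: CountMatrix,
    sf: pd.Series,
    alpha: pd.Series,
    contrast: Contrast,
) -> pd.DataFrame:
    """Wald test of log2 fold change between two groups under the NB model.

    Group means are computed on normalized counts with a pseudocount of 0.5;
    the standard error of the log2 fold change follows from the delta method
    with ``var(count) = mu + alpha * mu**2``.  Features with zero counts in
    all contrast samples get missing p and FDR and are excluded from the
    multiple-testing correction.

    Returns a DataFrame indexed by feature id with columns ``base_mean``,
    ``log2fc``, ``se``, ``stat``, ``p``, ``fdr``.
    """
    for g in (contrast.group_a, contrast.group_b):
        if g not in set(cm.meta["group"]):
            raise ValueError(f"unknown group label {g!r}")

    ln2 = np.log(2.0)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    a_idx = [cm.sample_ids.index(s) for s in cm.samples_in_group(contrast.group_a)]
    b_idx = [cm.sample_ids.index(s) for s in cm.samples_in_group(contrast.group_b)]
    al = alpha.to_numpy()

    def group_stats(idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
        sub = norm[:, idx]
        m = sub.mean(axis=1) + PSEUDOCOUNT
        inv_s = float(np.sum(1.0 / sf.to_numpy()[idx]))
        n = len(idx)
        # var of the group mean of normalized counts under the NB model
        v = m * inv_s / n**2 + al * m**2 / n
        return m, v

    m_a, v_a = group_stats(a_idx)
    m_b, v_b = group_stats(b_idx)

    # difference of logs so reversing the contrast negates log2fc exactly
    log2fc = np.log2(m_b) - np.log2(m_a)
    se = np.sqrt(v_a / m_a**2 + v_b / m_b**2) / ln2
    stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    allzero = norm[:, a_idx + b_idx].sum(axis=1) == 0
    p = np.where(allzero, np.nan, p)
    fdr = bh_fdr(p)

    base_mean = norm[:, a_idx + b_idx].mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "fdr": fdr,
        },
        index=cm.counts.index.rename("feature_id"),
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (running-minimum form).

    Missing values are excluded from ``m`` and returned missing.  Raises on
    p outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out


def threshold_results(
    results: pd.DataFrame,
    fdr_max: float,
    min_abs_fc: float = 1.5,
    p_max: float | None = None,
) -> tuple[list[str], list[str]]:
    """Split features into up- and down-regulated id lists.

    ``min_abs_fc`` is a linear fold change >= 1; up means
    ``2**log2fc >= min_abs_fc``, down means ``2**log2fc <= 1/min_abs_fc``.
    When ``p_max`` is given the raw p-value replaces the FDR as the
    significance filter (the lenient screen used before FDR diagnostics).
    """
    if min_abs_fc < 1:
        raise ValueError("min_abs_fc must be >= 1")
    if results.empty:
        return [], []
    fc = np.power(2.0, results["log2fc"].to_numpy())
    if p_max is not None:
        sig = results["p"].to_numpy() < p_max
    else:
        sig = results["fdr"].to_numpy() < fdr_max
    sig = sig & ~np.isnan(results["p"].to_numpy())
    up = results.index[sig & (fc >= min_abs_fc)].tolist()
    down = results.index[sig & (fc <= 1.0 / min_abs_fc)].tolist()
    return up, down
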