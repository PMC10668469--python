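"""Normalization and differential expression.

The DE model is a per-feature negative-binomial GLM with log link fitted
against continuous gestational age (plus optional batch), with library-size
factors entering as offsets.  Dispersion is estimated per feature by method
of moments on size-factor-normalized counts, shrunk 50/50 toward a fitted
mean-dispersion trend, and floored; significance is a Wald test on the age
coefficient reported in log2 units per week, adjusted per layer with
Benjamini-Hochberg.

This is deliberately a compact NB-Wald pipeline validated by simulation
calibration rather than a re-implementation of any particular DE package.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, SampleTable

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
MIN_DISPERSION = 1e-8

DE_COLUMNS = ["base_mean", "log2fc", "se", "wald_stat", "p", "padj", "status"]


# ---------------------------------------------------------------------------
# size factors and normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Only features with strictly positive counts in every sample contribute
    ratios (the geometric reference is undefined elsewhere).
    """
    counts = cm.counts.to_numpy(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; size factors are "
            "undefined (consider a pseudo-reference fallback on such data)")
    ref = counts[positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geomean
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - np.mean(log_sf)  # rescale: geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=cm.sample_ids, name="size_factor")


def normalize_counts(cm: CountMatrix, size_factors: pd.Series,
                     log2: bool = False, pseudocount: float = 1.0) -> pd.DataFrame:
    """Divide each sample's counts by its size factor; optionally
    log2(x + pseudocount)."""
    if set(size_factors.index) != set(cm.sample_ids):
        raise ValueError("size factor samples do not match the count matrix")
    sf = size_factors.reindex(cm.sample_ids).to_numpy(float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    norm = cm.counts.to_numpy(float) / sf[None, :]
    if log2:
        norm = np.log2(norm + pseudocount)
    return pd.DataFrame(norm, index=cm.feature_ids, columns=cm.sample_ids)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are propagated and
    excluded from the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        bad = p[mask][(p[mask] < 0) | (p[mask] > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _moment_dispersions(norm: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature method-of-moments NB dispersion on normalized counts.

    The design's OLS fit supplies per-sample means so that covariate-driven
    variance is not mistaken for overdispersion; alpha solves
    sum((y - mu)^2 - mu) = alpha * sum(mu^2).
    """
    hat = design @ np.linalg.pinv(design)
    mu = norm @ hat.T
    mu = np.clip(mu, 1e-8, None)
    resid2 = (norm - mu) ** 2
    num = (resid2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    alpha = np.where(den > 0, num / den, 0.0)
    base_mean = norm.mean(axis=1)
    return np.clip(alpha, MIN_DISPERSION, None), base_mean


def _trend_shrink(alpha: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mean over features and average each raw estimate
    50/50 with the trend value at its mean."""
    ok = (base_mean > 0) & np.isfinite(alpha)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
        a0, a1 = np.clip(coef[0], 0.0, None), np.clip(coef[1], 0.0, None)
    else:  # too few features to fit a trend; fall back to the global mean
        a0, a1 = float(np.mean(alpha[ok])) if ok.any() else 0.0, 0.0
    trend = a0 + a1 / np.clip(base_mean, 1e-8, None)
    shrunk = 0.5 * alpha + 0.5 * trend
    return np.clip(shrunk, MIN_DISPERSION, None)


# ---------------------------------------------------------------------------
# NB regression against continuous age
# ---------------------------------------------------------------------------

def _build_design(samples: SampleTable, sample_ids, covariate: str,
                  extra_covariates) -> np.ndarray:
    t = samples.table.loc[list(sample_ids)]
    cols = [np.ones(len(t)), t[covariate].to_numpy(float)]
    for extra in extra_covariates:
        if extra not in t.columns:
            continue
        levels = pd.unique(t[extra])
        if len(levels) < 2:
            continue  # constant covariate carries no information
        for lev in levels[1:]:
            cols.append((t[extra] == lev).to_numpy(float))
    return np.column_stack(cols)


def fit_nb_continuous(cm: CountMatrix, samples: SampleTable,
                      covariate: str = "gestational_age",
                      extra_covariates: tuple[str, ...] = ("batch",),
                      size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-feature NB Wald test of the continuous-age coefficient.

    Returns a DE table with ``log2fc`` = fitted slope in log2 units per week,
    Wald ``p`` and BH-``padj`` computed across features with status ``ok``.
    All-zero features get status ``low_count`` and NA statistics; features
    whose GLM fails to converge get status ``failed``.
    """
    samples.require_samples(cm.sample_ids)
    if cm.n_samples < 6:
        raise ValueError("continuous DE requires at least 6 samples")
    ages = samples.table.loc[cm.sample_ids, covariate].to_numpy(float)
    if np.ptp(ages) == 0:
        raise ValueError(f"covariate {covariate!r} does not vary")

    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    sf = size_factors.reindex(cm.sample_ids).to_numpy(float)
    offset = np.log(sf)
    design = _build_design(samples, cm.sample_ids, covariate, extra_covariates)

    counts = cm.counts.to_numpy(float)
    norm = counts / sf[None, :]
    alpha_raw, base_mean = _moment_dispersions(norm, design)
    alpha = _trend_shrink(alpha_raw, base_mean)

    n_feat = cm.n_features
    res = pd.DataFrame(index=cm.feature_ids, columns=DE_COLUMNS)
    res["base_mean"] = base_mean
    res["status"] = "ok"

    log2fc = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    wald = np.full(n_feat, np.nan)
    pval = np.full(n_feat, np.nan)
    status = np.array(["ok"] * n_feat, dtype=object)

    for i in range(n_feat):
        y = counts[i]
        if not y.any():
            status[i] = "low_count"
            continue
        fam = sm.families.NegativeBinomial(alpha=float(alpha[i]))
        try:
            fit = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
            beta, bse = fit.params[1], fit.bse[1]
            if not (np.isfinite(beta) and np.isfinite(bse) and bse > 0):
                raise ValueError("non-finite estimate")
        except Exception:
            status[i] = "failed"
            continue
        log2fc[i] = beta / LN2
        se[i] = bse / LN2
        wald[i] = beta / bse
        pval[i] = 2.0 * scipy.stats.norm.sf(abs(wald[i]))

    res["log2fc"], res["se"], res["wald_stat"], res["p"] = log2fc, se, wald, pval
    res["status"] = status
    padj = np.full(n_feat, np.nan)
    ok = status == "ok"
    padj[ok] = adjust_bh(pval[ok])
    res["padj"] = padj
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("fit_nb_continuous: %d of %d features excluded from BH "
                    "(low_count/failed)", n_bad, n_feat)
    return res


# ---------------------------------------------------------------------------
# two-group comparison (protein layer)
# ---------------------------------------------------------------------------

def fit_two_group(abundances: pd.DataFrame, groups: pd.Series,
                  adjust: bool = False) -> pd.DataFrame:
    """Welch t-test per feature on log2 abundances between two groups.

    ``log2fc`` is (mean of second group level) - (mean of first); p-values
    are reported raw by default, matching the protein layer's significance
    rule.
    """
    groups = groups.reindex(abundances.columns)
    levels = list(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a_cols = groups.index[groups == levels[0]]
    b_cols = groups.index[groups == levels[1]]

    res = pd.DataFrame(index=abundances.index, columns=DE_COLUMNS)
    for i, feat in enumerate(abundances.index):
        a = abundances.loc[feat, a_cols].dropna().to_numpy(float)
        b = abundances.loc[feat, b_cols].dropna().to_numpy(float)
        res.iat[i, 0] = np.nanmean(abundances.loc[feat].to_numpy(float))
        if len(a) < 2 or len(b) < 2:
            res.iat[i, 6] = "failed"
            continue
        lfc = float(np.mean(b) - np.mean(a))
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(np.mean(a), np.mean(b)):
            stat, p, sed = 0.0, 1.0, np.nan
        else:
            t = scipy.stats.ttest_ind(b, a, equal_var=False)
            stat, p = float(t.statistic), float(t.pvalue)
            sed = lfc / stat if stat != 0 else np.nan
        res.iloc[i, 1:6] = [lfc, sed, stat, p, np.nan]
        res.iat[i, 6] = "ok"
    ok = res["status"] == "ok"
    if adjust:
        res.loc[ok, "padj"] = adjust_bh(res.loc[ok, "p"].to_numpy(float))
    else:
        res.loc[ok, "padj"] = res.loc[ok, "p"]
    return res


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def pca_samples(norm_log: pd.DataFrame, n_top_features: int = 500,
                n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA on feature-centered log-normalized values, using the
    top-variance features.  Returns (coordinates, variance fractions)."""
    if norm_log.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    var = norm_log.var(axis=1)
    top = var.sort_values(ascending=False, kind="stable").index[:n_top_features]
    x = norm_log.loc[top].to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    k = min(n_components, min(x.T.shape))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x.T)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(coords, index=norm_log.columns, columns=cols),
            pca.explained_variance_ratio_)


def subtype_composition(cm: CountMatrix) -> pd.DataFrame:
    """Per-subtype fraction of total counts and number of distinct species."""
    if cm.n_features == 0 or cm.counts.to_numpy().sum() == 0:
        raise ValueError("cannot compute composition of an empty matrix")
    totals = cm.counts.sum(axis=1).groupby(cm.annotations["subtype"]).sum()
    species = cm.annotations.groupby("subtype").size()
    out = pd.DataFrame({
        "count_fraction": totals / totals.sum(),
        "n_species": species.reindex(totals.index).fillna(0).astype(int),
    })
    return out.sort_values("count_fraction", ascending=False)


def split_by_direction(de: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Significant features split by slope sign; log2fc == 0 joins neither."""
    sig = de[(de["padj"].astype(float) < alpha) & de["padj"].notna()]
    up = list(sig.index[sig["log2fc"].astype(float) > 0])
    down = list(sig.index[sig["log2fc"].astype(float) < 0])
    return up, down
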