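"""Negative-binomial differential ribosome-loading engine.

Per contrast, each gene is fit as a two-group NB model with log link, fixed
gene-wise dispersion alpha (variance = mu + alpha * mu**2) and per-sample
offsets log(size factor).  The group log-means are maximum-likelihood
estimates obtained by Fisher scoring; the Wald statistic is the difference of
group log2 means over its standard error, with a two-sided normal tail.
No fold-change shrinkage is applied, so the rescue comparison of absolute
log2 fold changes downstream is on the raw estimation scale.

Normalization is median-of-ratios to a geometric-mean pseudo-reference;
dispersion is a within-condition method-of-moments estimate pooled across
conditions, computed once on the full matrix and shared by every contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from trap_rescue.design import Contrast, conditions, validate_design
from trap_rescue.errors import ConfigError, DataError

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["base_mean", "log2fc", "se", "wald_p", "bh_q", "testable"]


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference set is genes with nonzero counts in every sample.  With
    ``pseudo_reference=True`` the geometric mean is instead taken over
    nonzero entries only (a fallback for sparse matrices).
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise DataError("counts must be nonnegative")
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        loggeo = np.nanmean(logx, axis=1)
        use = ~np.isnan(loggeo)
    else:
        use = (x > 0).all(axis=1)
        if not use.any():
            raise ConfigError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to fall back to a nonzero-entry reference"
            )
        loggeo = np.zeros(x.shape[0])
        loggeo[use] = np.log(x[use]).mean(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.log(x[use]) - loggeo[use, None]
    factors = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments dispersion on normalized counts, pooled across conditions.

    alpha_g = max(floor, (pooled within-condition variance - mean) / mean**2),
    variances weighted by within-condition degrees of freedom.  Conditions
    with fewer than 2 replicates contribute nothing.
    """
    design = validate_design(design)
    norm = counts / factors.reindex(counts.columns).to_numpy()
    ss = np.zeros(len(counts))
    df = 0
    used_samples: list[str] = []
    for _cond, samples in conditions(design).items():
        samples = [s for s in samples if s in counts.columns]
        if len(samples) < 2:
            continue
        sub = norm[samples].to_numpy()
        ss += sub.var(axis=1, ddof=1) * (len(samples) - 1)
        df += len(samples) - 1
        used_samples.extend(samples)
    if df == 0:
        raise DataError("no condition has >= 2 replicates; cannot estimate dispersion")
    pooled_var = ss / df
    mean = norm[used_samples].to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(mean > 0, alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")


def _fit_group(y: np.ndarray, f: np.ndarray, alpha: np.ndarray, max_iter: int = 100,
               tol: float = 1e-12):
    """Vectorized per-gene MLE of the group log-mean with fixed dispersion.

    y: genes x samples counts, f: size factors, alpha: per-gene dispersion.
    Returns (beta_hat, fisher_info, ok) where mu = f * exp(beta).  Genes with
    zero total count are flagged not-ok (log-mean unbounded below).
    """
    total = y.sum(axis=1)
    ok = total > 0
    beta = np.where(ok, np.log(np.maximum(total, 1) / f.sum()), 0.0)
    for _ in range(max_iter):
        mu = f[None, :] * np.exp(beta)[:, None]
        w = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.where(ok & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -10, 10)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = f[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info, ok


def wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    design: pd.DataFrame,
    contrast: Contrast,
) -> pd.DataFrame:
    """Two-group NB Wald test for one contrast.

    Returns per-gene base_mean, log2fc, se, wald_p, bh_q and a testable flag.
    Genes with zero counts throughout either group are not testable (their
    log fold change is unbounded); they are reported, not dropped.
    """
    design = validate_design(design)
    cond = conditions(design)
    for side in (contrast.numerator, contrast.denominator):
        if len(cond.get(side, [])) < 2:
            raise ConfigError(f"contrast {contrast.name}: condition {side} has <2 replicates")
    alpha = dispersions.reindex(counts.index).to_numpy()
    out = {}
    for label, side in (("num", contrast.numerator), ("den", contrast.denominator)):
        samples = cond[side]
        y = counts[samples].to_numpy(dtype=float)
        f = factors.reindex(samples).to_numpy(dtype=float)
        out[label] = _fit_group(y, f, alpha)
    b1, i1, ok1 = out["num"]
    b2, i2, ok2 = out["den"]
    testable = ok1 & ok2
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = (b1 - b2) / LN2
        se = np.sqrt(1.0 / i1 + 1.0 / i2) / LN2
        z = log2fc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    norm = counts / factors.reindex(counts.columns).to_numpy()
    both = cond[contrast.numerator] + cond[contrast.denominator]
    res = pd.DataFrame(
        {
            "base_mean": norm[both].mean(axis=1),
            "log2fc": np.where(testable, log2fc, np.nan),
            "se": np.where(testable, se, np.nan),
            "wald_p": np.where(testable, wald_p, np.nan),
            "testable": testable,
        },
        index=counts.index,
    )
    res["bh_q"] = bh_adjust(res["wald_p"])
    return res[DE_COLUMNS]


def bh_adjust(pvals) -> pd.Series:
    """Benjamini–Hochberg step-up q-values; NaN entries (not-testable genes)
    are excluded from the number of tests and returned as NaN."""
    p = pd.Series(pvals, dtype=float)
    mask = p.notna()
    vals = p[mask].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    if mask.any():
        q[mask] = multipletests(vals, method="fdr_bh")[1]
    return q
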