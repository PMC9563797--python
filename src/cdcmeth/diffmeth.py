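"""Paired differential methylation with empirical-Bayes moderated t-statistics.

The paired design is reduced to one-sample inference on the per-pair M-value
differences: for each CpG g the pair differences are modelled as
``dM_g ~ 1 (+ set-level covariates)`` by least squares, the per-CpG residual
variance s2_g is shrunk toward a prior via the scaled-inverse-chi-square
empirical Bayes model (prior df d0, prior variance s0^2, estimated by the
method of moments on log variances), and

    t_g = effect_g / sqrt(stilde2_g * v11),
    stilde2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g),

with p-values from a t distribution on d0 + d_g degrees of freedom
(d0 = inf gives the normal limit).  Benjamini-Hochberg controls the FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import MethylationMatrix, PairedDesign

__all__ = [
    "pair_differences",
    "fit_variance_prior",
    "moderated_t",
    "adjust_bh",
    "paired_stats",
]


def pair_differences(M: MethylationMatrix, design: PairedDesign) -> pd.DataFrame:
    """Per-pair mean(patient M) - mean(control M), one column per set.

    Multi-sample sets are averaged within role before differencing.
    """
    if design.n_pairs < 2:
        raise ValueError("need >= 2 pairs")
    vals = M.values
    missing = [s for s in design.all_samples() if s not in vals.columns]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing}")
    cols = {}
    for s in design.sets:
        cols[s.pair_id] = vals[s.patients].mean(axis=1) - vals[s.controls].mean(axis=1)
    return pd.DataFrame(cols, index=vals.index)


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0), by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Works on e_g = log s2_g - digamma(d_g/2) + log(d_g/2), whose theoretical
    mean is log s0^2 + digamma(d0/2) - log(d0/2) and whose excess variance
    over trigamma(d_g/2) is trigamma(d0/2).  Zero or negative excess spread
    means no evidence of variance heterogeneity: d0 = +inf.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    G = s2.size
    if G < 100:
        raise ValueError("need >= 100 CpGs with finite positive variance")
    e = np.log(s2) - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e) * G / (G - 1))
    excess = evar - _trigamma(d_g / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def moderated_t(
    dM: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moderated one-sample t on the pair differences.

    ``covariates`` (optional) is a pair x covariate frame aligned to the
    columns of ``dM``; the tested effect is the intercept of
    ``dM ~ 1 + covariates``.  ``prior`` is (d0, s0^2); when omitted it is
    estimated from the data by :func:`fit_variance_prior`.

    Returns a frame indexed by probe id with columns effect, s2, t, p,
    p_adj, direction, plus attrs d0, s02, df_residual.
    """
    n = dM.shape[1]
    if covariates is not None:
        cov = covariates.loc[list(dM.columns)].astype(float)
        X = np.column_stack([np.ones(n), cov.values])
    else:
        X = np.ones((n, 1))
    p_par = X.shape[1]
    if n < p_par + 1:
        raise ValueError("too few pairs for the requested covariates")
    if np.linalg.matrix_rank(X) < p_par:
        raise ValueError("rank-deficient covariate matrix")

    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T  # p x n
    Y = dM.values  # G x n
    coef = Y @ pinv.T  # G x p
    resid = Y - coef @ X.T
    d_g = n - p_par
    s2 = (resid**2).sum(axis=1) / d_g
    v11 = xtx_inv[0, 0]

    if prior is None:
        d0, s02 = fit_variance_prior(s2, d_g)
    else:
        d0, s02 = prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    effect = coef[:, 0]
    se = np.sqrt(s2_post * v11)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    # degenerate zero-variance, zero-effect CpGs (exactly constant input)
    t[(se == 0) & (effect == 0)] = 0.0
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "effect": effect,
            "s2": s2,
            "t": t,
            "p": p,
            "p_adj": adjust_bh(p),
            "direction": np.where(t < 0, "hypo", np.where(t > 0, "hyper", "none")),
        },
        index=dM.index,
    )
    out.attrs.update({"d0": d0, "s02": s02, "df_residual": d_g})
    return out


def paired_stats(
    M: MethylationMatrix,
    design: PairedDesign,
    covariates: list | None = None,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: pair differences + eBayes moderated t.

    ``covariates`` names columns of the design's set-level covariate frame
    to adjust for (e.g. ``["age_diff", "sex"]``).
    """
    dM = pair_differences(M, design)
    cov = None
    if covariates:
        cov = design.covariate_frame()[list(covariates)]
    return moderated_t(dM, cov, prior)
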