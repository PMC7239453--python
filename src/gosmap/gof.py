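"""Goodness-of-fit and predictive criteria: DIC, WAIC, CPO, Moran's I.

All four criteria operate on the M x N posterior log-likelihood matrix
(:func:`gosmap.models.loglik_matrix`) or on posterior residual summaries:

* DIC = 2 p_D - 2 log p(y | theta-bar), with the plug-in evaluated at the
  posterior mean of the linear predictor mu.
* WAIC = 2 sum_i { var_m[log p(y_i | theta^(m))] - log mean_m p(y_i | theta^(m)) },
  with p_W = sum_i var_m[log p] (the sample-variance penalty).
* CPO_i, the leave-one-out predictive ordinate, estimated by the harmonic
  mean of the per-draw likelihoods; models are compared on -sum_i log CPO_i,
  and areas with scaled CPO (CPO_i / max_j CPO_j) below 0.01 are flagged as
  poorly fit.
* Moran's I on the posterior-median residuals, with a two-sided p-value
  from the normal approximation, to check that no spatial autocorrelation
  remains after the structured effect is accounted for.

``compare_models`` applies the usual within-2 / within-7 DIC and WAIC bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .graph import AreaGraph

__all__ = ["GofResult", "dic", "waic", "cpo", "morans_i", "compare_models",
           "compute_gof"]


@dataclass
class GofResult:
    dic: float
    p_d: float
    waic: float
    p_w: float
    neg_sum_log_cpo: float
    cpo: np.ndarray
    scaled_cpo_flags: np.ndarray
    morans_i: float
    morans_p: float
    label: str = ""


def dic(loglik: np.ndarray, loglik_at_posterior_mean: np.ndarray):
    """Deviance information criterion from the log-likelihood matrix.

    p_D = mean posterior deviance minus the deviance at the plug-in;
    DIC = 2 p_D - 2 sum_i log p(y_i | theta-bar).
    """
    loglik = np.asarray(loglik, dtype=float)
    ll_bar = np.asarray(loglik_at_posterior_mean, dtype=float)
    mean_dev = float(np.mean(-2.0 * loglik.sum(axis=1)))
    dev_at_mean = float(-2.0 * ll_bar.sum())
    p_d = 0.5 * (mean_dev - dev_at_mean)
    return dev_at_mean + 2.0 * p_d, p_d


def waic(loglik: np.ndarray):
    """WAIC and its effective-parameter penalty p_W.

    p_W = sum_i var_m[log p(y_i | theta^(m))] (sample variance over draws);
    the log pointwise predictive density uses a max-shifted log-mean-exp.
    """
    loglik = np.asarray(loglik, dtype=float)
    m = loglik.shape[0]
    if m < 2:
        raise ValueError("WAIC needs at least 2 draws")
    p_w = float(np.var(loglik, axis=0, ddof=1).sum())
    lppd = float((logsumexp(loglik, axis=0) - np.log(m)).sum())
    return 2.0 * p_w - 2.0 * lppd, p_w


def cpo(loglik: np.ndarray):
    """Harmonic-mean estimate of the conditional predictive ordinates.

    CPO_i = [ mean_m 1 / p(y_i | theta^(m)) ]^{-1}, computed via a stable
    log-sum-exp of the negated log-likelihoods.  Areas with a non-finite
    harmonic term (a zero-likelihood draw) are excluded from the summary sum
    with a warning; the score reported is -sum_i log CPO_i.  Scaled flags
    mark areas with CPO_i / max_j CPO_j < 0.01.
    """
    loglik = np.asarray(loglik, dtype=float)
    m = loglik.shape[0]
    if m < 2:
        raise ValueError("CPO needs at least 2 draws")
    log_cpo = -(logsumexp(-loglik, axis=0) - np.log(m))
    cpo_i = np.exp(log_cpo)
    good = np.isfinite(log_cpo)
    if not good.all():
        warnings.warn(f"{int((~good).sum())} area(s) with zero-likelihood draws "
                      "excluded from the CPO sum", stacklevel=2)
    score = float(-log_cpo[good].sum())
    scaled = cpo_i / np.nanmax(np.where(good, cpo_i, np.nan))
    flags = good & (scaled < 0.01)
    return cpo_i, score, flags


def morans_i(resid, graph: AreaGraph):
    """Moran's I of a residual summary, with the normal-approximation test.

    I = (N / S0) sum_ij w_ij (e_i - ebar)(e_j - ebar) / sum_i (e_i - ebar)^2.
    The two-sided p-value uses E[I] = -1/(N-1) and the variance of I under
    the normality assumption.
    """
    e = np.asarray(resid, dtype=float)
    n = e.shape[0]
    z = e - e.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    W = graph.W
    s0 = float(W.sum())
    num = float(z @ (W @ z))
    i_stat = (n / s0) * num / denom
    # moments under normality for symmetric binary weights
    s1 = 2.0 * s0                      # 0.5 * sum (w_ij + w_ji)^2, binary symmetric
    deg = graph.degrees
    s2 = float(np.sum((2.0 * deg) ** 2))
    e_i = -1.0 / (n - 1)
    var_i = ((n**2 * s1 - n * s2 + 3.0 * s0**2)
             / (s0**2 * (n**2 - 1.0))) - e_i**2
    zscore = (i_stat - e_i) / np.sqrt(var_i)
    p = float(2.0 * norm.sf(abs(zscore)))
    return float(i_stat), p


def compare_models(results: list, morans_alpha: float = 0.05) -> pd.DataFrame:
    """Comparison table with best-model flags and within-2/7 bands.

    For DIC and WAIC, each variant is banded as "best", "within_2",
    "within_7" or "" relative to the minimum; the minimum -sum log CPO is
    flagged, and small Moran's I p-values are highlighted.
    """
    if not results:
        raise ValueError("need at least one model result")

    def band(vals):
        vals = np.asarray(vals, dtype=float)
        delta = vals - vals.min()
        out = np.where(delta == 0, "best",
                       np.where(delta <= 2, "within_2",
                                np.where(delta <= 7, "within_7", "")))
        return out

    df = pd.DataFrame({
        "label": [r.label for r in results],
        "dic": [r.dic for r in results],
        "p_d": [r.p_d for r in results],
        "waic": [r.waic for r in results],
        "p_w": [r.p_w for r in results],
        "neg_sum_log_cpo": [r.neg_sum_log_cpo for r in results],
        "morans_i": [r.morans_i for r in results],
        "morans_p": [r.morans_p for r in results],
    })
    df["dic_band"] = band(df["dic"])
    df["waic_band"] = band(df["waic"])
    cpo_vals = df["neg_sum_log_cpo"].to_numpy()
    df["cpo_best"] = cpo_vals == cpo_vals.min()
    df["morans_flag"] = df["morans_p"] < morans_alpha
    return df


def compute_gof(sample, data, graph: AreaGraph, label: str = "") -> GofResult:
    """All GoF criteria for one fitted model.

    The DIC plug-in evaluates the Poisson likelihood at the posterior mean
    of the linear predictor mu.  Moran's I uses the posterior-median
    residuals, matching the convention of the fraction of spatial variation.
    """
    from scipy.special import gammaln

    from .derived import compute_residuals
    from .models import loglik_matrix

    if sample.n_areas != data.n:
        raise ValueError("sample and data disagree on the number of areas")
    ll = loglik_matrix(sample, data)
    log_lam = np.log(data.E) + sample.mu.mean(axis=0)
    ll_bar = data.y * log_lam - np.exp(log_lam) - gammaln(data.y + 1.0)
    d, p_d = dic(ll, ll_bar)
    w, p_w = waic(ll)
    cpo_i, score, flags = cpo(ll)
    resid = compute_residuals(sample, data).median
    i_stat, p = morans_i(resid, graph)
    return GofResult(dic=d, p_d=p_d, waic=w, p_w=p_w, neg_sum_log_cpo=score,
                     cpo=cpo_i, scaled_cpo_flags=flags, morans_i=i_stat,
                     morans_p=p, label=label)
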