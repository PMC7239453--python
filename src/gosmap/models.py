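"""Bayesian spatial Poisson models for areal counts.

Two conditional-autoregressive models are provided for observed counts
``y_i ~ Poisson(E_i exp(mu_i))`` with expected counts ``E_i``:

* Leroux: ``mu_i = beta'x_i + s_i`` where the structured random effect s has
  full conditionals ``s_i | s_-i ~ N(rho sum_j w_ij s_j / (rho sum_j w_ij +
  1 - rho), sigma_s^2 / (rho sum_j w_ij + 1 - rho))`` with mixing parameter
  ``rho ~ Unif(0, 1)``.
* BYM (convolution): ``mu_i = beta'x_i + s_i + u_i`` with an intrinsic CAR
  (ICAR) prior for s — conditional mean the neighbour average, conditional
  variance ``sigma_s^2 / sum_j w_ij`` — and iid unstructured effects
  ``u_i ~ N(0, sigma_u^2)``, ``sigma_u^2 ~ N(0, 10)+``.

Regression coefficients carry N(0, sigma^2) priors with sigma^2 fixed at 100
by default.  The variance hyperprior for sigma_s^2 is either inverse-gamma
IG(alpha, eta) (shape/rate) or a left-truncated normal N(pi, nu)+; the
choice of hyperprior largely controls how strongly the fitted risk surface
is smoothed, which is exactly the behaviour the goodness-of-smoothing
statistics in :mod:`gosmap.gos` are designed to detect.

Fitting is by Metropolis-within-Gibbs: single-site random-walk Metropolis
for s (and u) vectorised over graph-colouring classes, coordinatewise
random-walk Metropolis for beta, conjugate Gibbs for sigma_s^2 under the IG
hyperprior, log-scale Metropolis under LTN, and Metropolis on logit(rho)
using the eigenvalue form of the Leroux precision determinant.  Step sizes
adapt by Robbins-Monro toward 40% acceptance during burn-in only, so
retained draws come from a fixed transition kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .graph import AreaGraph

__all__ = [
    "AreaData",
    "HyperpriorConfig",
    "ModelSpec",
    "McmcConfig",
    "PosteriorSample",
    "sample_leroux",
    "sample_bym",
    "rescale_bym_identifiability",
    "loglik_matrix",
    "variant_grid",
]

_MU_CLIP = 40.0  # |log relative risk| bound guarding exp overflow in proposals


@dataclass
class AreaData:
    """Observed/expected counts and covariates for N areas.

    ``X`` must include the intercept column; ``covariates(names)`` helpers
    are deliberately omitted — construct X explicitly.
    """

    y: np.ndarray
    E: np.ndarray
    X: np.ndarray
    area_ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            self.X = self.X.T
        if self.E.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("y, E and X have inconsistent lengths")
        if np.any(self.E <= 0):
            raise ValueError("expected counts E must be positive")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)) or not np.all(np.isfinite(self.y)):
            raise ValueError("y must be non-negative integer counts with no missing values")
        if self.area_ids is not None and len(self.area_ids) != n:
            raise ValueError("area_ids length mismatch")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def raw_sir(self) -> np.ndarray:
        """Observed standardised incidence ratio y/E."""
        return self.y / self.E


@dataclass
class HyperpriorConfig:
    """Hyperprior for sigma_s^2 plus the fixed pieces of the prior layer.

    family "ig": sigma_s^2 ~ IG(alpha, eta), shape/rate.
    family "ltn": sigma_s^2 ~ N(pi, nu) truncated to (0, inf), mean/variance.
    ``beta_prior_variance`` is sigma^2 in beta_k ~ N(0, sigma^2), fixed at
    100.  ``u_variance_prior`` is the (mean, variance) of the N(., .)+ prior
    for sigma_u^2 in the BYM model, default (0, 10).
    """

    family: str = "ig"
    alpha: float = 1.0
    eta: float = 0.01
    pi: float = 0.0
    nu: float = 1.0
    beta_prior_variance: float = 100.0
    u_variance_prior: tuple = (0.0, 10.0)

    def __post_init__(self) -> None:
        if self.family not in ("ig", "ltn"):
            raise ValueError(f"unknown hyperprior family {self.family!r}")
        if self.family == "ig" and (self.alpha <= 0 or self.eta <= 0):
            raise ValueError("IG shape and rate must be positive")
        if self.family == "ltn" and self.nu <= 0:
            raise ValueError("LTN variance nu must be positive")
        if self.beta_prior_variance <= 0:
            raise ValueError("beta prior variance must be positive")


@dataclass
class ModelSpec:
    model: str = "leroux"  # "leroux" | "bym"
    hyperprior: HyperpriorConfig = field(default_factory=HyperpriorConfig)

    def __post_init__(self) -> None:
        if self.model not in ("leroux", "bym"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class McmcConfig:
    iterations: int = 20_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.iterations, self.burn_in + 1, self.thinning) < 1:
            raise ValueError("iterations, burn_in, thinning must be positive")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.n_draws < 2:
            raise ValueError("need at least 2 retained draws")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorSample:
    """Retained MCMC draws; M rows, one per retained iteration."""

    model: str
    beta: np.ndarray           # M x (k+1)
    s: np.ndarray              # M x N structured effects
    mu: np.ndarray             # M x N log relative risks
    sigma_s2: np.ndarray       # M
    u: np.ndarray | None = None        # M x N, BYM only
    sigma_u2: np.ndarray | None = None  # M, BYM only
    rho: np.ndarray | None = None       # M, Leroux only
    area_ids: list | None = None
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def n_areas(self) -> int:
        return self.mu.shape[1]


# ---------------------------------------------------------------------------
# hyperprior log-densities (unnormalised) for the Metropolis variance updates


def _log_hyperprior(sig2: float, hp: HyperpriorConfig) -> float:
    if sig2 <= 0:
        return -np.inf
    if hp.family == "ig":
        return -(hp.alpha + 1.0) * np.log(sig2) - hp.eta / sig2
    return -0.5 * (sig2 - hp.pi) ** 2 / hp.nu


def _log_ltn(sig2: float, mean: float, var: float) -> float:
    if sig2 <= 0:
        return -np.inf
    return -0.5 * (sig2 - mean) ** 2 / var


class _Adapt:
    """Robbins-Monro log-step adaptation toward a target acceptance rate."""

    def __init__(self, shape, step: float = 0.3, target: float = 0.4):
        self.log_step = np.full(shape, np.log(step))
        self.target = target

    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, accepted, t: int, idx=None) -> None:
        gain = (t + 1.0) ** -0.6
        delta = gain * (np.asarray(accepted, dtype=float) - self.target)
        if idx is None:
            self.log_step += delta
        else:
            self.log_step[idx] += delta
        np.clip(self.log_step, np.log(1e-5), np.log(50.0), out=self.log_step)


def _init_sigma2(hp: HyperpriorConfig) -> float:
    if hp.family == "ig":
        guess = hp.eta / (hp.alpha + 1.0)  # prior mode
    else:
        guess = max(hp.pi, np.sqrt(hp.nu) / 2.0)
    return float(np.clip(guess, 1e-4, 10.0))


def _sampler(data: AreaData, graph: AreaGraph, spec: ModelSpec, mcmc: McmcConfig) -> PosteriorSample:
    bym = spec.model == "bym"
    hp = spec.hyperprior
    rng = np.random.default_rng(mcmc.seed)
    y, E, X = data.y, data.E, data.X
    N, p = X.shape
    if graph.n != N:
        raise ValueError("graph and data disagree on the number of areas")
    W = graph.W
    deg = graph.degrees
    colors = graph.coloring()
    if bym and graph.isolated.any():
        raise ValueError("BYM/ICAR requires every area to have at least one neighbour")

    if bym:
        icar_rank = N - graph.n_components
    else:
        # eigenvalues of D - W give log det(rho (D-W) + (1-rho) I)
        lap_eigs = np.linalg.eigvalsh((sp.diags(deg) - W).toarray())

    # initial state: intercept at the overall log-SIR, everything else flat
    beta = np.zeros(p)
    beta[0] = np.log(max(y.sum(), 0.5) / E.sum())
    s = np.zeros(N)
    u = np.zeros(N)
    rho = 0.5
    sig_s2 = _init_sigma2(hp)
    sig_u2 = 1.0
    bx = X @ beta
    logE = np.log(E)

    ad_s = _Adapt(N)
    ad_u = _Adapt(N)
    ad_b = _Adapt(p, step=0.1)
    ad_sig = _Adapt((), step=0.5)
    ad_sigu = _Adapt((), step=0.5)
    ad_rho = _Adapt((), step=0.5)

    M = mcmc.n_draws
    out_beta = np.empty((M, p))
    out_s = np.empty((M, N))
    out_mu = np.empty((M, N))
    out_sig = np.empty(M)
    out_u = np.empty((M, N)) if bym else None
    out_sigu = np.empty(M) if bym else None
    out_rho = None if bym else np.empty(M)
    acc_count = {"s": 0.0, "beta": 0.0, "u": 0.0, "scalar": 0.0}

    def pois_delta(idx, eta_old, eta_new):
        """Change in Poisson log-likelihood when mu[idx] moves eta_old->eta_new."""
        lam_old = np.exp(np.clip(logE[idx] + eta_old, -_MU_CLIP, _MU_CLIP))
        lam_new = np.exp(np.clip(logE[idx] + eta_new, -_MU_CLIP, _MU_CLIP))
        return y[idx] * (eta_new - eta_old) - (lam_new - lam_old)

    def quad_forms(svec):
        sDWs = float(svec @ (deg * svec) - svec @ (W @ svec))
        return sDWs, float(svec @ svec)

    adapting = True
    keep = 0
    for t in range(mcmc.iterations):
        if t == mcmc.burn_in:
            adapting = False

        # --- structured effects s, one colour class at a time
        for idx in colors:
            if bym:
                cond_prec = deg[idx] / sig_s2
                cond_mean = (W[idx] @ s) / deg[idx]
            else:
                denom = rho * deg[idx] + (1.0 - rho)
                cond_prec = denom / sig_s2
                cond_mean = rho * (W[idx] @ s) / denom
            prop = s[idx] + ad_s.step()[idx] * rng.standard_normal(idx.size)
            base = bx[idx] + (u[idx] if bym else 0.0)
            dlp = pois_delta(idx, base + s[idx], base + prop)
            dlp -= 0.5 * cond_prec * ((prop - cond_mean) ** 2 - (s[idx] - cond_mean) ** 2)
            acc = np.log(rng.random(idx.size)) < dlp
            s[idx] = np.where(acc, prop, s[idx])
            if adapting:
                ad_s.update(acc, t, idx)
            acc_count["s"] += acc.mean() / len(colors)

        if bym:
            # ICAR impropriety: recentre s, shift the mean into the intercept
            sbar = s.mean()
            s -= sbar
            beta[0] += sbar
            bx += sbar

            # --- unstructured effects u (iid given the rest: one shot)
            prop = u + ad_u.step() * rng.standard_normal(N)
            dlp = pois_delta(slice(None), bx + s + u, bx + s + prop)
            dlp -= 0.5 * (prop**2 - u**2) / sig_u2
            acc = np.log(rng.random(N)) < dlp
            u = np.where(acc, prop, u)
            if adapting:
                ad_u.update(acc, t)
            acc_count["u"] += acc.mean()

        # --- regression coefficients, coordinatewise
        latent = s + u if bym else s
        for j in range(p):
            propj = beta[j] + ad_b.step()[j] * rng.standard_normal()
            delta = X[:, j] * (propj - beta[j])
            dlp = float(np.sum(pois_delta(slice(None), bx + latent, bx + latent + delta)))
            dlp -= 0.5 * (propj**2 - beta[j] ** 2) / hp.beta_prior_variance
            accj = np.log(rng.random()) < dlp
            if accj:
                beta[j] = propj
                bx = bx + delta
                acc_count["beta"] += 1.0 / p
            if adapting:
                ad_b.update(float(accj), t, j)

        # --- sigma_s^2
        sDWs, ss = quad_forms(s)
        if bym:
            quad = sDWs
            rank = icar_rank
        else:
            quad = rho * sDWs + (1.0 - rho) * ss
            rank = N
        if hp.family == "ig":
            sig_s2 = 1.0 / rng.gamma(hp.alpha + 0.5 * rank, 1.0 / (hp.eta + 0.5 * quad))
        else:
            prop = sig_s2 * np.exp(ad_sig.step() * rng.standard_normal())
            num = -0.5 * rank * np.log(prop) - 0.5 * quad / prop + _log_hyperprior(prop, hp) + np.log(prop)
            den = -0.5 * rank * np.log(sig_s2) - 0.5 * quad / sig_s2 + _log_hyperprior(sig_s2, hp) + np.log(sig_s2)
            accd = np.log(rng.random()) < num - den
            if accd:
                sig_s2 = float(prop)
            if adapting:
                ad_sig.update(float(accd), t)

        if bym:
            # --- sigma_u^2 under its N(0, 10)+ prior
            uu = float(u @ u)
            mean_u, var_u = hp.u_variance_prior
            prop = sig_u2 * np.exp(ad_sigu.step() * rng.standard_normal())
            num = -0.5 * N * np.log(prop) - 0.5 * uu / prop + _log_ltn(prop, mean_u, var_u) + np.log(prop)
            den = -0.5 * N * np.log(sig_u2) - 0.5 * uu / sig_u2 + _log_ltn(sig_u2, mean_u, var_u) + np.log(sig_u2)
            accd = np.log(rng.random()) < num - den
            if accd:
                sig_u2 = float(prop)
            if adapting:
                ad_sigu.update(float(accd), t)
        else:
            # --- rho on the logit scale; log det via Laplacian eigenvalues
            logit = np.log(rho) - np.log1p(-rho)
            prop_logit = logit + ad_rho.step() * rng.standard_normal()
            prop_rho = float(np.clip(1.0 / (1.0 + np.exp(-prop_logit)), 1e-12, 1.0 - 1e-12))

            def rho_target(r):
                evals = r * lap_eigs + (1.0 - r)
                return (
                    0.5 * np.sum(np.log(np.maximum(evals, 1e-300)))
                    - 0.5 * (r * sDWs + (1.0 - r) * ss) / sig_s2
                    + np.log(r) + np.log1p(-r)  # Unif(0,1) prior + logit Jacobian
                )

            accd = np.log(rng.random()) < rho_target(prop_rho) - rho_target(rho)
            if accd:
                rho = float(prop_rho)
            if adapting:
                ad_rho.update(float(accd), t)

        if t >= mcmc.burn_in and (t - mcmc.burn_in) % mcmc.thinning == 0 and keep < M:
            out_beta[keep] = beta
            out_s[keep] = s
            out_mu[keep] = bx + s + (u if bym else 0.0)
            out_sig[keep] = sig_s2
            if bym:
                out_u[keep] = u
                out_sigu[keep] = sig_u2
            else:
                out_rho[keep] = rho
            keep += 1

    acceptance = {k: v / mcmc.iterations for k, v in acc_count.items()}
    return PosteriorSample(
        model=spec.model,
        beta=out_beta,
        s=out_s,
        mu=out_mu,
        sigma_s2=out_sig,
        u=out_u,
        sigma_u2=out_sigu,
        rho=out_rho,
        area_ids=list(graph.area_ids),
        acceptance=acceptance,
    )


def sample_leroux(data: AreaData, graph: AreaGraph, spec: ModelSpec, mcmc: McmcConfig) -> PosteriorSample:
    """Fit the Leroux model; returns retained posterior draws.

    Seeded runs are bit-reproducible.  Isolated areas are permitted: their
    conditional prior degenerates to N(0, sigma_s^2/(1 - rho)).
    """
    if spec.model != "leroux":
        raise ValueError("spec.model must be 'leroux'")
    return _sampler(data, graph, spec, mcmc)


def sample_bym(data: AreaData, graph: AreaGraph, spec: ModelSpec, mcmc: McmcConfig) -> PosteriorSample:
    """Fit the BYM convolution model; s is recentred to sum to zero at every
    iteration (the ICAR prior is improper) with the mean shifted into the
    intercept, so ``mu`` is unaffected."""
    if spec.model != "bym":
        raise ValueError("spec.model must be 'bym'")
    return _sampler(data, graph, spec, mcmc)


def rescale_bym_identifiability(sample: PosteriorSample) -> PosteriorSample:
    """Reallocate (s, u) per draw by the standard-deviation ratio.

    The BYM structured and unstructured effects are only identified through
    their sum.  For each draw the total t = s + u is split as
    s* = w t, u* = (1 - w) t with w = sd(s) / (sd(s) + sd(u)), preserving
    s + u (and hence mu) elementwise.  Draws where both fields are constant
    are left unchanged.
    """
    if sample.model != "bym" or sample.u is None:
        raise ValueError("identifiability rescaling applies to BYM samples only")
    sd_s = sample.s.std(axis=1, ddof=1)
    sd_u = sample.u.std(axis=1, ddof=1)
    tot = sd_s + sd_u
    w = np.where(tot > 0, sd_s / np.where(tot > 0, tot, 1.0), np.nan)
    t = sample.s + sample.u
    new_s = np.where(np.isnan(w)[:, None], sample.s, w[:, None] * t)
    new_u = np.where(np.isnan(w)[:, None], sample.u, (1.0 - w)[:, None] * t)
    return replace(sample, s=new_s, u=new_u)


def loglik_matrix(sample: PosteriorSample, data: AreaData) -> np.ndarray:
    """M x N matrix of Poisson log-pmf values log p(y_i | mu_i^(m)).

    Entry (m, i) is the log-pmf of y_i under mean E_i exp(mu_i^(m)).
    """
    if sample.n_areas != data.n:
        raise ValueError("sample and data disagree on the number of areas")
    log_lam = np.log(data.E)[None, :] + sample.mu
    lam = np.exp(np.clip(log_lam, -700, 700))
    y = data.y[None, :]
    return y * log_lam - lam - gammaln(y + 1.0)


# ---------------------------------------------------------------------------
# Posterior draw serialisation: one CSV per parameter block plus a manifest


def save_draws(sample: PosteriorSample, directory) -> None:
    """Write posterior draws as CSVs with a JSON manifest (round-trips)."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blocks = {"beta": sample.beta, "s": sample.s, "mu": sample.mu,
              "sigma_s2": sample.sigma_s2}
    if sample.u is not None:
        blocks["u"] = sample.u
    if sample.sigma_u2 is not None:
        blocks["sigma_u2"] = sample.sigma_u2
    if sample.rho is not None:
        blocks["rho"] = sample.rho
    for name, arr in blocks.items():
        pd.DataFrame(np.atleast_2d(arr.T).T).to_csv(directory / f"{name}.csv", index=False)
    manifest = {
        "model": sample.model,
        "n_draws": sample.n_draws,
        "n_areas": sample.n_areas,
        "area_ids": [str(a) for a in (sample.area_ids or [])],
        "blocks": sorted(blocks),
        "acceptance": sample.acceptance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_draws(directory) -> PosteriorSample:
    """Read back a draw archive written by :func:`save_draws`."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())

    def block(name, squeeze=False):
        arr = pd.read_csv(directory / f"{name}.csv").to_numpy(dtype=float)
        return arr.ravel() if squeeze else arr

    return PosteriorSample(
        model=manifest["model"],
        beta=block("beta"),
        s=block("s"),
        mu=block("mu"),
        sigma_s2=block("sigma_s2", squeeze=True),
        u=block("u") if "u" in manifest["blocks"] else None,
        sigma_u2=block("sigma_u2", squeeze=True) if "sigma_u2" in manifest["blocks"] else None,
        rho=block("rho", squeeze=True) if "rho" in manifest["blocks"] else None,
        area_ids=manifest["area_ids"] or None,
        acceptance=manifest.get("acceptance", {}),
    )


# ---------------------------------------------------------------------------
# The twelve-variant hyperprior grid


def variant_grid(family: str = "ig") -> dict:
    """Twelve labelled hyperprior settings, A (strongest smoothing) to L
    (most diffuse).

    The grid spans strongly informative small-variance priors for sigma_s^2,
    which force the structured effect toward its conditional mean
    (over-smoothing), through to very diffuse priors that let the field
    chase the raw rates (under-smoothing).  Labels are approximately ordered
    in descending order of smoothing intensity.
    """
    labels = "ABCDEFGHIJKL"
    if family == "ig":
        # (shape alpha, rate eta): prior mass over sigma_s^2 rises left to right
        grid = [
            (2000.0, 1.0), (500.0, 1.0), (200.0, 1.0), (100.0, 1.0),
            (50.0, 1.0), (20.0, 1.0), (10.0, 1.0), (5.0, 1.0),
            (2.0, 0.6), (1.0, 0.5), (1.0, 1.0), (0.5, 1.5),
        ]
        return {
            lab: HyperpriorConfig(family="ig", alpha=a, eta=e)
            for lab, (a, e) in zip(labels, grid)
        }
    if family == "ltn":
        # (mean pi, variance nu) of N(pi, nu)+ on sigma_s^2
        grid = [
            (0.001, 1e-6), (0.005, 1e-5), (0.01, 1e-4), (0.05, 1e-4),
            (0.1, 1e-3), (0.2, 1e-2), (0.5, 1e-2), (0.5, 0.1),
            (1.0, 0.1), (1.0, 1.0), (2.0, 4.0), (5.0, 25.0),
        ]
        return {
            lab: HyperpriorConfig(family="ltn", pi=m, nu=v)
            for lab, (m, v) in zip(labels, grid)
        }
    raise ValueError(f"unknown hyperprior family {family!r}")
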