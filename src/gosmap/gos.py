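"""Goodness-of-smoothing (GoS) statistics and their PASS/FAIL criteria.

Classical model-choice criteria measure fit; none of them ask whether a
spatial model smoothed the risk surface too much or too little.  Five
complementary statistics quantify the degree of smoothing a fitted model
applied, each comparing the smoothed covariate-adjusted SIR (CASIR) against
its raw baseline (CARSIR) or probing the smoothed surface directly:

1. **Ratio of variograms** — areal variograms on the boundary-crossing
   distance; the ratio of the CASIR to CARSIR variogram, averaged over lags.
   Near 0: the smoothed surface is flat (over-smoothing); near 1: as rough
   as the raw data (under-smoothing).
2. **Kurtosis preservation** — smooth as much as possible (low roughness of
   the neighbour-mean deviations) while the spatial excess kurtosis of the
   smoothed SIR stays at least that of the raw SIR, so rare large deviations
   survive the smoothing.
3. **Cohen's kappa** on quantile categories of CASIR vs CARSIR: small kappa
   means heavy smoothing, kappa near 1 means almost none.
4. **Fraction of spatial variation** psi = Var(s*) / (Var(s*) + Var(eps*)),
   from per-area posterior medians.
5. **Relative position of CASIR** — where each area's CASIR estimate sits
   between its raw baseline (0 = no shrinkage) and the posterior mean of the
   neighbours' CASIR (1 = maximal shrinkage).

Three named cut-off profiles turn the statistics into PASS/FAIL flags:
``u`` (unbiased), ``c`` (conservative) and ``pu`` (penalise
under-smoothing).  A consensus count over the variogram-ratio, kappa and
relative-position criteria under ``pu`` drives model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import AreaGraph, BoundaryDistanceMatrix, neighbor_mean
from .derived import DerivedSurfaces
from .models import AreaData, PosteriorSample

__all__ = [
    "VariogramResult", "ConfusionMatrix", "GosResult", "CutoffProfile",
    "variogram", "variogram_ratio", "spatial_excess_kurtosis", "roughness",
    "kurtosis_preservation", "quantile_categorize", "confusion_matrix",
    "cohens_kappa", "kappa_gos", "fraction_spatial_variation",
    "relative_position_casir", "apply_cutoffs", "consensus", "compute_gos",
    "PROFILES", "default_max_lag",
]


# ---------------------------------------------------------------------------
# Variograms on boundary-crossing distance


@dataclass
class VariogramResult:
    lags: np.ndarray          # 1..H
    gamma_area: np.ndarray    # N x H, NaN where N_i(h) = 0
    counts: np.ndarray        # N x H pair counts N_i(h)
    gamma_mean: np.ndarray    # H, average over areas with N_i(h) > 0


def variogram(z, d: BoundaryDistanceMatrix, H: int) -> VariogramResult:
    """Areal variogram gamma_i(h) = sum_{d_ij <= h, j != i} (z_i - z_j)^2 / (2 N_i(h)).

    Pairs are included when the boundary-crossing distance is at most the
    lag h.  Areas with no pairs at some lag are flagged NaN and excluded
    from the lag average gamma(h).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    if H < 1:
        raise ValueError("H must be >= 1")
    n = z.shape[0]
    sq = (z[:, None] - z[None, :]) ** 2
    reach = (d.d > 0) & ~d.unreachable  # j != i, reachable
    lags = np.arange(1, H + 1)
    gamma_area = np.full((n, H), np.nan)
    counts = np.zeros((n, H), dtype=int)
    for k, h in enumerate(lags):
        inc = reach & (d.d <= h)
        c = inc.sum(axis=1)
        counts[:, k] = c
        with np.errstate(invalid="ignore", divide="ignore"):
            g = (sq * inc).sum(axis=1) / (2.0 * c)
        gamma_area[:, k] = np.where(c > 0, g, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gamma_mean = np.nanmean(gamma_area, axis=0)
    return VariogramResult(lags=lags, gamma_area=gamma_area, counts=counts,
                           gamma_mean=gamma_mean)


def default_max_lag(d: BoundaryDistanceMatrix, cap: int = 10) -> int:
    """Default H: the graph diameter (largest finite distance), capped."""
    finite = d.d[(d.d > 0) & ~d.unreachable]
    if finite.size == 0:
        raise ValueError("graph has no reachable pairs")
    return int(min(int(finite.max()), cap))


def variogram_ratio(casir, carsir, d: BoundaryDistanceMatrix,
                    H: int | None = None) -> float:
    """Mean over lags of gamma_CASIR(h) / gamma_CARSIR(h).

    Both variograms are averaged over areas at each lag before taking the
    ratio; lags with a zero CARSIR variogram are excluded with a warning.
    """
    if H is None:
        H = default_max_lag(d)
    v_num = variogram(casir, d, H).gamma_mean
    v_den = variogram(carsir, d, H).gamma_mean
    ok = np.isfinite(v_num) & np.isfinite(v_den) & (v_den > 0)
    if not ok.any():
        raise ValueError("all lags excluded: CARSIR variogram is zero everywhere")
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} lag(s) excluded from the variogram ratio", stacklevel=2)
    return float(np.mean(v_num[ok] / v_den[ok]))


# ---------------------------------------------------------------------------
# Kurtosis preservation


def _deviations(z, graph: AreaGraph) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev = z - neighbor_mean(graph, z)
    return dev[~graph.isolated]


def spatial_excess_kurtosis(z, graph: AreaGraph) -> float:
    """Excess kurtosis of the deviations from the first-order neighbour mean.

    Kurt = E[(z_i - zbar(w_i))^4] / E[(z_i - zbar(w_i))^2]^2 - 3, with the
    expectations taken as plain averages over areas with neighbours.  Large
    values mean the spatial variation is dominated by infrequent, extreme
    deviations.
    """
    dev = _deviations(z, graph)
    if dev.size < 3:
        raise ValueError("need at least 3 areas with neighbours")
    m2 = np.mean(dev**2)
    if m2 == 0:
        raise ValueError("constant field: spatial kurtosis undefined")
    return float(np.mean(dev**4) / m2**2 - 3.0)


def roughness(z, graph: AreaGraph) -> float:
    """Sample standard deviation of the neighbour-mean deviations."""
    dev = _deviations(z, graph)
    return float(np.std(dev, ddof=1))


def kurtosis_preservation(smoothed_sir, raw_sir, graph: AreaGraph):
    """Kurtosis of the smoothed and raw SIR plus roughness of the smoothed SIR.

    The PASS rule (applied in :func:`apply_cutoffs`) requires the smoothed
    kurtosis to be at least the raw kurtosis, and the smoothed roughness to
    be within the profile's tolerance of the minimum roughness across the
    set of compared models.
    """
    return (
        spatial_excess_kurtosis(smoothed_sir, graph),
        spatial_excess_kurtosis(raw_sir, graph),
        roughness(smoothed_sir, graph),
    )


# ---------------------------------------------------------------------------
# Kappa


@dataclass
class ConfusionMatrix:
    c: np.ndarray  # K x K counts

    @property
    def n(self) -> int:
        return int(self.c.sum())


def quantile_categorize(z, probs=(0.25, 0.75)) -> np.ndarray:
    """Categorise a vector by its own empirical quantiles.

    ``probs`` are the cut probabilities (strictly increasing, in (0,1));
    the result has K = len(probs) + 1 integer categories 0..K-1 assigned by
    half-open intervals [q_{k-1}, q_k) of the type-7 empirical quantiles.
    """
    z = np.asarray(z, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0 or np.any(np.diff(probs) <= 0) \
            or probs[0] <= 0 or probs[-1] >= 1:
        raise ValueError("probs must be strictly increasing within (0, 1)")
    if np.ptp(z) == 0:
        warnings.warn("degenerate vector: all areas fall in one category", stacklevel=2)
        return np.zeros(z.shape[0], dtype=int)
    cuts = np.quantile(z, probs)  # type-7 (linear interpolation) quantiles
    return np.searchsorted(cuts, z, side="right")


def confusion_matrix(a, b) -> ConfusionMatrix:
    """Cross-tabulation over the shared category universe of ``a`` and ``b``."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("categorisations must have equal length")
    cats = np.unique(np.concatenate([a, b]))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    k = cats.size
    c = np.zeros((k, k), dtype=int)
    np.add.at(c, (ai, bi), 1)
    return ConfusionMatrix(c=c)


def cohens_kappa(a, b) -> float:
    """kappa = (Pr(Ao) - Pr(Ae)) / (1 - Pr(Ae)).

    Pr(Ao) is the observed agreement (diagonal of the confusion matrix) and
    Pr(Ae) the chance agreement from the row/column marginal products.
    """
    cm = confusion_matrix(a, b)
    n = cm.n
    pr_o = np.trace(cm.c) / n
    pr_e = float(cm.c.sum(axis=1) @ cm.c.sum(axis=0)) / n**2
    if pr_e >= 1.0:
        raise ValueError("degenerate marginals (Pr(Ae) = 1): kappa undefined")
    return float((pr_o - pr_e) / (1.0 - pr_e))


def kappa_gos(casir, carsir, n_categories: int = 3) -> float:
    """Kappa between quantile categories of CASIR and CARSIR (the baseline).

    3 categories use cuts (0.25, 0.75); 5 categories use (0.1, 0.3, 0.7,
    0.9).  Smaller values indicate greater smoothing.
    """
    probs = {3: (0.25, 0.75), 5: (0.1, 0.3, 0.7, 0.9)}.get(n_categories)
    if probs is None:
        raise ValueError("n_categories must be 3 or 5")
    return cohens_kappa(quantile_categorize(casir, probs),
                        quantile_categorize(carsir, probs))


# ---------------------------------------------------------------------------
# Fraction of spatial variation


def fraction_spatial_variation(sample: PosteriorSample, data: AreaData) -> float:
    """psi = Var(s*) / (Var(s*) + Var(eps*)) in [0, 1].

    Per-area posterior medians s*_i and eps*_i are taken first; the
    variances over areas use divisor N - 1.  For BYM the residuals already
    exclude the unstructured effect, which is treated as spatial noise.
    """
    from .derived import compute_residuals

    s_star = np.median(sample.s, axis=0)
    e_star = compute_residuals(sample, data).median
    vs = float(np.var(s_star, ddof=1))
    ve = float(np.var(e_star, ddof=1))
    if vs + ve == 0:
        raise ValueError("both variance components are zero: psi undefined")
    return vs / (vs + ve)


# ---------------------------------------------------------------------------
# Relative position of CASIR


@dataclass
class RelativePosition:
    r: np.ndarray              # raw relative positions, NaN where excluded
    capped: np.ndarray         # capped values for summaries
    excluded: np.ndarray       # bool mask
    reasons: np.ndarray        # '', 'zero_count', 'narrow_range', 'isolated'


def relative_position_casir(sample: PosteriorSample, data: AreaData,
                            graph: AreaGraph, min_log_range: float = 0.03,
                            cap: tuple = (-0.2, 1.2),
                            scale: str = "log") -> RelativePosition:
    """Where each CASIR estimate sits between no shrinkage and full shrinkage.

    The lower endpoint (position 0) is the raw baseline CARSIR_i; the upper
    endpoint (position 1) is the posterior mean of the neighbours' CASIR,
    estimated as the neighbour mean of the posterior-mean CASIR surface.
    Computed on the log scale by default:
    r_i = (log CASIR_i - log CARSIR_i) / (log m_i - log CARSIR_i).

    Areas are excluded when y_i = 0 (CARSIR undefined as a baseline on the
    log scale), when the log-range of potential values is below
    ``min_log_range``, or when the area has no neighbours.  Values are
    capped to ``cap`` for summaries only.
    """
    from .derived import compute_casir, compute_carsir

    casir = compute_casir(sample).mean
    carsir = compute_carsir(sample, data).mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = neighbor_mean(graph, casir)
    n = data.n
    reasons = np.full(n, "", dtype=object)
    reasons[graph.isolated] = "isolated"
    zero = carsir <= 0
    reasons[zero & (reasons == "")] = "zero_count"
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == "log":
            denom = np.log(m) - np.log(carsir)
            numer = np.log(casir) - np.log(carsir)
        elif scale == "linear":
            denom = m - carsir
            numer = casir - carsir
        else:
            raise ValueError(f"unknown scale {scale!r}")
    narrow = np.abs(denom) < min_log_range
    reasons[narrow & (reasons == "")] = "narrow_range"
    excluded = reasons != ""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(excluded, np.nan, numer / np.where(denom == 0, np.nan, denom))
    capped = np.clip(r, cap[0], cap[1])
    return RelativePosition(r=r, capped=capped, excluded=excluded, reasons=reasons)


# ---------------------------------------------------------------------------
# Cut-off profiles and PASS/FAIL flags


@dataclass(frozen=True)
class CutoffProfile:
    """One named set of GoS cut-offs.

    ``kurtosis_tol`` is the fractional roughness tolerance (roughness must
    be below the comparison-set minimum times 1 + tol); None disables the
    kurtosis criterion for the profile.
    """

    name: str
    variogram_bounds: tuple
    kappa_bounds: tuple
    relpos_proportion: float
    relpos_bounds: tuple
    kurtosis_tol: float | None = None


PROFILES = {
    "u": CutoffProfile("u", (0.2, 0.8), (0.05, 0.95), 0.75, (0.01, 0.99), 0.30),
    "c": CutoffProfile("c", (0.25, 0.75), (0.1, 0.9), 0.85, (0.02, 0.98), 0.10),
    "pu": CutoffProfile("pu", (0.1, 0.4), (0.05, 0.7), 0.75, (0.2, 0.98), None),
}


@dataclass
class GosResult:
    """The five GoS statistics for one fitted model variant."""

    variogram_ratio: float
    kurtosis_smoothed: float
    kurtosis_raw: float
    roughness: float
    kappa3: float
    kappa5: float
    psi: float
    rel_pos: RelativePosition
    label: str = ""
    flags: dict = field(default_factory=dict)  # profile -> criterion -> bool


def apply_cutoffs(result: GosResult, profile: CutoffProfile,
                  comparison_set: list | None = None) -> dict:
    """PASS/FAIL per criterion under one cut-off profile.

    ``comparison_set`` supplies the other models' GosResults for the
    roughness-minimum part of the kurtosis criterion; a singleton comparison
    degenerates to PASS with a warning.  Flags are stored on ``result`` and
    returned.
    """
    lo, hi = profile.variogram_bounds
    flags = {"variogram_ratio": bool(lo <= result.variogram_ratio <= hi)}

    if profile.kurtosis_tol is not None:
        comp = comparison_set or [result]
        if len(comp) == 1:
            warnings.warn("kurtosis roughness criterion over a single model is trivially PASS",
                          stacklevel=2)
        min_rough = min(r.roughness for r in comp)
        flags["kurtosis"] = bool(
            result.kurtosis_smoothed >= result.kurtosis_raw
            and result.roughness <= min_rough * (1.0 + profile.kurtosis_tol)
        )

    klo, khi = profile.kappa_bounds
    flags["kappa"] = bool(klo <= result.kappa3 <= khi)

    rlo, rhi = profile.relpos_bounds
    r = result.rel_pos.r[~result.rel_pos.excluded]
    if r.size:
        prop = float(np.mean((r >= rlo) & (r <= rhi)))
    else:
        prop = 0.0
    flags["rel_pos"] = bool(prop >= profile.relpos_proportion)

    result.flags[profile.name] = flags
    return flags


def consensus(flags_by_model: dict) -> dict:
    """Count, per model, how many of the three ``pu`` consensus criteria
    (variogram ratio, kappa, relative position) PASS.

    A count of 2 or more marks the variant as a consensus choice.
    """
    out = {}
    for label, flags in flags_by_model.items():
        pu = flags["pu"] if "pu" in flags else flags
        out[label] = int(sum(bool(pu[k]) for k in ("variogram_ratio", "kappa", "rel_pos")))
    return out


# ---------------------------------------------------------------------------
# One-call evaluation for a fitted model


def compute_gos(sample: PosteriorSample, data: AreaData, graph: AreaGraph,
                surfaces: DerivedSurfaces | None = None,
                d: BoundaryDistanceMatrix | None = None,
                H: int | None = None, label: str = "",
                kurtosis_surface: str = "sir") -> GosResult:
    """Evaluate all five GoS statistics for one posterior sample.

    ``kurtosis_surface`` selects the surface pair fed to the kurtosis
    criterion: "sir" (smoothed vs raw SIR, the default) or "casir"
    (CASIR vs CARSIR).
    """
    from .graph import boundary_distances
    from .derived import derive_surfaces

    if surfaces is None:
        surfaces = derive_surfaces(sample, data)
    if d is None:
        d = boundary_distances(graph)
    casir = surfaces.casir.mean
    carsir = surfaces.carsir.mean
    if kurtosis_surface == "sir":
        kz, kraw = surfaces.sir.mean, surfaces.raw_sir
    elif kurtosis_surface == "casir":
        kz, kraw = casir, carsir
    else:
        raise ValueError(f"unknown kurtosis_surface {kurtosis_surface!r}")
    k_sm, k_raw, rough = kurtosis_preservation(kz, kraw, graph)
    return GosResult(
        variogram_ratio=variogram_ratio(casir, carsir, d, H=H),
        kurtosis_smoothed=k_sm,
        kurtosis_raw=k_raw,
        roughness=rough,
        kappa3=kappa_gos(casir, carsir, 3),
        kappa5=kappa_gos(casir, carsir, 5),
        psi=fraction_spatial_variation(sample, data),
        rel_pos=relative_position_casir(sample, data, graph),
        label=label,
    )
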