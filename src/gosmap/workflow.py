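"""Orchestration: fit a grid of model variants, score them, and report.

``run_comparison`` drives the whole pipeline from a single configuration:
for each labelled (model, hyperprior) variant it fits the sampler with a
variant-specific seed derived from the master seed, computes the derived
surfaces, evaluates every goodness-of-smoothing and goodness-of-fit
statistic, applies the requested cut-off profiles, and builds the consensus
count over the three penalise-under-smoothing criteria.  ``render_report``
writes the tidy CSV/JSON tables (and optional diagnostic plots).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from .derived import DerivedSurfaces, derive_surfaces
from .gof import GofResult, compare_models, compute_gof
from .gos import PROFILES, GosResult, apply_cutoffs, compute_gos, consensus
from .graph import AreaGraph, boundary_distances, build_graph
from .models import (AreaData, HyperpriorConfig, McmcConfig, ModelSpec,
                     rescale_bym_identifiability, sample_bym, sample_leroux)
from .synthetic import read_dataset

log = logging.getLogger("gosmap")

__all__ = ["RunConfig", "ComparisonBundle", "run_comparison", "render_report",
           "variant_seed", "ReportModel"]


def variant_seed(master_seed: int, label: str) -> int:
    """Per-variant seed derived by hashing (master seed, label), so adding a
    variant never perturbs the others' chains."""
    return zlib.crc32(f"{master_seed}:{label}".encode()) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration for one comparison run."""

    variants: list                 # (label, ModelSpec) pairs, labels unique
    data_path: str | None = None   # dataset prefix for read_dataset
    graph_path: str | None = None  # explicit adjacency file, else <prefix>.gal
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    profiles: tuple = ("u", "c", "pu")
    seed: int = 0
    output: str | None = None
    kappa_categories: int = 3
    plots: bool = False

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.variants]
        if len(set(labels)) != len(labels):
            raise ValueError("variant labels must be unique")
        for p in self.profiles:
            if p not in PROFILES:
                raise ValueError(f"unknown cut-off profile {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        variants = []
        for v in cfg["variants"]:
            hp_keys = ("family", "alpha", "eta", "pi", "nu", "beta_prior_variance")
            hp = HyperpriorConfig(**{k: v[k] for k in hp_keys if k in v})
            variants.append((str(v["label"]), ModelSpec(v.get("model", "leroux"), hp)))
        mcmc = McmcConfig(**cfg.get("mcmc", {}))
        return cls(
            variants=variants,
            data_path=cfg.get("data"),
            graph_path=cfg.get("graph"),
            mcmc=mcmc,
            profiles=tuple(cfg.get("profiles", ("u", "c", "pu"))),
            seed=int(cfg.get("seed", 0)),
            output=cfg.get("output"),
            kappa_categories=int(cfg.get("kappa_categories", 3)),
            plots=bool(cfg.get("plots", False)),
        )


@dataclass
class VariantResult:
    label: str
    spec: ModelSpec
    gos: GosResult
    gof: GofResult
    surfaces: DerivedSurfaces
    error: str | None = None


@dataclass
class ComparisonBundle:
    """Everything ``run_comparison`` produced for one configuration."""

    results: list                  # VariantResult, fitted variants only
    failures: dict                 # label -> error message
    consensus: dict                # label -> count in {0..3}
    profiles: tuple
    seed: int

    def gos_table(self) -> pd.DataFrame:
        """One row per (variant, statistic, profile) with value and flag."""
        rows = []
        for r in self.results:
            g = r.gos
            stats = {
                "variogram_ratio": g.variogram_ratio,
                "kurtosis_smoothed": g.kurtosis_smoothed,
                "kurtosis_raw": g.kurtosis_raw,
                "roughness": g.roughness,
                "kappa3": g.kappa3,
                "kappa5": g.kappa5,
                "psi": g.psi,
                "rel_pos_median": float(np.nanmedian(g.rel_pos.capped)),
            }
            flagname = {"variogram_ratio": "variogram_ratio", "kappa3": "kappa",
                        "kurtosis_smoothed": "kurtosis", "rel_pos_median": "rel_pos"}
            for stat, value in stats.items():
                for prof in self.profiles:
                    flags = g.flags.get(prof, {})
                    key = flagname.get(stat)
                    flag = flags.get(key) if key else None
                    rows.append({
                        "label": r.label, "statistic": stat, "profile": prof,
                        "value": value,
                        "flag": {True: "PASS", False: "FAIL", None: ""}[flag],
                    })
        return pd.DataFrame(rows, columns=["label", "statistic", "profile", "value", "flag"])

    def gof_table(self) -> pd.DataFrame:
        return compare_models([r.gof for r in self.results])

    def consensus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"label": k, "n_pass": v, "consensus": v >= 2}
             for k, v in self.consensus.items()],
            columns=["label", "n_pass", "consensus"],
        )


def _load_inputs(config: RunConfig):
    if config.data_path is None:
        raise ValueError("config must name a dataset (data: <prefix>)")
    data, graph, _ = read_dataset(config.data_path)
    if config.graph_path is not None:
        graph = build_graph(config.graph_path)
    return data, graph


def run_comparison(config: RunConfig, data: AreaData | None = None,
                   graph: AreaGraph | None = None) -> ComparisonBundle:
    """Fit every variant, score it, flag it, and form the consensus.

    A sampler failure aborts only that variant; the failure is recorded in
    the bundle.  Inputs may be passed in memory (``data``/``graph``) or
    loaded from the paths in the config.  Input files are never mutated.
    """
    if data is None or graph is None:
        data, graph = _load_inputs(config)
    d = boundary_distances(graph)
    results: list[VariantResult] = []
    failures: dict[str, str] = {}
    for label, spec in config.variants:
        seed = variant_seed(config.seed, label)
        mcmc = replace(config.mcmc, seed=seed)
        try:
            fit = sample_bym if spec.model == "bym" else sample_leroux
            sample = fit(data, graph, spec, mcmc)
            if spec.model == "bym":
                sample = rescale_bym_identifiability(sample)
            surfaces = derive_surfaces(sample, data)
            gos = compute_gos(sample, data, graph, surfaces=surfaces, d=d, label=label)
            gof = compute_gof(sample, data, graph, label=label)
        except Exception as exc:  # noqa: BLE001 - per-variant isolation
            log.warning("variant %s failed: %s", label, exc)
            failures[label] = str(exc)
            continue
        log.info("variant %s: acceptance %s", label,
                 {k: round(v, 3) for k, v in sample.acceptance.items()})
        results.append(VariantResult(label=label, spec=spec, gos=gos,
                                     gof=gof, surfaces=surfaces))
    comparison = [r.gos for r in results]
    flags_by_model = {}
    for r in results:
        for prof in config.profiles:
            apply_cutoffs(r.gos, PROFILES[prof], comparison_set=comparison)
        if "pu" not in config.profiles:
            apply_cutoffs(r.gos, PROFILES["pu"], comparison_set=comparison)
        flags_by_model[r.label] = r.gos.flags
    cons = consensus(flags_by_model) if results else {}
    return ComparisonBundle(results=results, failures=failures, consensus=cons,
                            profiles=config.profiles, seed=config.seed)


# ---------------------------------------------------------------------------
# Report rendering


class VariantReport(BaseModel):
    label: str
    model: str
    variogram_ratio: float
    kurtosis_smoothed: float
    kurtosis_raw: float
    roughness: float
    kappa3: float
    kappa5: float
    psi: float
    rel_pos_median: float
    dic: float
    waic: float
    neg_sum_log_cpo: float
    morans_i: float
    morans_p: float
    flags: dict
    consensus_count: int


class ReportModel(BaseModel):
    """Schema of report.json (validated on write and readable for re-render)."""

    seed: int
    profiles: list
    variants: list[VariantReport]
    failures: dict


def bundle_to_report(bundle: ComparisonBundle) -> ReportModel:
    variants = []
    for r in bundle.results:
        variants.append(VariantReport(
            label=r.label,
            model=r.spec.model,
            variogram_ratio=r.gos.variogram_ratio,
            kurtosis_smoothed=r.gos.kurtosis_smoothed,
            kurtosis_raw=r.gos.kurtosis_raw,
            roughness=r.gos.roughness,
            kappa3=r.gos.kappa3,
            kappa5=r.gos.kappa5,
            psi=r.gos.psi,
            rel_pos_median=float(np.nanmedian(r.gos.rel_pos.capped)),
            dic=r.gof.dic,
            waic=r.gof.waic,
            neg_sum_log_cpo=r.gof.neg_sum_log_cpo,
            morans_i=r.gof.morans_i,
            morans_p=r.gof.morans_p,
            flags=r.gos.flags,
            consensus_count=bundle.consensus.get(r.label, 0),
        ))
    return ReportModel(seed=bundle.seed, profiles=list(bundle.profiles),
                       variants=variants, failures=bundle.failures)


def render_report(bundle: ComparisonBundle, outdir, plots: bool = False) -> dict:
    """Write the tidy tables (gos.csv, gof.csv, consensus.csv, report.json).

    Plot files (variograms, kurtosis/roughness, kappa, relative-position
    densities) are optional and have no effect on the tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gos_df = bundle.gos_table()
    gos_df.to_csv(outdir / "gos.csv", index=False)
    paths["gos"] = outdir / "gos.csv"
    if bundle.results:
        bundle.gof_table().to_csv(outdir / "gof.csv", index=False)
        paths["gof"] = outdir / "gof.csv"
    bundle.consensus_table().to_csv(outdir / "consensus.csv", index=False)
    paths["consensus"] = outdir / "consensus.csv"
    report = bundle_to_report(bundle)
    (outdir / "report.json").write_text(report.model_dump_json(indent=1))
    paths["report"] = outdir / "report.json"
    if plots and bundle.results:
        paths["plots"] = _render_plots(bundle, outdir)
    return paths


def _render_plots(bundle: ComparisonBundle, outdir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in bundle.results:
        vals = [v for v in (r.gos.rel_pos.capped,) ][0]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            ax.hist(vals, bins=20, histtype="step", label=r.label, density=True)
    ax.set_xlabel("relative position of CASIR")
    ax.set_ylabel("density")
    ax.legend()
    p = outdir / "relative_position.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [r.label for r in bundle.results]
    ax.plot(labels, [r.gos.variogram_ratio for r in bundle.results], "o-",
            label="variogram ratio")
    ax.plot(labels, [r.gos.kappa3 for r in bundle.results], "s-", label="kappa (3 cat)")
    ax.set_ylabel("statistic")
    ax.legend()
    p = outdir / "gos_statistics.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written
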