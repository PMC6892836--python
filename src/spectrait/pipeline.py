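"""End-to-end orchestration of the analysis per irrigation scope.

For each requested scope (a single treatment, or "FL+LM" = both treatments'
plots pooled) the pipeline computes, in order: the 23-index SRI table and
index-trait R2 values; genetic correlations and heritabilities for every
index and trait; full-spectrum PLSR with LOOCV (calibration/validation
statistics and VIP-based sensitive band intervals); stepwise wavelength
models inside those intervals; per-group SRI models; reduced-feature PLSR
on the selected wavelengths and on all indices; and UPGMA genotype
clustering with cluster contrasts.  An optional exhaustive two-band contour
scan can be included.  Every table lands in the report dict and, when an
output directory is given, on disk next to a manifest recording the
parameters that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import contour as cm
from . import plsr as pl
from . import smlr as sm
from . import sri as sri_mod
from .quantgen import screen_indices
from .simulate import SimulationConfig, SyntheticExperiment, generate_experiment
from .spectra import SpectraSet

log = logging.getLogger("spectrait")

SCOPES_DEFAULT = ("FL", "LM", "FL+LM")
TRAITS = ("DW", "WC", "GY")


@dataclass
class RunConfig:
    scopes: tuple[str, ...] = SCOPES_DEFAULT
    traits: tuple[str, ...] = TRAITS
    seed: int = 0
    max_lv: int = 10
    contour: bool = False
    contour_step: int = 5
    validation_fraction: float = 0.25
    vip_threshold: float = 1.0
    weight_quantile: float = 0.75
    merge_gap: int = 5
    n_clusters: int = 3
    outdir: Path | None = None
    simulation: SimulationConfig | None = None
    extra: dict = dc_field(default_factory=dict)


def _scope_mask(meta: pd.DataFrame, scope: str) -> np.ndarray:
    if scope == "FL+LM":
        return np.ones(len(meta), dtype=bool)
    return (meta["treatment"] == scope).to_numpy()


def run_pipeline(
    config: RunConfig,
    spectra: SpectraSet | None = None,
    traits: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the report dict of tables.

    Either pass measured ``spectra`` and ``traits`` or set
    ``config.simulation`` to generate a synthetic trial first.
    """
    t0 = time.time()
    experiment: SyntheticExperiment | None = None
    if spectra is None or traits is None:
        if config.simulation is None:
            raise ValueError("either data or a simulation config is required")
        log.info("generating synthetic experiment (%d plots)", config.simulation.n_plots)
        experiment = generate_experiment(config.simulation)
        spectra = experiment.spectra
        traits = experiment.traits

    registry = sri_mod.default_registry()
    report: dict = {"scopes": {}, "parameters": _manifest_params(config)}
    for scope in config.scopes:
        report["scopes"][scope] = _run_scope(config, scope, spectra, traits, registry)
    report["elapsed_s"] = time.time() - t0
    if config.outdir is not None:
        render_report(report, config.outdir)
        if experiment is not None:
            experiment.write(Path(config.outdir) / "experiment")
    return report


def _run_scope(
    config: RunConfig,
    scope: str,
    spectra: SpectraSet,
    traits: pd.DataFrame,
    registry,
) -> dict:
    stage_t = time.time()
    mask = _scope_mask(spectra.meta, scope)
    sub = spectra.subset(mask)
    sub_traits = traits.loc[traits["plot_id"].isin(sub.plot_ids)].reset_index(drop=True)
    out: dict = {"n_plots": len(sub)}
    log.info("[%s] %d plots", scope, len(sub))

    sri_table = sri_mod.compute_sri_table(sub, registry)
    out["sri_table"] = sri_table
    out["index_trait_r2"] = pd.concat(
        {t: sri_mod.index_trait_r2(sri_table, sub_traits, t)["r2"] for t in config.traits},
        axis=1,
    )

    out["screening"] = screen_indices(sri_table, sub_traits, list(config.traits), scope)

    if config.contour:
        out["contour"] = {}
        for t in config.traits:
            cmap = cm.scan_pairs(sub, sub_traits, t, step=config.contour_step, scope=scope)
            hot = cm.extract_hotspots(cmap)
            out["contour"][t] = {
                "map": cmap,
                "hotspots": hot,
                "shortlist": cm.wavelength_shortlist(hot) if hot.regions else [],
            }

    y_by_trait = {
        t: sub_traits.set_index("plot_id").loc[sub.plot_ids, t].to_numpy(dtype=float)
        for t in config.traits
    }

    cal_rows, interval_rows, wl_models, group_rows = [], [], {}, []
    selected_wavelengths: set[int] = set()
    for t in config.traits:
        y = y_by_trait[t]
        cv = pl.calibrate_validate(
            sub.values, y,
            validation_fraction=config.validation_fraction,
            seed=config.seed,
            max_lv=config.max_lv,
        )
        cal_rows.append(
            {
                "scope": scope, "trait": t, "onlv": cv.onlv.n_lv,
                "q2_cum": cv.onlv.q2, "acceptable": cv.onlv.acceptable,
                "cal_r2": cv.calibration.r2, "cal_rmse": cv.calibration.rmse,
                "cal_re_pct": cv.calibration.re_pct,
                "val_r2": cv.validation.r2, "val_rmse": cv.validation.rmse,
                "val_re_pct": cv.validation.re_pct,
            }
        )
        model = pl.fit_plsr(sub.values, y, cv.onlv.n_lv)
        vip_vec = pl.vip(model)
        intervals = pl.extract_band_intervals(
            vip_vec,
            model.weights,
            sub.wavelengths,
            vip_threshold=config.vip_threshold,
            weight_quantile=config.weight_quantile,
            merge_gap=config.merge_gap,
            trait=t,
            scope=scope,
        )
        interval_rows += [
            {
                "scope": scope, "trait": t, "start_nm": iv.start,
                "end_nm": iv.end, "mean_vip": iv.mean_vip,
            }
            for iv in intervals
        ]
        if intervals:
            wl_model = sm.wavelengths_from_intervals(sub, intervals, sub_traits, t, scope)
            wl_models[t] = wl_model
            selected_wavelengths |= {int(p[1:]) for p in wl_model.predictors}
        for group in sri_mod.GROUPS:
            gm = sm.group_model(sri_table, registry, group, sub_traits, t, scope)
            group_rows.append(
                {
                    "scope": scope, "trait": t, "group": group, "r2": gm.r2,
                    "rmse": gm.rmse, "equation": gm.equation(),
                }
            )
    out["plsr_full_spectrum"] = pd.DataFrame(cal_rows)
    out["band_intervals"] = pd.DataFrame(interval_rows)
    out["wavelength_models"] = pd.DataFrame(
        [
            {
                "scope": scope, "trait": t, "r2": m.r2, "rmse": m.rmse,
                "equation": m.equation(),
                "wavelengths": ",".join(p[1:] for p in m.predictors),
            }
            for t, m in wl_models.items()
        ]
    )
    out["group_models"] = pd.DataFrame(group_rows)

    # reduced-feature PLSR: selected wavelengths and all SRIs
    feat_rows = []
    wl_sorted = sorted(selected_wavelengths)
    for t in config.traits:
        y = y_by_trait[t]
        if wl_sorted:
            F = np.column_stack([sub.band(w) for w in wl_sorted])
            res = pl.plsr_on_features(F, y, max_lv=config.max_lv)
            feat_rows.append(
                {
                    "scope": scope, "trait": t, "features": "wavelengths",
                    "n_features": len(wl_sorted), "onlv": res.onlv.n_lv,
                    "r2": res.metrics.r2, "rmse": res.metrics.rmse,
                }
            )
        res = pl.plsr_on_features(sri_table.to_numpy(), y, max_lv=config.max_lv)
        feat_rows.append(
            {
                "scope": scope, "trait": t, "features": "sris",
                "n_features": sri_table.shape[1], "onlv": res.onlv.n_lv,
                "r2": res.metrics.r2, "rmse": res.metrics.rmse,
            }
        )
    out["feature_plsr"] = pd.DataFrame(feat_rows)

    profiles = clu.genotype_profiles(sub_traits, scope)
    linkage = clu.upgma(profiles)
    assignments = clu.cut_clusters(linkage, k=min(config.n_clusters, len(profiles)))
    summary = clu.cluster_summary(assignments, profiles)
    out["cluster_summary"] = summary
    out["cluster_newick"] = clu.to_newick(linkage, list(profiles.index))
    contrasts = []
    for t in config.traits:
        if len(summary) >= 2:
            contrasts.append(
                {
                    "scope": scope, "trait": t, "reference": 1, "comparison": 2,
                    "decrease_pct": clu.relative_decrease(summary, 1, 2, t),
                }
            )
    out["cluster_contrasts"] = pd.DataFrame(contrasts)
    out["elapsed_s"] = time.time() - stage_t
    log.info("[%s] done in %.1f s", scope, out["elapsed_s"])
    return out


def _manifest_params(config: RunConfig) -> dict:
    params = {
        "scopes": list(config.scopes),
        "traits": list(config.traits),
        "seed": config.seed,
        "max_lv": config.max_lv,
        "contour": config.contour,
        "contour_step": config.contour_step,
        "validation_fraction": config.validation_fraction,
        "vip_threshold": config.vip_threshold,
        "weight_quantile": config.weight_quantile,
        "merge_gap": config.merge_gap,
        "n_clusters": config.n_clusters,
    }
    if config.simulation is not None:
        s = config.simulation
        params["simulation"] = {
            "n_genotypes": s.n_genotypes,
            "treatments": list(s.treatments),
            "n_years": s.n_years,
            "n_reps": s.n_reps,
            "spectral_noise_sd": s.spectral_noise_sd,
            "trait_spectrum_gain": dict(s.trait_spectrum_gain),
            "seed": s.seed,
        }
    return params


def render_report(report: dict, outdir: str | Path) -> None:
    """Write every report table as CSV plus a Markdown overview and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    md = ["# Analysis report", ""]
    for scope, tables in report["scopes"].items():
        tag = scope.replace("+", "plus").replace("/", "_")
        sdir = outdir / tag
        sdir.mkdir(exist_ok=True)
        md.append(f"## Scope {scope} ({tables['n_plots']} plots)\n")
        for key, value in tables.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(sdir / f"{key}.csv")
                if key in ("plsr_full_spectrum", "cluster_summary", "cluster_contrasts"):
                    md.append(f"### {key}\n")
                    md.append(value.to_markdown(index=False))
                    md.append("")
            elif key == "cluster_newick":
                (sdir / "dendrogram.nwk").write_text(value)
            elif key == "contour":
                for t, cdata in value.items():
                    cdata["map"].write_csv(sdir / f"contour_{t}.csv")
    (outdir / "report.md").write_text("\n".join(md))
    manifest = {"parameters": report["parameters"], "elapsed_s": report.get("elapsed_s")}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
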