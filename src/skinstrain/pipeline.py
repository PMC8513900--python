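"""End-to-end report assembly over a directory of input CSVs.

Each step consumes validated tables (:mod:`skinstrain.io`), runs the
corresponding analysis module, and returns a plain DataFrame or dict;
:func:`run_pipeline` wires them together and writes the report bundle.
Every written table carries provenance columns (config hash, source file);
the run timestamp lives in ``report.json`` so the numeric tables are
byte-reproducible for a given config and inputs.
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import deposition as dep
from . import growth as gw
from . import morphometrics as morpho
from . import segmented as seg
from . import strain as st
from . import tensile as tens
from .config import PipelineConfig
from .geometry import DiscGeometry, curvature_corrected_disc_area, equivalent_sphere_radius_mm
from .io import read_table

__all__ = [
    "run_pipeline",
    "growth_step",
    "strain_step",
    "breakpoint_step",
    "deposition_step",
    "tensile_step",
    "morphometrics_step",
]


def growth_step(growth_df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Sigmoid fits of the mean area series per cultivar x region."""
    rows = []
    for (cultivar, region), grp in growth_df.groupby(["cultivar", "region"]):
        means = grp.groupby("dafb")["area_cm2"].mean()
        series = gw.GrowthSeries(cultivar, means.index.to_numpy(), means.to_numpy(), region)
        fit = gw.fit_sigmoid(series, model=config.sigmoid_model)
        row = {
            "cultivar": cultivar,
            "region": region,
            "model": fit.model,
            "a_max": fit.a_max,
            "k": fit.k,
            "t_mid": fit.t_mid,
            "rss": fit.rss,
            "converged": fit.converged,
            "n_times": fit.n,
        }
        if fit.converged:
            rate, t_at = gw.max_growth_rate(fit)
            row["max_rate"] = rate
            row["dafb_at_max_rate"] = t_at
            row["relative_rate_at_max"] = rate / float(fit.predict(t_at))
        else:
            row["max_rate"] = np.nan
            row["dafb_at_max_rate"] = np.nan
            row["relative_rate_at_max"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _whole_fits(fits: pd.DataFrame, config: PipelineConfig) -> dict[str, gw.SigmoidFit]:
    out = {}
    for _, r in fits[fits["region"] == "whole"].iterrows():
        out[r["cultivar"]] = gw.SigmoidFit(
            model=r["model"], a_max=r["a_max"], k=r["k"], t_mid=r["t_mid"],
            rss=r["rss"], converged=bool(r["converged"]), n=int(r["n_times"]),
            cultivar=r["cultivar"],
        )
    return out


def strain_step(
    disc_df: pd.DataFrame, fits: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Apparent and cumulative strain partition per cultivar and DAFB.

    Apparent strains are averaged over discs; cumulative strains use the
    fitted whole-fruit area at each sampling time and the per-time mean
    disc ratios.
    """
    whole = _whole_fits(fits, config)
    rows = []
    for cultivar, grp in disc_df.groupby("cultivar"):
        if cultivar not in whole:
            raise ValueError(f"no whole-fruit growth fit for cultivar {cultivar!r}")
        fit = whole[cultivar]
        for dafb, sub in grp.groupby("dafb"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", st.StrainInputWarning)
                recs = [
                    st.DiscStrainRecord(cultivar, float(dafb), r.a_i_mm2, r.a_cm_mm2, r.a_dcm_mm2)
                    for r in sub.itertuples()
                ]
                apparent = [st.apparent_strains(r) for r in recs]
                mean = sub[["a_i_mm2", "a_cm_mm2", "a_dcm_mm2"]].mean()
                mean_rec = st.DiscStrainRecord(
                    cultivar, float(dafb), mean["a_i_mm2"], mean["a_cm_mm2"], mean["a_dcm_mm2"]
                )
            a_total = float(fit.predict(dafb))
            cs = st.cumulative_strains(mean_rec, a_total, config.a0_cm2)
            ei = np.array([a.eps_exc_iso_pct for a in apparent])
            ex = np.array([a.eps_extr_pct for a in apparent])
            tot = ei + ex
            rows.append(
                {
                    "cultivar": cultivar,
                    "dafb": float(dafb),
                    "n_discs": len(recs),
                    "apparent_eps_exc_iso_pct": ei.mean(),
                    "apparent_eps_extr_pct": ex.mean(),
                    "apparent_eps_total_pct": tot.mean(),
                    "apparent_eps_total_se": tot.std(ddof=1) / np.sqrt(len(tot))
                    if len(tot) > 1
                    else np.nan,
                    "a_total_cm2": a_total,
                    "eps_total": cs.eps_total,
                    "eps_exc_iso": cs.eps_exc_iso,
                    "eps_extr": cs.eps_extr,
                    "eps_resid": cs.eps_resid,
                    "eps_plastic": cs.eps_plastic,
                }
            )
    return pd.DataFrame(rows).sort_values(["cultivar", "dafb"]).reset_index(drop=True)


def breakpoint_step(strains: pd.DataFrame, config: PipelineConfig) -> dict:
    """Segmented fits of elastic and wax-fixed strain against total strain."""
    out: dict[str, dict] = {}
    for cultivar, grp in strains.groupby("cultivar"):
        grp = grp.sort_values("eps_total")
        if len(grp) < seg.MIN_POINTS:
            out[cultivar] = {"skipped": f"only {len(grp)} time points (< {seg.MIN_POINTS})"}
            continue
        entry = {}
        for comp in ("eps_exc_iso", "eps_extr"):
            fit = seg.fit_segmented(grp["eps_total"].to_numpy(), grp[comp].to_numpy())
            f_stat, p = seg.biphasic_test(fit)
            entry[comp] = {
                "breakpoint_eps_total": fit.breakpoint_x,
                "slope_1": fit.slope_1,
                "slope_2": fit.slope_2,
                "rss": fit.rss,
                "linear_rss": fit.linear_rss,
                "f_stat": f_stat,
                "p_value": p,
            }
        out[cultivar] = entry
    return out


def deposition_step(
    mass_df: pd.DataFrame, fits: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Per-area mass kinetics, plateau onset, and whole-fruit rates."""
    whole = _whole_fits(fits, config)
    out: dict[str, dict] = {}
    for cultivar, grp in mass_df.groupby("cultivar"):
        g = grp.copy()
        g["cm_pa"] = g["cm_ug"] / g["disc_area_mm2"]
        g["dcm_pa"] = g["dcm_ug"] / g["disc_area_mm2"]
        g["wax_pa"] = g["cm_pa"] - g["dcm_pa"]
        per_time = g.groupby("dafb")[["cm_pa", "dcm_pa", "wax_pa"]].mean()
        entry = {}
        for comp in ("cm_pa", "dcm_pa", "wax_pa"):
            dfit = dep.fit_deposition(
                per_time.index.to_numpy(), per_time[comp].to_numpy(),
                model=config.deposition_model,
            )
            onset = dep.area_matched_onset(dfit) if dfit.converged else None
            comp_entry = {
                "m_inf": dfit.m_inf,
                "r": dfit.r,
                "t0": dfit.t0,
                "converged": dfit.converged,
                "plateau_onset_dafb": onset,
            }
            if cultivar in whole and whole[cultivar].converged and dfit.converged:
                times = per_time.index.to_numpy()
                comp_entry["whole_fruit_rate_ug_per_day"] = {
                    float(t): float(dep.whole_fruit_deposition_rate(dfit, whole[cultivar], t))
                    for t in times
                }
            entry[comp.replace("_pa", "")] = comp_entry
        out[cultivar] = entry
    return out


def tensile_step(
    curves_df: pd.DataFrame,
    annotations: pd.DataFrame | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-strip tensile summaries (stiffness, F_max, eps_max, annotation)."""
    ann = None
    if annotations is not None:
        ann = annotations.set_index("strip_id")["failed_at_lenticel"]
    rows = []
    for strip_id, grp in curves_df.groupby("strip_id"):
        grp = grp.sort_values("strain_pct")
        flag = None
        if ann is not None and strip_id in ann.index:
            flag = bool(ann.loc[strip_id])
        curve = tens.TensileCurve(
            strip_id=str(strip_id),
            cultivar=str(grp["cultivar"].iloc[0]),
            dafb=float(grp["dafb"].iloc[0]),
            strain_pct=grp["strain_pct"].to_numpy(),
            force_n=grp["force_n"].to_numpy(),
            failed_at_lenticel=flag,
        )
        s = tens.analyze_curve(curve, window_frac=config.stiffness_window_frac)
        rows.append(
            {
                "strip_id": s.strip_id,
                "cultivar": s.cultivar,
                "dafb": s.dafb,
                "stiffness_n_per_pct": s.stiffness_n_per_pct,
                "f_max_n": s.f_max_n,
                "eps_max_pct": s.eps_max_pct,
                "failed_at_lenticel": s.failed_at_lenticel,
            }
        )
    return pd.DataFrame(rows).sort_values(["cultivar", "dafb", "strip_id"]).reset_index(drop=True)


def morphometrics_step(
    counts_df: pd.DataFrame,
    areas_df: pd.DataFrame | None,
    cells_df: pd.DataFrame | None,
    config: PipelineConfig,
    fits: pd.DataFrame | None = None,
) -> dict:
    """Lenticel densities with marginal means, area trends, cell shapes."""
    counts = counts_df.copy()
    if config.curvature_correction and fits is not None:
        whole = _whole_fits(fits, config)

        def _corrected(row):
            fit = whole.get(row["cultivar"])
            if fit is None or not fit.converged:
                return row["disc_area_mm2"]
            radius = equivalent_sphere_radius_mm(float(fit.predict(row["dafb"])))
            flat_diam = 2.0 * np.sqrt(row["disc_area_mm2"] / np.pi)
            return curvature_corrected_disc_area(DiscGeometry(flat_diam, radius))

        counts["disc_area_mm2"] = counts.apply(_corrected, axis=1)
    counts["density"] = counts["count"] / counts["disc_area_mm2"]
    mm = morpho.marginal_means(counts, "density")
    out = {
        "density_cultivar_time_means": {
            f"{c}@{int(t)}": round(v, config.round_density)
            for (c, t), v in mm["cultivar_time_means"]["mean"].items()
        },
        "density_cultivar_means": {
            c: round(v, config.round_density)
            for c, v in mm["cultivar_means"]["mean"].items()
        },
        "density_region_means": {
            r: round(v, config.round_density)
            for r, v in mm["region_means"]["mean"].items()
        },
        "density_grand_mean": round(mm["grand_mean"], config.round_density),
    }
    if areas_df is not None:
        trends = {}
        for cultivar, grp in areas_df.groupby("cultivar"):
            slope, intercept, r2 = morpho.lenticel_area_trend(
                grp["dafb"].to_numpy(), grp["area_mm2"].to_numpy()
            )
            trends[cultivar] = {"slope_mm2_per_day": slope, "intercept_mm2": intercept, "r2": r2}
        out["lenticel_area_trend"] = trends
    if cells_df is not None:
        cells = cells_df.copy()
        cells["aspect_ratio"] = cells["anticlinal_diam_um"] / cells["periclinal_diam_um"]
        cells["periclinal_area_um2"] = cells["periclinal_diam_um"] ** 2
        summary = (
            cells.groupby(["cultivar", "layer"])[["aspect_ratio", "periclinal_area_um2"]]
            .mean()
            .round(3)
        )
        out["cell_shape_means"] = {
            f"{c}/{layer}": row.to_dict() for (c, layer), row in summary.iterrows()
        }
    return out


_INPUTS = {
    "growth": ("growth.csv", True),
    "disc_areas": ("disc_areas.csv", True),
    "cuticle_mass": ("cuticle_mass.csv", False),
    "tensile_curves": ("tensile_curves.csv", False),
    "tensile_annotations": ("tensile_annotations.csv", False),
    "lenticel_counts": ("lenticel_counts.csv", False),
    "lenticel_areas": ("lenticel_areas.csv", False),
    "cell_measures": ("cell_measures.csv", False),
}


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> dict:
    """Run every applicable step over ``input_dir`` and write the report.

    ``growth.csv`` and ``disc_areas.csv`` are required; the other tables
    are analyzed when present.  Returns the report dict (also written as
    ``report.json``).  All outputs land inside ``out_dir``.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    for name, (fname, required) in _INPUTS.items():
        path = input_dir / fname
        if path.exists():
            tables[name] = read_table(path, name)
        elif required:
            raise FileNotFoundError(f"required input {fname} not found in {input_dir}")

    cfg_hash = config.hash()
    report: dict = {
        "config_hash": cfg_hash,
        "config": {k: getattr(config, k) for k in (
            "a0_cm2", "sigmoid_model", "deposition_model", "stiffness_window_frac",
            "curvature_correction", "seed",
        )},
        "input_dir": str(input_dir),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }

    def _write(df: pd.DataFrame, fname: str, source: str) -> None:
        df = df.copy()
        df["config_hash"] = cfg_hash
        df["source_file"] = source
        df.to_csv(out_dir / fname, index=False)

    fits = growth_step(tables["growth"], config)
    _write(fits, "growth_fits.csv", "growth.csv")
    report["growth"] = {
        r["cultivar"]: {
            "max_rate_cm2_per_day": round(r["max_rate"], 2),
            "dafb_at_max_rate": round(r["dafb_at_max_rate"], 1),
        }
        for _, r in fits[fits["region"] == "whole"].iterrows()
        if r["converged"]
    }

    strains = strain_step(tables["disc_areas"], fits, config)
    _write(strains.round(
        {c: config.round_pct for c in strains.columns if c.startswith("apparent")}
    ), "strains.csv", "disc_areas.csv")
    report["apparent_strain_final_pct"] = {
        c: round(g.sort_values("dafb")["apparent_eps_total_pct"].iloc[-1], config.round_pct)
        for c, g in strains.groupby("cultivar")
    }

    bp = breakpoint_step(strains, config)
    report["breakpoints"] = bp
    with open(out_dir / "breakpoints.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "fits": bp}, fh, indent=2, default=float)

    if "cuticle_mass" in tables:
        depo = deposition_step(tables["cuticle_mass"], fits, config)
        report["deposition"] = depo
        with open(out_dir / "deposition.json", "w") as fh:
            json.dump({"config_hash": cfg_hash, "fits": depo}, fh, indent=2, default=float)

    if "tensile_curves" in tables:
        summaries = tensile_step(
            tables["tensile_curves"], tables.get("tensile_annotations"), config
        )
        _write(summaries, "tensile_summaries.csv", "tensile_curves.csv")
        report["tensile"] = {}
        for cultivar, grp in summaries.groupby("cultivar"):
            flags = grp["failed_at_lenticel"].dropna()
            report["tensile"][cultivar] = {
                "mean_stiffness_n_per_pct": round(grp["stiffness_n_per_pct"].mean(), 3),
                "mean_f_max_n": round(grp["f_max_n"].mean(), 2),
                "mean_eps_max_pct": round(grp["eps_max_pct"].mean(), config.round_pct),
                "lenticel_failure_frequency": (
                    round(float(flags.mean()), 2) if len(flags) else None
                ),
            }

    if "lenticel_counts" in tables:
        morph = morphometrics_step(
            tables["lenticel_counts"],
            tables.get("lenticel_areas"),
            tables.get("cell_measures"),
            config,
            fits=fits,
        )
        report["morphometrics"] = morph
        with open(out_dir / "morphometrics.json", "w") as fh:
            json.dump({"config_hash": cfg_hash, **morph}, fh, indent=2, default=float)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
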