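"""Synthetic two-cultivar datasets with the structure the pipeline assumes.

The generator emulates the developmental measurements of a russet-
susceptible ('apple_like') and a non-susceptible ('tommy_like') mango
cultivar: sigmoid whole-fruit area growth, dot-pattern regional growth,
early-rapid-then-area-matched cuticle deposition, skin-disc area triplets
whose strain partition is exact before noise, quasi-linear tensile curves
with a fracture point, Poisson lenticel counts whose density is diluted by
surface growth, and cell-shape measurements.

Structural choices
------------------
* Whole-fruit area follows a logistic; regional dot-pattern series share
  the shape with per-region rate-constant scalings.
* Disc ratios A_CM/A_i and A_DCM/A_i stay at 1 while deposition keeps
  pace with expansion, then decay as 1 - c(1 - A(t_lag)/A(t)): strain
  that is not fixed by new deposition accumulates in proportion to the
  further area growth.  This makes the elastic and wax-fixed components
  exactly biphasic (hinge at eps_total = A(t_lag)/A0 - 1) and the
  residual component exactly linear in total cumulative strain.
* Mass per area rises as a saturating exponential; plateau onset is where
  deposition has matched area expansion.
* Tensile curves are C^1: a power-law toe joined to a final linear segment
  whose slope is the target stiffness, fracturing at (eps_max, F_max).
* Noise is multiplicative Gaussian with a stated CV for areas, masses and
  lenticel areas, additive (sigma = CV x F_max) for forces, and Poisson
  for counts.  All randomness derives from the profile seed via per-table
  child streams, so any single table regenerates reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deposition as dep
from . import growth as gw
from . import morphometrics as morpho
from . import segmented as seg
from . import strain as st
from . import tensile as tens
from .geometry import DiscGeometry, curvature_corrected_disc_area, equivalent_sphere_radius_mm

__all__ = [
    "CultivarProfile",
    "SyntheticBundle",
    "default_profiles",
    "generate_dataset",
    "evaluate_contrasts",
    "CONTRAST_NAMES",
    "DEFAULT_TIMES",
]

#: Default sampling grid, DAFB: weekly through the early phase (where the
#: strain-partition regime change happens) and biweekly thereafter.
DEFAULT_TIMES = (41, 48, 55, 62, 69, 76, 83, 97, 111, 125, 139, 153)

_REGIONS = morpho.REGIONS
_TABLE_NAMES = (
    "fruit_dimensions",
    "growth",
    "disc_areas",
    "cuticle_mass",
    "tensile_curves",
    "tensile_annotations",
    "lenticel_counts",
    "lenticel_areas",
    "cell_measures",
)


@dataclass(frozen=True)
class CultivarProfile:
    """Generating parameters for one cultivar.

    Growth is logistic (``a_max_cm2``, ``k_growth`` per day, ``t_mid``
    DAFB).  Deposition of CM mass per unit area is a saturating
    exponential (``m_inf_cm_ug_mm2``, ``r_dep`` per day, ``t0_dep``); the
    dewaxed fraction is ``dcm_frac``.  Disc-area ratios follow
    ``1 - c (1 - exp(-q t))``.  Tensile stiffness and fracture strain are
    linear in DAFB from ``t_ref_tensile``; fracture force is linear with a
    cap.  Lenticel number per fruit is fixed (density dilutes with area),
    per-lenticel area grows linearly, and regional density weights
    multiply the whole-fruit mean density.
    """

    name: str
    # growth
    a_max_cm2: float
    k_growth: float
    t_mid: float
    region_k_scale: tuple[float, ...] = (1.00, 0.97, 1.03, 0.99, 1.01)
    # deposition
    m_inf_cm_ug_mm2: float = 2.0
    r_dep: float = 0.1
    t0_dep: float = 30.0
    dcm_frac: float = 0.8
    # disc-ratio trajectories: ratio(t) = 1 - c (1 - A(t_lag)/A(t)) for
    # t > t_lag, else 1.  Deposition keeps the skin strain-free until
    # t_lag; beyond it, un-fixed strain accumulates in proportion to the
    # further area growth, which makes the elastic and wax-fixed
    # components exactly biphasic (hinged) and the residual component
    # exactly linear against total cumulative strain.
    c_cm: float = 0.17
    c_dcm: float = 0.29
    t_lag_ratio: float = 55.0
    # tensile
    t_ref_tensile: float = 55.0
    s0_n_per_pct: float = 0.05
    s_slope: float = 0.0015
    f0_n: float = 1.5
    f_slope: float = 0.0
    f_cap: float = 1.5
    eps0_pct: float = 35.0
    eps_slope: float = 0.12
    fail0: float = 0.3
    fail_slope: float = 0.004
    # lenticels
    n_lenticels_total: float = 4000.0
    lenticel_area0_mm2: float = 0.01
    lenticel_area_slope: float = 0.0012
    region_weights: tuple[float, ...] = (1.75, 0.45, 1.35, 0.90, 0.55)
    # cells
    hypo_anticlinal_slope: float = 0.0
    hypo_periclinal0_um: float = 20.0
    hypo_periclinal_slope: float = 0.08
    # sampling / noise
    punch_diameter_mm: float = 8.0
    cv_area: float = 0.03
    cv_disc: float = 0.02
    cv_mass: float = 0.05
    cv_force: float = 0.01  # sigma as a fraction of F_max (additive)
    cv_lenticel_area: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("k_growth", "r_dep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cv_area", "cv_disc", "cv_mass", "cv_force", "cv_lenticel_area"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        for t in (41.0, 160.0):
            for r in (self.ratio_cm(t), self.ratio_dcm(t)):
                if not 0.0 < r <= 1.2:
                    raise ValueError("disc ratios must stay in (0, 1.2]")

    # ------------------------------------------------------------------
    # noiseless generating curves
    def area_cm2(self, t):
        return gw.logistic(t, self.a_max_cm2, self.k_growth, self.t_mid)

    def _ratio_factor(self, t):
        a_lag = self.area_cm2(self.t_lag_ratio)
        a = np.asarray(self.area_cm2(t))
        return np.maximum(1.0 - a_lag / a, 0.0)

    def ratio_cm(self, t):
        return 1.0 - self.c_cm * self._ratio_factor(t)

    def ratio_dcm(self, t):
        return 1.0 - self.c_dcm * self._ratio_factor(t)

    def cm_per_area(self, t):
        t = np.asarray(t, dtype=float)
        return self.m_inf_cm_ug_mm2 * (1.0 - np.exp(-self.r_dep * (t - self.t0_dep)))

    def stiffness(self, t):
        return self.s0_n_per_pct + self.s_slope * (np.asarray(t, dtype=float) - self.t_ref_tensile)

    def f_max(self, t):
        return np.minimum(self.f0_n + self.f_slope * (np.asarray(t, dtype=float) - self.t_ref_tensile), self.f_cap)

    def eps_max(self, t):
        return np.maximum(self.eps0_pct - self.eps_slope * (np.asarray(t, dtype=float) - self.t_ref_tensile), 5.0)

    def fail_prob(self, t):
        return np.clip(self.fail0 + self.fail_slope * (np.asarray(t, dtype=float) - self.t_ref_tensile), 0.0, 0.95)

    def lenticel_area_mm2(self, t):
        return self.lenticel_area0_mm2 + self.lenticel_area_slope * np.asarray(t, dtype=float)


def default_profiles(seed: int = 0) -> tuple[CultivarProfile, CultivarProfile]:
    """The two documented cultivar parameter sets.

    ``apple_like`` (russet-susceptible): smaller fruit with a lower peak
    area growth rate (3.03 cm^2/day at 94 DAFB), a lower cuticle
    deposition rate whose per-area mass plateaus earlier (~69 DAFB),
    deeper and faster disc-ratio decay (hence more elastic and wax-fixed
    strain, final apparent strain sum 28.9%), an earlier elastic-strain
    breakpoint, a weaker and more extensible membrane (lower S, lower
    F_max), fewer but larger lenticels, and more frequent lenticel-
    associated failure (~70% at maturity).

    ``tommy_like`` (non-susceptible) is the converse on every axis
    (peak rate 3.85 cm^2/day at 103 DAFB, plateau ~83 DAFB, final
    apparent strain sum 24.9%, failure frequency ~59%).
    """
    apple = CultivarProfile(
        name="apple_like",
        a_max_cm2=350.0,
        k_growth=4.0 * 3.03 / 350.0,
        t_mid=94.0,
        m_inf_cm_ug_mm2=1.6,
        # 1%-of-initial-rate plateau onset at 69 DAFB, measured from the
        # first sampling at 41 DAFB
        r_dep=math.log(100.0) / (69.0 - 41.0),
        t0_dep=30.0,
        dcm_frac=0.80,
        # final apparent strains 17.0% + 11.9% = 28.9% at 153 DAFB;
        # strain onset (hence breakpoint at eps_total ~ 71) at 55 DAFB
        c_cm=0.17186,
        c_dcm=0.29212,
        t_lag_ratio=55.0,
        s0_n_per_pct=0.05,
        s_slope=0.0015,
        f0_n=1.5,
        f_slope=0.0,
        f_cap=1.5,
        eps0_pct=35.0,
        eps_slope=0.12,
        fail0=0.30,
        fail_slope=0.004,
        n_lenticels_total=3900.0,
        lenticel_area0_mm2=0.01,
        lenticel_area_slope=0.0012,
        region_weights=(1.75, 0.45, 1.35, 0.90, 0.55),
        hypo_anticlinal_slope=0.0,
        hypo_periclinal0_um=20.0,
        seed=seed,
    )
    tommy = CultivarProfile(
        name="tommy_like",
        a_max_cm2=450.0,
        k_growth=4.0 * 3.85 / 450.0,
        t_mid=103.0,
        m_inf_cm_ug_mm2=2.4,
        r_dep=math.log(100.0) / (83.0 - 41.0),  # plateau onset at 83 DAFB
        t0_dep=30.0,
        dcm_frac=0.80,
        # final apparent strains 14.5% + 10.4% = 24.9% at 153 DAFB;
        # later strain onset (breakpoint at eps_total ~ 88) at 62 DAFB
        c_cm=0.15136,
        c_dcm=0.25992,
        t_lag_ratio=62.0,
        s0_n_per_pct=0.08,
        s_slope=0.0020,
        f0_n=2.0,
        f_slope=0.0536,
        f_cap=3.5,
        eps0_pct=40.0,
        eps_slope=0.10,
        fail0=0.20,
        fail_slope=0.00375,
        n_lenticels_total=8700.0,
        lenticel_area0_mm2=0.01,
        lenticel_area_slope=0.0004,
        region_weights=(1.97, 0.65, 0.62, 0.95, 0.81),
        hypo_anticlinal_slope=0.03,
        hypo_periclinal0_um=22.0,
        hypo_periclinal_slope=0.10,
        seed=seed,
    )
    return apple, tommy


# ----------------------------------------------------------------------
# tensile curve construction


def tensile_curve_shape(s: float, f_max: float, eps_max: float, n: int = 300):
    """Noiseless force-strain curve: power toe + linear segment to fracture.

    The final segment has slope exactly ``s`` (the true maximum slope) and
    ends at (eps_max, f_max); the toe exponent is chosen so the join is
    C^1.  Requires s * eps_max > f_max (the max slope must exceed the
    secant slope).  Returns (strain_pct, force_n) with ``n`` samples on
    the rising branch.
    """
    rho = s * eps_max / f_max
    if rho <= 1.0:
        raise ValueError("need s * eps_max > f_max for a rising-slope curve")
    m = max(2.0, rho + 2.0)
    eps_t = eps_max * (1.0 - 1.0 / rho) * m / (m - 1.0)
    a = s / (m * eps_t ** (m - 1.0))
    strain = np.linspace(0.0, eps_max, n)
    force = np.where(
        strain < eps_t,
        a * strain**m,
        f_max - s * (eps_max - strain),
    )
    return strain, force


# ----------------------------------------------------------------------
# dataset generation


@dataclass
class SyntheticBundle:
    """All generated input tables plus the generating truth."""

    profile: CultivarProfile
    tables: dict[str, pd.DataFrame]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def _rng(seed: int, table: str) -> np.random.Generator:
    idx = _TABLE_NAMES.index(table)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def _mult_noise(rng, cv: float, size) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    return 1.0 + cv * rng.standard_normal(size)


def generate_dataset(
    profile: CultivarProfile,
    times=DEFAULT_TIMES,
    n_fruit: int = 15,
    n_strips_per_time: int = 15,
    n_lenticel_reps: int = 6,
    n_cells: int = 5,
    curve_samples: int = 600,
) -> SyntheticBundle:
    """Generate every input table for one cultivar, deterministically.

    All tables derive from ``profile.seed`` through independent per-table
    child streams, so regenerating with the same profile is byte-identical
    and regenerating a single table does not perturb the others.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if n_fruit < 1:
        raise ValueError("n_fruit must be >= 1")
    p = profile
    tables: dict[str, pd.DataFrame] = {}

    area_true = p.area_cm2(times)

    # --- fruit dimensions (sphere-consistent, mass from unit density) ---
    rng = _rng(p.seed, "fruit_dimensions")
    rows = []
    for t, a in zip(times, area_true):
        a_noisy = a * _mult_noise(rng, p.cv_area, n_fruit)
        for j, ai in enumerate(a_noisy):
            d = math.sqrt(ai * 100.0 / math.pi)  # mm, sphere with area ai
            r_cm = d / 20.0
            rows.append(
                {
                    "cultivar": p.name,
                    "fruit_id": f"{p.name}-f{j}",
                    "dafb": t,
                    "length_mm": round(d, 3),
                    "diam1_mm": round(d, 3),
                    "diam2_mm": round(d, 3),
                    "mass_g": round(4.0 / 3.0 * math.pi * r_cm**3, 3),
                }
            )
    tables["fruit_dimensions"] = pd.DataFrame(rows)

    # --- growth: whole-fruit areas + regional dot patterns ---
    rng = _rng(p.seed, "growth")
    rows = []
    for t, a in zip(times, area_true):
        for j, ai in enumerate(a * _mult_noise(rng, p.cv_area, n_fruit)):
            rows.append(
                {
                    "cultivar": p.name,
                    "fruit_id": f"{p.name}-f{j}",
                    "region": "whole",
                    "dafb": t,
                    "area_cm2": ai,
                }
            )
    # dot-pattern series: relative units, shared shape, scaled k per region
    for region, k_scale in zip(_REGIONS, p.region_k_scale):
        rel = gw.logistic(times, 10.0, p.k_growth * k_scale, p.t_mid)
        noisy = rel * _mult_noise(rng, p.cv_area, (n_fruit, len(times)))
        for j in range(n_fruit):
            for t, v in zip(times, noisy[j]):
                rows.append(
                    {
                        "cultivar": p.name,
                        "fruit_id": f"{p.name}-f{j}",
                        "region": region,
                        "dafb": t,
                        "area_cm2": v,
                    }
                )
    tables["growth"] = pd.DataFrame(rows)

    # --- disc-area triplets for strain analysis ---
    rng = _rng(p.seed, "disc_areas")
    rows = []
    for t, a in zip(times, area_true):
        radius = equivalent_sphere_radius_mm(float(a))
        a_i0 = curvature_corrected_disc_area(
            DiscGeometry(p.punch_diameter_mm, radius)
        )
        r_cm = float(p.ratio_cm(t))
        r_dcm = float(p.ratio_dcm(t))
        for j in range(n_fruit):
            noise = _mult_noise(rng, p.cv_disc, 3)
            rows.append(
                {
                    "cultivar": p.name,
                    "fruit_id": f"{p.name}-f{j}",
                    "dafb": t,
                    "a_i_mm2": a_i0 * noise[0],
                    "a_cm_mm2": a_i0 * r_cm * noise[1],
                    "a_dcm_mm2": a_i0 * r_dcm * noise[2],
                }
            )
    tables["disc_areas"] = pd.DataFrame(rows)

    # --- cuticle mass per disc ---
    rng = _rng(p.seed, "cuticle_mass")
    rows = []
    for t, a in zip(times, area_true):
        radius = equivalent_sphere_radius_mm(float(a))
        disc_area = curvature_corrected_disc_area(
            DiscGeometry(p.punch_diameter_mm, radius)
        )
        cm_pa = max(float(p.cm_per_area(t)), 0.0)
        for j in range(n_fruit):
            noise = _mult_noise(rng, p.cv_mass, 2)
            cm_ug = cm_pa * disc_area * noise[0]
            dcm_ug = p.dcm_frac * cm_pa * disc_area * noise[1]
            rows.append(
                {
                    "cultivar": p.name,
                    "fruit_id": f"{p.name}-f{j}",
                    "dafb": t,
                    "cm_ug": cm_ug,
                    "dcm_ug": min(dcm_ug, cm_ug),
                    "disc_area_mm2": disc_area,
                }
            )
    tables["cuticle_mass"] = pd.DataFrame(rows)

    # --- tensile curves (long form) + annotations ---
    rng = _rng(p.seed, "tensile_curves")
    t_tensile = times[times >= p.t_ref_tensile]
    chunks, ann_rows, strip_truth = [], [], []
    for t in t_tensile:
        s_true = float(p.stiffness(t))
        f_true = float(p.f_max(t))
        e_true = float(p.eps_max(t))
        for j in range(n_strips_per_time):
            strip = f"{p.name}-t{int(t)}-s{j}"
            strain, force = tensile_curve_shape(s_true, f_true, e_true, curve_samples)
            # post-peak force drop defines the fracture
            step = strain[1] - strain[0]
            strain = np.concatenate([strain, [e_true + step, e_true + 2 * step]])
            force = np.concatenate([force, [0.5 * f_true, 0.1 * f_true]])
            noisy = np.clip(
                force + p.cv_force * f_true * rng.standard_normal(force.shape), 0.0, None
            )
            chunks.append(
                pd.DataFrame(
                    {
                        "strip_id": strip,
                        "cultivar": p.name,
                        "dafb": t,
                        "strain_pct": strain,
                        "force_n": noisy,
                    }
                )
            )
            failed = bool(rng.random() < p.fail_prob(t))
            ann_rows.append({"strip_id": strip, "failed_at_lenticel": int(failed)})
            strip_truth.append(
                {
                    "strip_id": strip,
                    "dafb": float(t),
                    "stiffness": s_true,
                    "f_max": f_true,
                    "eps_max": e_true,
                    "strain_step": float(step),
                }
            )
    tables["tensile_curves"] = pd.concat(chunks, ignore_index=True)
    tables["tensile_annotations"] = pd.DataFrame(ann_rows)

    # --- lenticel counts and areas ---
    rng = _rng(p.seed, "lenticel_counts")
    disc_area = math.pi * (p.punch_diameter_mm / 2.0) ** 2
    rows = []
    for t, a in zip(times, area_true):
        mean_density = p.n_lenticels_total / (float(a) * 100.0)  # per mm^2
        for region, w in zip(_REGIONS, p.region_weights):
            lam = mean_density * w * disc_area
            counts = rng.poisson(lam, n_lenticel_reps)
            for j, c in enumerate(counts):
                rows.append(
                    {
                        "cultivar": p.name,
                        "dafb": t,
                        "region": region,
                        "count": int(c),
                        "disc_area_mm2": disc_area,
                    }
                )
    tables["lenticel_counts"] = pd.DataFrame(rows)

    rng = _rng(p.seed, "lenticel_areas")
    rows = []
    for t in times:
        base = float(p.lenticel_area_mm2(t))
        for j, v in enumerate(base * _mult_noise(rng, p.cv_lenticel_area, n_lenticel_reps)):
            rows.append(
                {"cultivar": p.name, "dafb": t, "lenticel_id": j, "area_mm2": max(v, 1e-6)}
            )
    tables["lenticel_areas"] = pd.DataFrame(rows)

    # --- cell measures ---
    rng = _rng(p.seed, "cell_measures")
    rows = []
    for t in times:
        dt = t - times[0]
        layer_specs = [
            ("epidermis", None, max(20.0 - 0.05 * dt, 5.0), 8.0 + 0.05 * dt),
        ]
        for depth in (30.0, 50.0, 70.0):
            layer_specs.append(
                (
                    "hypodermis",
                    depth,
                    25.0 + p.hypo_anticlinal_slope * dt,
                    p.hypo_periclinal0_um + p.hypo_periclinal_slope * dt,
                )
            )
        for layer, depth, anti, peri in layer_specs:
            for j in range(n_cells):
                noise = _mult_noise(rng, 0.08, 2)
                rows.append(
                    {
                        "cultivar": p.name,
                        "dafb": t,
                        "layer": layer,
                        "depth_um": depth if depth is not None else np.nan,
                        "anticlinal_diam_um": anti * noise[0],
                        "periclinal_diam_um": peri * noise[1],
                    }
                )
    tables["cell_measures"] = pd.DataFrame(rows)

    # --- generating truth ---
    t_final = float(times[-1])
    r_cm_f = float(p.ratio_cm(t_final))
    r_dcm_f = float(p.ratio_dcm(t_final))
    truth = {
        "profile": dataclasses.asdict(p),
        "times": [float(t) for t in times],
        "max_growth_rate_cm2_per_day": p.a_max_cm2 * p.k_growth / 4.0,
        "dafb_at_max_growth": p.t_mid,
        # onset measured operationally: 1% of the deposition rate at the
        # first sampling time (the reference the estimator uses)
        "deposition_onset_dafb": float(times[0]) + math.log(100.0) / p.r_dep,
        "apparent_eps_exc_iso_final_pct": (1.0 - r_cm_f) / r_dcm_f * 100.0,
        "apparent_eps_extr_final_pct": (r_cm_f - r_dcm_f) / r_dcm_f * 100.0,
        "apparent_eps_total_final_pct": (1.0 - r_dcm_f) / r_dcm_f * 100.0,
        "tensile_strips": strip_truth,
        "lenticel_failure_prob_final": float(p.fail_prob(t_final)),
    }
    return SyntheticBundle(profile=p, tables=tables, truth=truth)


# ----------------------------------------------------------------------
# end-to-end directional contrasts

CONTRAST_NAMES = (
    "lower_max_growth_rate",
    "earlier_deposition_plateau",
    "higher_eps_exc_iso_at_matched_eps_total",
    "higher_eps_extr_at_matched_eps_total",
    "earlier_breakpoint",
    "lower_stiffness_and_fmax",
    "larger_lenticel_areas",
    "higher_lenticel_failure_frequency",
)


def _pipeline_summary(bundle: SyntheticBundle, a0_cm2: float = st.DEFAULT_A0_CM2) -> dict:
    """Run the analysis modules on one bundle; the numbers the contrasts use."""
    import warnings as _warnings
    # growth: fit the mean whole-fruit series
    g = bundle.tables["growth"]
    whole = g[g["region"] == "whole"].groupby("dafb")["area_cm2"].mean()
    series = gw.GrowthSeries(bundle.profile.name, whole.index.to_numpy(), whole.to_numpy())
    fit = gw.fit_sigmoid(series)
    max_rate, t_at_max = gw.max_growth_rate(fit)

    # deposition: CM mass per area, mean per time
    cm = bundle.tables["cuticle_mass"].copy()
    cm["cm_per_area"] = cm["cm_ug"] / cm["disc_area_mm2"]
    per_time = cm.groupby("dafb")["cm_per_area"].mean()
    dfit = dep.fit_deposition(per_time.index.to_numpy(), per_time.to_numpy())
    onset = dep.area_matched_onset(dfit)

    # strain partition from mean disc ratios per time
    d = bundle.tables["disc_areas"]
    means = d.groupby("dafb")[["a_i_mm2", "a_cm_mm2", "a_dcm_mm2"]].mean()
    eps_total, eps_ei, eps_ex = [], [], []
    apparent_final = None
    for t, row in means.iterrows():
        with _warnings.catch_warnings():
            # early-development discs are strain-free; noise can invert the
            # area ordering there, which the record flags by design
            _warnings.simplefilter("ignore", st.StrainInputWarning)
            rec = st.DiscStrainRecord(
                bundle.profile.name, float(t), row["a_i_mm2"], row["a_cm_mm2"], row["a_dcm_mm2"]
            )
        cs = st.cumulative_strains(rec, float(fit.predict(t)), a0_cm2)
        eps_total.append(cs.eps_total)
        eps_ei.append(cs.eps_exc_iso)
        eps_ex.append(cs.eps_extr)
        ap = st.apparent_strains(rec)
        apparent_final = ap  # last time point wins (times are sorted)
    eps_total = np.asarray(eps_total)
    eps_ei = np.asarray(eps_ei)
    eps_ex = np.asarray(eps_ex)
    bp = seg.fit_segmented(eps_total, eps_ei)

    # tensile
    curves = bundle.tables["tensile_curves"]
    ann = bundle.tables["tensile_annotations"].set_index("strip_id")["failed_at_lenticel"]
    summaries = []
    for strip_id, grp in curves.groupby("strip_id"):
        grp = grp.sort_values("strain_pct")
        curve = tens.TensileCurve(
            strip_id=strip_id,
            cultivar=bundle.profile.name,
            dafb=float(grp["dafb"].iloc[0]),
            strain_pct=grp["strain_pct"].to_numpy(),
            force_n=grp["force_n"].to_numpy(),
            failed_at_lenticel=bool(ann.loc[strip_id]),
        )
        summaries.append(tens.analyze_curve(curve))
    mean_s = float(np.mean([s.stiffness_n_per_pct for s in summaries]))
    mean_f = float(np.mean([s.f_max_n for s in summaries]))
    fail_freq = tens.lenticel_failure_frequency(summaries)

    mean_lenticel_area = float(bundle.tables["lenticel_areas"]["area_mm2"].mean())

    return {
        "max_growth_rate": max_rate,
        "dafb_at_max_growth": t_at_max,
        "deposition_onset": onset,
        "eps_total": eps_total,
        "eps_exc_iso": eps_ei,
        "eps_extr": eps_ex,
        "apparent_final_total_pct": apparent_final.eps_total_pct,
        "breakpoint": bp.breakpoint_x,
        "mean_stiffness": mean_s,
        "mean_f_max": mean_f,
        "lenticel_failure_frequency": fail_freq,
        "mean_lenticel_area": mean_lenticel_area,
    }


def _matched_mean(sa: dict, sb: dict, key: str) -> tuple[float, float]:
    """Means of component-vs-eps_total curves interpolated on a shared grid."""
    lo = max(sa["eps_total"].min(), sb["eps_total"].min())
    hi = min(sa["eps_total"].max(), sb["eps_total"].max())
    grid = np.linspace(lo, hi, 50)
    ya = np.interp(grid, sa["eps_total"], sa[key])
    yb = np.interp(grid, sb["eps_total"], sb[key])
    return float(ya.mean()), float(yb.mean())


def _contrasts_one(sa: dict, sb: dict) -> dict[str, bool]:
    """Contrast booleans for one replicate pair of pipeline summaries."""
    ei_a, ei_b = _matched_mean(sa, sb, "eps_exc_iso")
    ex_a, ex_b = _matched_mean(sa, sb, "eps_extr")
    return {
        "lower_max_growth_rate": sa["max_growth_rate"] < sb["max_growth_rate"],
        "earlier_deposition_plateau": (
            sa["deposition_onset"] is not None
            and sb["deposition_onset"] is not None
            and sa["deposition_onset"] < sb["deposition_onset"]
        ),
        "higher_eps_exc_iso_at_matched_eps_total": ei_a > ei_b,
        "higher_eps_extr_at_matched_eps_total": ex_a > ex_b,
        "earlier_breakpoint": sa["breakpoint"] < sb["breakpoint"],
        "lower_stiffness_and_fmax": (
            sa["mean_stiffness"] < sb["mean_stiffness"] and sa["mean_f_max"] < sb["mean_f_max"]
        ),
        "larger_lenticel_areas": sa["mean_lenticel_area"] > sb["mean_lenticel_area"],
        "higher_lenticel_failure_frequency": (
            sa["lenticel_failure_frequency"] > sb["lenticel_failure_frequency"]
        ),
    }


def _replicate_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(7, i)).generate_state(1)[0] % 2**31)


def evaluate_contrasts(
    profile_a: CultivarProfile,
    profile_b: CultivarProfile,
    n_replicates: int = 5,
    times=DEFAULT_TIMES,
    n_fruit: int = 15,
    a0_cm2: float = st.DEFAULT_A0_CM2,
) -> dict[str, bool]:
    """The eight directional susceptible-vs-non-susceptible contrasts.

    ``profile_a`` plays the russet-susceptible role.  ``n_replicates``
    independent dataset pairs are generated (replicate seeds derived from
    each profile's own seed) and fully analyzed; each contrast is decided
    by majority vote over replicates, the standard guard against a single
    noisy draw.  Every contrast is a strict inequality, so swapping the
    two profiles reverses every verdict exactly.
    """
    votes = dict.fromkeys(CONTRAST_NAMES, 0)
    for i in range(n_replicates):
        pa = dataclasses.replace(profile_a, seed=_replicate_seed(profile_a.seed, i))
        pb = dataclasses.replace(profile_b, seed=_replicate_seed(profile_b.seed, i))
        sa = _pipeline_summary(generate_dataset(pa, times=times, n_fruit=n_fruit), a0_cm2)
        sb = _pipeline_summary(generate_dataset(pb, times=times, n_fruit=n_fruit), a0_cm2)
        for k, v in _contrasts_one(sa, sb).items():
            votes[k] += int(v)
    return {k: 2 * votes[k] > n_replicates for k in CONTRAST_NAMES}
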