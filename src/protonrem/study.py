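"""End-to-end study driver.

Reproduces the full workflow on a synthetic cohort: for every patient a 4D
phantom is generated, a clinical-style plan is robustly optimized at the
largest setup uncertainty, plans at the reduced uncertainties are regenerated
by dose mimicking, every plan is checked with the 3D robustness evaluation at
its own setup uncertainty, all plans are then compared under the identical
comprehensive 4D evaluation (weekly anatomies, breathing interplay, residual
setup/range errors), and the organ-dose / NTCP statistics are assembled with
paired Wilcoxon tests and Bonferroni control.

The default cohort mirrors a 10-patient mediastinal-lymphoma case mix: the
published course schedules (15 x 2.0 or 11 x 1.8 Gy(RBE)) and per-patient
point-max target motion (5-20 mm) are used as generator inputs, with the
remaining geometry jittered per patient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dataclasses_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import outcomes
from .eval3d import run_3drem
from .eval4d import TimingModel, run_4drem
from .phantom4d import (
    OOI_NAMES,
    PhantomConfig,
    compute_motion_stats,
    generate_phantom,
    make_average_ct,
)
from .planner import (
    MimicReference,
    ObjectiveSpec,
    OOITerm,
    SolverOptions,
    dose_mimic,
    make_plan_template,
    robust_optimize,
)
from .scenarios import (
    FractionErrorModel,
    evaluation_scenarios,
    optimization_scenarios,
)

__all__ = [
    "PatientSpec",
    "StudyConfig",
    "StudyResult",
    "DEFAULT_COHORT",
    "run_patient",
    "run_study",
    "write_study_outputs",
]


@dataclass
class PatientSpec:
    """Course prescription and target motion of one synthetic patient."""

    prescription_gy: float
    n_fractions: int
    point_max_motion_mm: float


# course schedules (15 x 2.0 / 11 x 1.8 Gy(RBE)) and point-max target motion
# of the emulated 10-patient case mix
DEFAULT_COHORT = [
    PatientSpec(30.0, 15, 20.0),
    PatientSpec(30.0, 15, 13.0),
    PatientSpec(30.0, 15, 17.0),
    PatientSpec(30.0, 15, 6.0),
    PatientSpec(30.0, 15, 14.0),
    PatientSpec(30.0, 15, 5.0),
    PatientSpec(19.8, 11, 6.0),
    PatientSpec(19.8, 11, 9.0),
    PatientSpec(19.8, 11, 6.5),
    PatientSpec(30.0, 15, 10.0),
]


@dataclass
class StudyConfig:
    n_patients: int = 10
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 3.0
    setup_uncertainties_mm: tuple[float, ...] = (5.0, 4.0, 3.0)
    range_uncertainty_pct: float = 3.0
    n_fractions_sim: int = 8
    n_scenarios_4d: int = 14
    seed: int = 1
    max_iter: int = 200
    mimic_max_iter: int = 150
    tol: float = 1e-6
    ntcp_coefficient_per_gy: float = 0.074
    ooi_weight: float = 1.0
    body_weight: float = 0.15
    target_weight: float = 10.0
    weekly_variation_mm: float = 2.0
    spot_sigma_mm: float = 7.0
    layer_spacing_mm: float = 10.0
    cohort: list[PatientSpec] = field(default_factory=lambda: list(DEFAULT_COHORT))

    def validate(self):
        su = self.setup_uncertainties_mm
        if any(b >= a for a, b in zip(su, su[1:])):
            raise ValueError("setup uncertainties must be strictly decreasing")
        if self.n_patients < 1 or self.n_patients > len(self.cohort):
            raise ValueError("n_patients out of range for the configured cohort")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = [PatientSpec(**p) for p in d["cohort"]]
        for key in ("grid_shape", "setup_uncertainties_mm"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses_fields(cls)}
        if unknown:
            raise ValueError(f"unknown study-config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def _patient_phantom_config(cfg: StudyConfig, i: int, spec: PatientSpec) -> PhantomConfig:
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1000 + i])
    radii_scale = rng.uniform(0.85, 1.2, size=3)
    base = np.array([12.0, 10.0, 14.0])
    ctv_radii = tuple(base * radii_scale)
    ctv_center = (
        float(rng.uniform(-4.0, 4.0)),
        -6.0,
        8.0 + float(rng.uniform(-4.0, 4.0)),
    )
    return PhantomConfig(
        grid_shape=tuple(cfg.grid_shape),
        spacing_mm=cfg.spacing_mm,
        ctv_center=ctv_center,
        ctv_radii=ctv_radii,
        target_peak_motion_mm=spec.point_max_motion_mm,
        n_weeks=cfg.n_fractions_sim,
        weekly_variation_mm=cfg.weekly_variation_mm,
    )


def _objective(avg, itv, cfg: StudyConfig, prescription: float) -> ObjectiveSpec:
    terms = [
        OOITerm(name, avg.masks[name], cfg.ooi_weight, "mean-dose")
        for name in OOI_NAMES
        if avg.masks.get(name) is not None and avg.masks[name].any()
    ]
    terms.append(OOITerm("body", avg.masks["body"], cfg.body_weight, "mean-dose"))
    return ObjectiveSpec(itv, prescription, cfg.target_weight, terms)


def run_patient(cfg: StudyConfig, i: int) -> dict:
    """Full pipeline for synthetic patient ``i`` (0-based)."""
    spec = cfg.cohort[i]
    ru = cfg.range_uncertainty_pct
    ph_cfg = _patient_phantom_config(cfg, i, spec)
    ph_seed = int(np.random.default_rng([cfg.seed & 0x7FFFFFFF, 3000 + i]).integers(2**31))
    phantom = generate_phantom(ph_cfg, ph_seed)
    motion = compute_motion_stats(phantom)
    avg = make_average_ct(phantom)
    itv = avg.masks["itv"]

    su_list = cfg.setup_uncertainties_mm
    su_ref = su_list[0]
    template = make_plan_template(
        avg, itv,
        gantry_angles=(330.0, 0.0, 30.0),
        prescription=spec.prescription_gy,
        n_fractions=spec.n_fractions,
        setup_margin_mm=su_ref,
        range_uncertainty_pct=ru,
        sigma_lateral=cfg.spot_sigma_mm,
        lateral_spacing=cfg.spot_sigma_mm,
        layer_spacing=cfg.layer_spacing_mm,
    )
    objective = _objective(avg, itv, cfg, spec.prescription_gy)
    opts = SolverOptions(max_iter=cfg.max_iter, tol=cfg.tol)

    ref_result = robust_optimize(
        template, avg, objective, optimization_scenarios(su_ref, ru), opts
    )
    # minimum-MU deliverability filter before any evaluation
    plans = {su_ref: ref_result.plan.pruned()}
    rem3 = {su_ref: run_3drem(plans[su_ref], avg, su_ref, ru, itv)}
    reference = MimicReference(rem3[su_ref].nominal_dose, rem3[su_ref].ooi, su_ref)

    for su in su_list[1:]:
        mim = dose_mimic(
            reference, template, avg,
            optimization_scenarios(su, ru), objective,
            SolverOptions(max_iter=cfg.mimic_max_iter, tol=cfg.tol,
                          init_weights=ref_result.weights),
        )
        plans[su] = mim.plan.pruned()
        rem3[su] = run_3drem(plans[su], avg, su, ru, itv)

    seed_4d = int(np.random.default_rng([cfg.seed & 0x7FFFFFFF, 2000 + i]).integers(2**31))
    error_model = FractionErrorModel(range_levels_pct=(-ru, 0.0, ru))
    rem4 = {}
    for su in su_list:
        # identical comprehensive uncertainty realization for all plans:
        # the 4D evaluation compares plans, not error draws
        rem4[su] = run_4drem(
            plans[su], phantom, error_model, seed=seed_4d,
            n_fractions=cfg.n_fractions_sim, n_scenarios=cfg.n_scenarios_4d,
            timing=TimingModel(),
        )

    rng_p = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 5000 + i])
    baseline = float(rng_p.uniform(6.0, 14.0))
    params = outcomes.ACEModelParams(baseline, cfg.ntcp_coefficient_per_gy)
    photon_mhd = rem3[su_ref].ooi.mean_dose["heart"] + float(rng_p.uniform(2.5, 7.0))

    return {
        "index": i,
        "spec": spec,
        "motion": motion,
        "plans": plans,
        "rem3": rem3,
        "rem4": rem4,
        "ntcp_params": params,
        "photon_mhd": photon_mhd,
    }


@dataclass
class StudyResult:
    config: StudyConfig
    metrics: pd.DataFrame
    coverage: pd.DataFrame
    tests: pd.DataFrame
    ntcp: pd.DataFrame
    summary: dict
    patients: list[dict]


_METRIC_KEYS = [("mean_" + n, n) for n in OOI_NAMES]


def _collect_metrics(patients, su_list):
    rows = []
    for p in patients:
        for su in su_list:
            ooi3 = p["rem3"][su].ooi
            ooi4 = p["rem4"][su].ooi
            for stage, ooi in (("3d_nominal", ooi3), ("4drem_mean", ooi4)):
                for key, name in _METRIC_KEYS:
                    if name in ooi.mean_dose:
                        rows.append(
                            dict(patient=p["index"] + 1, setting_mm=su, stage=stage,
                                 metric=key, value=ooi.mean_dose[name])
                        )
                for name, v in ooi.vx_pct.items():
                    thr = 5 if name == "lungs" else 4
                    rows.append(
                        dict(patient=p["index"] + 1, setting_mm=su, stage=stage,
                             metric=f"v{thr}_{name}_pct", value=v)
                    )
                for name, v in ooi.vx_cm3.items():
                    thr = 5 if name == "lungs" else 4
                    rows.append(
                        dict(patient=p["index"] + 1, setting_mm=su, stage=stage,
                             metric=f"v{thr}_{name}_cm3", value=v)
                    )
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig()
    cfg.validate()
    su_list = list(cfg.setup_uncertainties_mm)
    patients = [run_patient(cfg, i) for i in range(cfg.n_patients)]

    metrics = _collect_metrics(patients, su_list)

    cov_rows = []
    for p in patients:
        for su in su_list:
            for method, res in (("3drem", p["rem3"][su]), ("4drem", p["rem4"][su])):
                v = res.verdict
                cov_rows.append(
                    dict(patient=p["index"] + 1, setting_mm=su, method=method,
                         d98_pct=v.d98_pct_of_rx, v95_pct=v.v95_pct, passed=v.passed)
                )
    coverage = pd.DataFrame(cov_rows)

    test_rows = []
    alpha_thr = outcomes.bonferroni_threshold(0.05, 3)
    for stage in ("3d_nominal", "4drem_mean"):
        sub = metrics[metrics.stage == stage]
        for key, _ in _METRIC_KEYS:
            by = {
                su: sub[(sub.metric == key) & (sub.setting_mm == su)]
                .sort_values("patient")["value"].to_numpy()
                for su in su_list
            }
            if any(len(v) == 0 for v in by.values()):
                continue
            comps, thr = outcomes.paired_comparisons(key, {f"{su:g}mm": by[su] for su in su_list})
            for c in comps:
                test_rows.append(
                    dict(stage=stage, metric=key, pair=f"{c.setting_a} vs {c.setting_b}",
                         p_value=c.p_value, alpha=thr.displayed, significant=c.significant)
                )
    tests = pd.DataFrame(test_rows)

    ntcp_rows = []
    for p in patients:
        params = p["ntcp_params"]
        for su in su_list:
            mhd4 = p["rem4"][su].ooi.mean_dose["heart"]
            risk = outcomes.ace_ntcp(mhd4, params)
            photon_risk = outcomes.ace_ntcp(p["photon_mhd"], params)
            delta = photon_risk - risk
            ntcp_rows.append(
                dict(patient=p["index"] + 1, setting_mm=su, mhd_4drem_gy=mhd4,
                     ntcp_pct=risk, photon_mhd_gy=p["photon_mhd"],
                     delta_ntcp_vs_photon=delta,
                     mbs_qualifies=outcomes.mbs_gate(delta))
            )
    ntcp = pd.DataFrame(ntcp_rows)

    summary = _summarize(cfg, patients, metrics, coverage, tests, ntcp, su_list, alpha_thr)
    return StudyResult(cfg, metrics, coverage, tests, ntcp, summary, patients)


def _mhd_by_setting(metrics, stage, su_list):
    sub = metrics[(metrics.stage == stage) & (metrics.metric == "mean_heart")]
    return {
        su: sub[sub.setting_mm == su].sort_values("patient")["value"].to_numpy()
        for su in su_list
    }


def _monotone_fraction(by, su_list):
    arr = np.stack([by[su] for su in su_list], axis=1)  # patients x settings
    ok = np.all(np.diff(arr, axis=1) <= 1e-12, axis=1)
    return float(ok.mean())


def _summarize(cfg, patients, metrics, coverage, tests, ntcp, su_list, alpha_thr):
    nom = _mhd_by_setting(metrics, "3d_nominal", su_list)
    m4d = _mhd_by_setting(metrics, "4drem_mean", su_list)
    s = {
        "n_patients": len(patients),
        "n_optimization_scenarios": len(
            optimization_scenarios(su_list[0], cfg.range_uncertainty_pct)
        ),
        "n_evaluation_scenarios": len(
            evaluation_scenarios(su_list[0], cfg.range_uncertainty_pct)
        ),
        "bonferroni_alpha_displayed": alpha_thr.displayed,
        "coverage_pass_fraction_3drem": float(
            coverage[coverage.method == "3drem"]["passed"].mean()
        ),
        "coverage_pass_fraction_4drem": float(
            coverage[coverage.method == "4drem"]["passed"].mean()
        ),
        "mhd_monotone_fraction_nominal": _monotone_fraction(nom, su_list),
        "mhd_monotone_fraction_4drem": _monotone_fraction(m4d, su_list),
        "motion_point_max_mm": [p["motion"].point_max_motion_mm for p in patients],
        "motion_mean_mm": [p["motion"].mean_motion_mm for p in patients],
    }
    for su in su_list:
        s[f"mhd_median_nominal_{su:g}mm"] = float(np.median(nom[su]))
        s[f"mhd_median_4drem_{su:g}mm"] = float(np.median(m4d[su]))
    pair_names = [
        (su_list[0], su_list[1]),
        (su_list[0], su_list[2]),
        (su_list[1], su_list[2]),
    ] if len(su_list) >= 3 else []
    for a, b in pair_names:
        red = []
        for p in patients:
            params = p["ntcp_params"]
            ra = outcomes.ace_ntcp(p["rem4"][a].ooi.mean_dose["heart"], params)
            rb = outcomes.ace_ntcp(p["rem4"][b].ooi.mean_dose["heart"], params)
            red.append(ra - rb)
        s[f"ntcp_reduction_median_{a:g}v{b:g}"] = float(np.median(red))
    for stage_key, stage in (("nominal", "3d_nominal"), ("4drem", "4drem_mean")):
        sub = tests[(tests.stage == stage) & (tests.metric == "mean_heart")]
        for _, row in sub.iterrows():
            pair = row["pair"].replace("mm", "").replace(" vs ", "v")
            s[f"wilcoxon_p_mhd_{stage_key}_{pair}"] = float(row["p_value"])
    return s


def write_study_outputs(result: StudyResult, outdir) -> None:
    """Persist the study tables, summary and a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.coverage.to_csv(outdir / "coverage.csv", index=False)
    result.tests.to_csv(outdir / "tests.csv", index=False)
    result.ntcp.to_csv(outdir / "ntcp.csv", index=False)
    with open(outdir / "summary.json", "w") as f:
        json.dump(result.summary, f, indent=1)
    cfg_dict = asdict(result.config)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": result.config.seed,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
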