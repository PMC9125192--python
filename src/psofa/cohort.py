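"""Synthetic minipig sepsis cohort generator.

Emulates the statistical structure of a fecal-peritonitis minipig study:
each inoculated animal receives a log-uniform inoculum load (total CFU), a
latent severity monotone in log10 CFU drives its trajectory template, and
the supportive-therapy rules run in-loop over the invasive-monitoring
window (16-24 h) so vasopressor and diuretic states arise endogenously
from the simulated physiology rather than being scripted.

Five templates exist: *sham* (saline control, stationary), *non_responder*
(inoculated, never meets sepsis criteria), *sepsis* (organ dysfunction
with lactate >= 2 but no vasopressor need), *septic_shock* (deep
fluid-refractory hypotension, oliguria, late bilirubin rise, elevated big
endothelin and HMGB1) and *fulminant* (overwhelming early deterioration,
humanely terminated between 6 and 15 h, so no monitoring window exists).
Within the inoculated animals, template membership is assigned by latent-
severity rank at the configured study-flow fractions, so label counts are
exact per cohort while the CFU-severity coupling stays a single tunable
slope.  Biomarker timing follows the described kinetics: TNF-alpha peaks
at 6 h, IL-10 at 16 h, bET/HMGB1 rise only in shock over 16-24 h, and
leucopenia bottoms at 16 h.

Trajectories are piecewise-linear template medians modulated by the
within-template severity quantile and multiplied by lognormal measurement
noise.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .micro import BAND_EDGES, severity_band
from .samples import MonitoringSample, TherapyState
from .therapy import TherapyAction, TherapyPolicy, evaluate_triggers

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "perturb"]

#: anchor times (h) of the piecewise-linear templates
_ANCHOR_T = np.array([0.0, 6.0, 12.0, 16.0, 18.0, 20.0, 24.0])

# per-variable template medians at the anchor times, per severity class.
# Values are chosen to lie inside the qualitative ranges the model
# describes (sepsis 3D scores ~1-3, shock ~5-9, persistent lactate >= 2
# only in shock, late bilirubin rise in shock, leucopenia at 16 h).
_TEMPLATES: dict[str, dict[str, list[float]]] = {
    "sham": {
        "map_mmHg": [88, 88, 88, 88, 88, 88, 88],
        "pao2_fio2": [450, 450, 448, 445, 445, 442, 440],
        "urine_output_ml_kg_h": [1.0, 1.0, 1.0, 0.95, 0.95, 0.9, 0.9],
        "bilirubin_umol_L": [10, 10, 10, 11, 11, 11, 12],
        "platelets_1e9_L": [300, 300, 295, 290, 290, 285, 285],
        "lactate_mmol_L": [1.2, 1.2, 1.2, 1.3, 1.3, 1.3, 1.3],
        "svo2_fraction": [0.70, 0.70, 0.70, 0.70, 0.69, 0.69, 0.69],
        "sao2_fraction": [0.97, 0.97, 0.97, 0.97, 0.97, 0.97, 0.97],
        "hb_g_dL": [10, 10, 10, 10, 10, 10, 10],
        "co_L_min": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
        "ci_L_min_m2": [4.5, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5],
        "cvp_mmHg": [6, 6, 6, 6, 6, 6, 6],
        "hr_bpm": [90, 90, 92, 92, 94, 94, 95],
        "ast_U_L": [40, 40, 42, 42, 44, 44, 45],
        "alt_U_L": [45, 45, 45, 46, 46, 46, 47],
        "creatinine_umol_L": [90, 90, 92, 92, 94, 94, 95],
        "albumin_g_L": [32, 32, 32, 31, 31, 31, 30],
        "wbc_1e9_L": [12, 12, 12, 11.5, 11.5, 11.5, 11],
        "elwi_ml_kg": [7, 7, 7, 7, 7, 7, 7],
        "tnfa": [20, 22, 22, 24, 24, 24, 25],
        "il10": [10, 10, 11, 11, 12, 12, 12],
        "bet": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        "hmgb1": [2, 2, 2, 2, 2, 2, 2],
    },
    "non_responder": {
        "map_mmHg": [88, 86, 85, 84, 83, 83, 82],
        "pao2_fio2": [450, 440, 430, 420, 415, 410, 400],
        "urine_output_ml_kg_h": [1.0, 0.95, 0.9, 0.85, 0.85, 0.8, 0.8],
        "bilirubin_umol_L": [10, 11, 12, 13, 13, 14, 15],
        "platelets_1e9_L": [300, 290, 280, 270, 265, 260, 255],
        "lactate_mmol_L": [1.2, 1.3, 1.4, 1.4, 1.5, 1.5, 1.5],
        "svo2_fraction": [0.70, 0.70, 0.71, 0.72, 0.72, 0.72, 0.72],
        "sao2_fraction": [0.97, 0.97, 0.97, 0.97, 0.97, 0.96, 0.96],
        "hb_g_dL": [10, 10, 10.2, 10.3, 10.3, 10.4, 10.5],
        "co_L_min": [4.0, 4.1, 4.2, 4.4, 4.5, 4.5, 4.6],
        "ci_L_min_m2": [4.5, 4.6, 4.7, 4.9, 5.0, 5.0, 5.1],
        "cvp_mmHg": [6, 6, 6, 6, 6, 6, 6],
        "hr_bpm": [90, 94, 96, 100, 100, 102, 104],
        "ast_U_L": [40, 44, 48, 52, 54, 56, 60],
        "alt_U_L": [45, 46, 47, 48, 48, 49, 50],
        "creatinine_umol_L": [90, 95, 100, 105, 105, 110, 110],
        "albumin_g_L": [32, 31, 30, 28, 27, 27, 26],
        "wbc_1e9_L": [12, 11, 10, 9, 9.5, 10, 10.5],
        "elwi_ml_kg": [7, 7, 7.2, 7.4, 7.4, 7.6, 7.6],
        "tnfa": [20, 60, 45, 35, 32, 30, 28],
        "il10": [10, 18, 25, 35, 30, 26, 22],
        "bet": [0.5, 0.5, 0.5, 0.55, 0.55, 0.6, 0.6],
        "hmgb1": [2, 2.2, 2.4, 2.6, 2.6, 2.8, 2.8],
    },
    "sepsis": {
        "map_mmHg": [88, 84, 79, 75, 72, 71, 69],
        "pao2_fio2": [450, 430, 400, 360, 330, 310, 290],
        "urine_output_ml_kg_h": [1.0, 0.9, 0.75, 0.5, 0.35, 0.32, 0.30],
        "bilirubin_umol_L": [10, 12, 14, 18, 20, 22, 24],
        "platelets_1e9_L": [300, 280, 250, 220, 200, 185, 170],
        "lactate_mmol_L": [1.2, 1.7, 2.0, 2.3, 2.6, 2.7, 2.8],
        "svo2_fraction": [0.70, 0.68, 0.66, 0.64, 0.63, 0.62, 0.61],
        "sao2_fraction": [0.97, 0.97, 0.96, 0.96, 0.95, 0.95, 0.94],
        "hb_g_dL": [10, 10.2, 10.4, 10.6, 10.8, 11, 11],
        "co_L_min": [4.0, 4.2, 4.4, 4.6, 4.7, 4.8, 4.8],
        "ci_L_min_m2": [4.5, 4.7, 4.9, 5.1, 5.2, 5.3, 5.3],
        "cvp_mmHg": [6, 6, 6, 7, 7, 7, 7],
        "hr_bpm": [90, 100, 105, 110, 112, 115, 118],
        "ast_U_L": [40, 50, 60, 70, 75, 80, 85],
        "alt_U_L": [45, 47, 49, 51, 52, 53, 54],
        "creatinine_umol_L": [90, 100, 110, 120, 125, 130, 135],
        "albumin_g_L": [32, 30, 28, 27, 26, 26, 25],
        "wbc_1e9_L": [12, 10, 8, 5, 6, 7, 8],
        "elwi_ml_kg": [7, 7.2, 7.5, 7.8, 8.0, 8.2, 8.4],
        "tnfa": [20, 300, 150, 80, 65, 55, 45],
        "il10": [10, 30, 60, 120, 95, 75, 55],
        "bet": [0.5, 0.5, 0.55, 0.6, 0.6, 0.65, 0.7],
        "hmgb1": [2, 2.5, 3, 3.5, 3.5, 4, 4],
    },
    "septic_shock": {
        "map_mmHg": [88, 80, 70, 60, 45, 44, 42],
        "pao2_fio2": [450, 400, 330, 270, 240, 215, 180],
        "urine_output_ml_kg_h": [1.0, 0.8, 0.6, 0.38, 0.22, 0.18, 0.12],
        "bilirubin_umol_L": [10, 14, 18, 22, 26, 40, 80],
        "platelets_1e9_L": [300, 250, 200, 150, 120, 95, 70],
        "lactate_mmol_L": [1.2, 2.2, 2.8, 3.4, 3.9, 4.3, 5.0],
        "svo2_fraction": [0.70, 0.66, 0.62, 0.58, 0.55, 0.53, 0.50],
        "sao2_fraction": [0.97, 0.96, 0.95, 0.94, 0.93, 0.92, 0.90],
        "hb_g_dL": [10, 10.5, 11, 11.4, 11.6, 11.8, 12],
        "co_L_min": [4.0, 4.3, 4.6, 4.9, 5.0, 5.0, 4.8],
        "ci_L_min_m2": [4.5, 4.8, 5.1, 5.4, 5.5, 5.5, 5.3],
        "cvp_mmHg": [6, 6, 7, 7, 8, 8, 8],
        "hr_bpm": [90, 105, 115, 128, 135, 140, 145],
        "ast_U_L": [40, 60, 90, 130, 160, 180, 210],
        "alt_U_L": [45, 50, 56, 62, 68, 72, 80],
        "creatinine_umol_L": [90, 110, 135, 165, 185, 200, 220],
        "albumin_g_L": [32, 29, 26, 23, 22, 21, 20],
        "wbc_1e9_L": [12, 9, 6, 3, 3.5, 4, 5],
        "elwi_ml_kg": [7, 7.5, 8.2, 9.0, 9.6, 10.2, 11.0],
        "tnfa": [20, 900, 420, 210, 160, 130, 105],
        "il10": [10, 60, 120, 250, 190, 150, 110],
        "bet": [0.5, 0.55, 0.7, 2.0, 3.0, 3.5, 4.0],
        "hmgb1": [2, 2.5, 3.5, 8, 12, 15, 18],
    },
    # terminated at 6-15 h: only the early anchors matter
    "fulminant": {
        "map_mmHg": [88, 62, 50, 45, 45, 45, 45],
        "pao2_fio2": [450, 200, 110, 90, 90, 90, 90],
        "urine_output_ml_kg_h": [1.0, 0.4, 0.15, 0.1, 0.1, 0.1, 0.1],
        "bilirubin_umol_L": [10, 25, 40, 50, 50, 50, 50],
        "platelets_1e9_L": [300, 200, 120, 90, 90, 90, 90],
        "lactate_mmol_L": [1.2, 4.0, 5.5, 6.0, 6.0, 6.0, 6.0],
        "svo2_fraction": [0.70, 0.40, 0.38, 0.35, 0.35, 0.35, 0.35],
        "sao2_fraction": [0.97, 0.92, 0.88, 0.86, 0.86, 0.86, 0.86],
        "hb_g_dL": [10, 12, 13, 13.5, 13.5, 13.5, 13.5],
        "co_L_min": [4.0, 4.5, 4.0, 3.6, 3.6, 3.6, 3.6],
        "ci_L_min_m2": [4.5, 5.0, 4.5, 4.0, 4.0, 4.0, 4.0],
        "cvp_mmHg": [6, 7, 8, 8, 8, 8, 8],
        "hr_bpm": [90, 130, 150, 160, 160, 160, 160],
        "ast_U_L": [40, 90, 180, 240, 240, 240, 240],
        "alt_U_L": [45, 55, 70, 80, 80, 80, 80],
        "creatinine_umol_L": [90, 130, 190, 230, 230, 230, 230],
        "albumin_g_L": [32, 15, 13, 12, 12, 12, 12],
        "wbc_1e9_L": [12, 6, 3, 2, 2, 2, 2],
        "elwi_ml_kg": [7, 9, 11, 12, 12, 12, 12],
        "tnfa": [20, 1500, 700, 400, 400, 400, 400],
        "il10": [10, 80, 180, 250, 250, 250, 250],
        "bet": [0.5, 1.5, 3.5, 5.0, 5.0, 5.0, 5.0],
        "hmgb1": [2, 6, 14, 20, 20, 20, 20],
    },
}

#: fraction-valued variables get tighter noise and [0, 1] clipping
_FRACTION_VARS = ("svo2_fraction", "sao2_fraction")

_CLASSES = ("sham", "non_responder", "sepsis", "septic_shock", "fulminant")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults reproduce the study flow: 36 animals of which a quarter are
    saline shams; among the 27 inoculated, 5/27 non-responders, 3/27
    fulminant and 9/19 of the remaining septic animals in shock.  The
    inoculum load is log10-uniform over ``cfu_log10_range`` (total CFU,
    spanning 6.2e5-1.6e10); ``severity_coupling`` is the slope of the
    latent severity on log10 CFU and ``severity_noise_sd`` the latent
    Gaussian noise, so coupling 0 decouples outcome from load entirely.
    """

    n_animals: int = 36
    sham_fraction: float = 0.25
    seed: int = 0
    cfu_log10_range: tuple[float, float] = (5.8, 10.2)
    severity_coupling: float = 1.0
    severity_noise_sd: float = 0.5
    noise_cv: float = 0.08
    fraction_noise_cv: float = 0.02
    map_noise_cv: float = 0.03
    nonresponder_fraction: float = 5 / 27
    fulminant_fraction: float = 3 / 27
    shock_fraction_of_septic: float = 9 / 19
    suspension_volume_ml: float = 200.0
    tnfa_peak_h: float = 6.0
    il10_peak_h: float = 16.0
    shock_marker_window: tuple[float, float] = (16.0, 24.0)
    window: tuple[float, float] = (16.0, 24.0)
    early_times: tuple[float, ...] = (0.0, 6.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if not 0 <= self.sham_fraction < 1:
            raise ValueError("sham_fraction must be in [0, 1)")
        if self.severity_coupling < 0:
            raise ValueError("severity_coupling must be >= 0")
        lo, hi = self.cfu_log10_range
        if not lo < hi:
            raise ValueError("cfu_log10_range must be ordered")
        for name in (
            "noise_cv", "fraction_noise_cv", "map_noise_cv", "severity_noise_sd"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        lo, hi = self.window
        return np.concatenate(
            [np.asarray(self.early_times), np.arange(lo, hi + 0.5)]
        )

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=list)
        return {
            "config": d,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        }


@dataclass
class Cohort:
    """Generated cohort tables, same schemas the scoring pipeline reads."""

    monitoring: pd.DataFrame
    therapy: pd.DataFrame
    microbiology: pd.DataFrame
    labels: pd.DataFrame
    config: CohortConfig

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("monitoring", "therapy", "microbiology", "labels"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        manifest = self.config.manifest()
        manifest["seed"] = self.config.seed
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=list) + "\n"
        )
        paths["manifest"] = outdir / "manifest.json"
        return paths


def _assign_classes(
    cfg: CohortConfig, latent: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rank inoculated animals by latent severity; fill study-flow quotas.

    Returns (class name per animal, within-class severity quantile u').
    """
    n = len(latent)
    n_nr = int(round(n * cfg.nonresponder_fraction))
    n_ful = int(round(n * cfg.fulminant_fraction))
    n_septic = n - n_nr - n_ful
    n_shock = int(round(n_septic * cfg.shock_fraction_of_septic))
    order = np.argsort(latent, kind="stable")
    classes = np.empty(n, dtype=object)
    uprime = np.zeros(n)

    blocks = [
        ("non_responder", order[:n_nr]),
        ("sepsis", order[n_nr : n_nr + (n_septic - n_shock)]),
        ("septic_shock", order[n_nr + (n_septic - n_shock) : n - n_ful]),
        ("fulminant", order[n - n_ful :]),
    ]
    for name, idx in blocks:
        classes[idx] = name
        k = len(idx)
        if k:
            uprime[idx] = (np.arange(k) + 0.5) / k  # idx already sorted by s
    return classes, uprime


def _interp_template(cls: str, var: str, times: np.ndarray) -> np.ndarray:
    return np.interp(times, _ANCHOR_T, np.asarray(_TEMPLATES[cls][var], float))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate one cohort; deterministic under fixed config + seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    policy = TherapyPolicy()

    n_sham = int(round(cfg.n_animals * cfg.sham_fraction))
    n_inoc = cfg.n_animals - n_sham

    lo, hi = cfg.cfu_log10_range
    log_cfu = rng.uniform(lo, hi, size=n_inoc)
    latent = cfg.severity_coupling * (log_cfu - lo) + rng.normal(
        0.0, cfg.severity_noise_sd, size=n_inoc
    )
    classes, uprime = _assign_classes(cfg, latent)
    # severity amplitude: template deviations scaled by within-class rank
    amp = 0.85 + 0.30 * uprime

    term_time = 6.0 + 9.0 * rng.uniform(size=n_inoc)  # fulminant endpoints

    monitoring_rows: list[dict] = []
    therapy_rows: list[dict] = []
    micro_rows: list[dict] = []
    label_rows: list[dict] = []

    def _noise(var: str, size: int) -> np.ndarray:
        if var in _FRACTION_VARS:
            cv = cfg.fraction_noise_cv
        elif var == "map_mmHg":
            cv = cfg.map_noise_cv  # arterial pressure traces are smooth
        else:
            cv = cfg.noise_cv
        return np.exp(rng.normal(0.0, cv, size=size))

    def _trajectory(cls: str, a: float, times: np.ndarray) -> dict[str, np.ndarray]:
        base = {v: _TEMPLATES["sham"][v][0] for v in _TEMPLATES["sham"]}
        out = {}
        for var in _TEMPLATES[cls]:
            med = _interp_template(cls, var, times)
            dev = med - base[var]
            vals = (base[var] + a * dev) * _noise(var, len(times))
            if var in _FRACTION_VARS:
                vals = np.clip(vals, 0.0, 1.0)
            else:
                vals = np.maximum(vals, 0.0)
            out[var] = vals
        return out

    animal_ids = [f"P{i+1:03d}" for i in range(cfg.n_animals)]
    sham_ids = set(animal_ids[:n_sham])

    for i, aid in enumerate(animal_ids):
        if aid in sham_ids:
            cls, a, u = "sham", 1.0, 0.0
        else:
            j = i - n_sham
            cls, a, u = classes[j], amp[j], uprime[j]

        if cls == "fulminant":
            t_end = term_time[i - n_sham]
            times = np.array(
                [t for t in cfg.early_times if t <= t_end], dtype=float
            )
        else:
            times = cfg.time_grid

        traj = _trajectory(cls, a, times)

        # in-loop supportive therapy over the monitoring window
        ne_dose = 0.0
        furo_cum = 0.0
        minutes_fluid = 0.0
        n_furo = 0
        held_map = 68.0 - 16.0 * u  # vasopressor MAP response (severity-dep.)
        w_lo, w_hi = cfg.window

        for k, t in enumerate(times):
            in_window = w_lo <= t <= w_hi
            cryst = 15.0 if in_window else 0.0
            if in_window and t > w_lo:
                minutes_fluid += 60.0

            map_t = traj["map_mmHg"][k]
            if ne_dose > 0:
                map_t = held_map * float(_noise("map_mmHg", 1)[0])
            urine_t = traj["urine_output_ml_kg_h"][k] + 0.10 * (1.0 - u) * n_furo
            pf = traj["pao2_fio2"][k]

            state = TherapyState(
                norepinephrine_ug_kg_min=ne_dose,
                furosemide_cum_mg=furo_cum,
                crystalloid_ml_kg_h=cryst,
                minutes_on_fluid_resuscitation=minutes_fluid,
            )
            sample = MonitoringSample(
                time_h=float(t),
                map_mmHg=float(map_t),
                pao2_fio2=float(pf),
                urine_output_ml_kg_h=float(urine_t),
                bilirubin_umol_L=float(traj["bilirubin_umol_L"][k]),
                platelets_1e9_L=float(traj["platelets_1e9_L"][k]),
                lactate_mmol_L=float(traj["lactate_mmol_L"][k]),
                pao2_mmHg=float(pf * 0.21),
                fio2_fraction=0.21,
                sao2_fraction=float(traj["sao2_fraction"][k]),
                svo2_fraction=float(traj["svo2_fraction"][k]),
                hb_g_dL=float(traj["hb_g_dL"][k]),
                co_L_min=float(traj["co_L_min"][k]),
                ci_L_min_m2=float(traj["ci_L_min_m2"][k]),
                cvp_mmHg=float(traj["cvp_mmHg"][k]),
                hr_bpm=float(traj["hr_bpm"][k]),
                ast_U_L=float(traj["ast_U_L"][k]),
                alt_U_L=float(traj["alt_U_L"][k]),
                creatinine_umol_L=float(traj["creatinine_umol_L"][k]),
                albumin_g_L=float(traj["albumin_g_L"][k]),
                wbc_1e9_L=float(traj["wbc_1e9_L"][k]),
                elwi_ml_kg=float(traj["elwi_ml_kg"][k]),
                tnfa=float(traj["tnfa"][k]),
                il10=float(traj["il10"][k]),
                bet=float(traj["bet"][k]),
                hmgb1=float(traj["hmgb1"][k]),
            )

            if in_window:
                actions = evaluate_triggers(sample, state, policy)
                if TherapyAction.START_NOREPINEPHRINE in actions:
                    ne_dose = policy.norepi_start_ug_kg_min
                elif ne_dose > 0 and map_t <= policy.map_norepi_trigger_mmHg:
                    ne_dose *= 2.0  # unresponsive hour: double
                if TherapyAction.GIVE_FUROSEMIDE in actions:
                    furo_cum += policy.furosemide_bolus_mg
                    n_furo += 1
                state = TherapyState(
                    norepinephrine_ug_kg_min=ne_dose,
                    furosemide_cum_mg=furo_cum,
                    crystalloid_ml_kg_h=cryst,
                    minutes_on_fluid_resuscitation=minutes_fluid,
                )

            row = {"animal_id": aid}
            row.update(
                {f: getattr(sample, f) for f in MonitoringSample.field_names()}
            )
            monitoring_rows.append(row)
            therapy_rows.append(
                {
                    "animal_id": aid,
                    "time_h": float(t),
                    "norepinephrine_ug_kg_min": state.norepinephrine_ug_kg_min,
                    "furosemide_cum_mg": state.furosemide_cum_mg,
                    "crystalloid_ml_kg_h": state.crystalloid_ml_kg_h,
                    "minutes_on_fluid_resuscitation": state.minutes_on_fluid_resuscitation,
                }
            )

        if aid in sham_ids:
            micro_rows.append(
                {
                    "animal_id": aid,
                    "cfu_per_ml": 0.0,
                    "total_cfu": 0.0,
                    "severity_band": "",
                    "hemoculture_cfu_per_ml": 0.0,
                    "hemoculture_positive": False,
                }
            )
            label_rows.append({"animal_id": aid, "true_label": "sham"})
        else:
            j = i - n_sham
            total = 10.0 ** log_cfu[j]
            # bacteremia proportional to realized severity, lognormal spread
            sev_q = (np.searchsorted(np.sort(latent), latent[j]) + 0.5) / n_inoc
            hemo = 10.0 ** (1.0 + 3.0 * sev_q + rng.normal(0.0, 0.3))
            positive = cls in ("sepsis", "septic_shock", "fulminant")
            micro_rows.append(
                {
                    "animal_id": aid,
                    "cfu_per_ml": total / cfg.suspension_volume_ml,
                    "total_cfu": total,
                    "severity_band": severity_band(total),
                    "hemoculture_cfu_per_ml": hemo if positive else 0.0,
                    "hemoculture_positive": positive,
                }
            )
            label_rows.append({"animal_id": aid, "true_label": cls})

    return Cohort(
        monitoring=pd.DataFrame(monitoring_rows),
        therapy=pd.DataFrame(therapy_rows),
        microbiology=pd.DataFrame(micro_rows),
        labels=pd.DataFrame(label_rows),
        config=cfg,
    )


def perturb(config: CohortConfig, parameter: str, delta: float) -> CohortConfig:
    """Pure config transform for sensitivity sweeps: parameter += delta."""
    if not hasattr(config, parameter):
        raise KeyError(f"unknown config parameter {parameter!r}")
    value = getattr(config, parameter)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise TypeError(f"parameter {parameter!r} is not numeric")
    new_value = value + delta
    if parameter == "n_animals":
        new_value = int(new_value)
    return replace(config, **{parameter: new_value})
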