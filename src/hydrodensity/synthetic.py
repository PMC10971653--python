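"""Synthetic cohorts with known ground truth for parameter-recovery testing.

The study's raw data are not deposited, so the pipeline is validated
against forward-simulated cohorts instead: draw a population with latent
true body density, head volume and lung volumes, simulate the girth
protocol and the in-water weighings (Archimedes run forwards, plus
measurement noise), and check that the analysis chain recovers the truth.

Sex-specific demographic defaults (sample sizes, height/mass/girth/age
moments) reproduce the study cohort's marginal structure.  Effect knobs —
head-volume bias, lung-volume offsets — default to zero so that recovery
tests are non-circular; systematic effects are injected explicitly per
experiment.  Offsets are defined as TRUE minus PREDICTED volume: a
negative TLC offset means participants hold less air than the reference
equation predicts, which lowers the TLC-condition fat estimate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .anthropometry import HEAD_VOLUME_COEF
from .densitometry import GI_GAS_L, Condition, density_from_pbf, water_density
from .lung_volumes import predict_rv, predict_tlc
from .participants import Sex


@dataclass(frozen=True)
class SexProfile:
    """Marginal moments for one sex (defaults mirror the study cohort)."""

    n: int
    height_mean_cm: float
    height_sd_cm: float
    mass_mean_kg: float
    mass_sd_kg: float
    hg_mean_cm: float
    hg_sd_cm: float
    fg_mean_cm: float
    fg_sd_cm: float
    age_mean_yr: float
    age_sd_yr: float
    age_min_yr: float
    age_max_yr: float
    pbf_mean: float
    pbf_sd: float


MALE_PROFILE = SexProfile(
    n=64,
    height_mean_cm=182.1, height_sd_cm=7.9,
    mass_mean_kg=90.6, mass_sd_kg=14.7,
    hg_mean_cm=58.3, hg_sd_cm=1.6,
    fg_mean_cm=67.7, fg_sd_cm=2.1,
    age_mean_yr=25.3, age_sd_yr=10.7, age_min_yr=18.0, age_max_yr=70.0,
    pbf_mean=18.0, pbf_sd=6.0,
)

FEMALE_PROFILE = SexProfile(
    n=58,
    height_mean_cm=168.7, height_sd_cm=6.2,
    mass_mean_kg=68.5, mass_sd_kg=12.1,
    hg_mean_cm=56.2, hg_sd_cm=1.6,
    fg_mean_cm=63.0, fg_sd_cm=2.1,
    age_mean_yr=22.9, age_sd_yr=8.4, age_min_yr=18.0, age_max_yr=65.0,
    pbf_mean=28.0, pbf_sd=7.0,
)

#: true percent body fat is truncated to this physiological band
PBF_BOUNDS = (3.0, 50.0)


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs, with study-condition defaults."""

    male: SexProfile = MALE_PROFILE
    female: SexProfile = FEMALE_PROFILE
    seed: int = 0
    water_temp_c: float = 32.5
    trial_noise_kg: float = 0.030
    girth_noise_mm: float = 2.0
    hv_bias_l: float = 0.0      # true head volume minus its girth prediction
    hv_sd_l: float = 0.0        # individual scatter of true HV around prediction+bias
    tlc_offset_l: float = 0.0   # true minus predicted TLC
    rv_offset_l: float = 0.0    # true minus predicted RV
    n_trials_tlc: int = 5
    n_trials_rv: int = 4
    emit_streams: bool = False
    stream_length: int = 150
    sample_noise_kg: float = 0.010

    def __post_init__(self):
        for name in ("trial_noise_kg", "girth_noise_mm", "hv_sd_l", "sample_noise_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.n_trials_tlc <= 7):
            raise ValueError("n_trials_tlc must be in 1..7")
        if not (0 < self.n_trials_rv <= 5):
            raise ValueError("n_trials_rv must be in 1..5")
        if self.male.n < 0 or self.female.n < 0:
            raise ValueError("sample sizes must be >= 0")

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _truncnorm(rng, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_sex(rng: np.random.Generator, sex: Sex, prof: SexProfile, start_id: int):
    n = prof.n
    height = _truncnorm(rng, prof.height_mean_cm, prof.height_sd_cm,
                        prof.height_mean_cm - 3.5 * prof.height_sd_cm,
                        prof.height_mean_cm + 3.5 * prof.height_sd_cm, n)
    mass = _truncnorm(rng, prof.mass_mean_kg, prof.mass_sd_kg,
                      max(40.0, prof.mass_mean_kg - 3.5 * prof.mass_sd_kg),
                      prof.mass_mean_kg + 3.5 * prof.mass_sd_kg, n)
    age = _truncnorm(rng, prof.age_mean_yr, prof.age_sd_yr, prof.age_min_yr, prof.age_max_yr, n)
    # girth truths live on the instrument's mm grid so that noiseless
    # measurements reproduce them exactly
    hg_mm = np.round(_truncnorm(rng, prof.hg_mean_cm * 10, prof.hg_sd_cm * 10,
                                (prof.hg_mean_cm - 3.5 * prof.hg_sd_cm) * 10,
                                (prof.hg_mean_cm + 3.5 * prof.hg_sd_cm) * 10, n))
    fg_mm = np.round(_truncnorm(rng, prof.fg_mean_cm * 10, prof.fg_sd_cm * 10,
                                (prof.fg_mean_cm - 3.5 * prof.fg_sd_cm) * 10,
                                (prof.fg_mean_cm + 3.5 * prof.fg_sd_cm) * 10, n))
    pbf = _truncnorm(rng, prof.pbf_mean, prof.pbf_sd, PBF_BOUNDS[0], PBF_BOUNDS[1], n)
    ids = [f"{'M' if sex is Sex.MALE else 'F'}{start_id + i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex.value,
            "age_yr": age,
            "height_cm": height,
            "mass_kg": mass,
            "true_hg_mm": hg_mm,
            "true_fg_mm": fg_mm,
            "true_pbf": pbf,
        }
    )


def generate_cohort(config: CohortConfig = CohortConfig(),
                    seed: Optional[int] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort with latent truth.

    Returns ``(participants, truth)``: demographics ready for the pipeline,
    and per-participant true density, fat, head volume, lung volumes and
    body volume.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = [
        _draw_sex(rng, Sex.MALE, config.male, 1),
        _draw_sex(rng, Sex.FEMALE, config.female, 1),
    ]
    raw = pd.concat(frames, ignore_index=True)

    participants = raw[["participant_id", "sex", "age_yr", "height_cm", "mass_kg"]].copy()
    participants["water_temp_c"] = config.water_temp_c

    db = np.array([density_from_pbf(p) for p in raw["true_pbf"]])
    body_volume = raw["mass_kg"].to_numpy() / db
    hv_pred, tlc_pred, rv_pred = [], [], []
    for _, r in raw.iterrows():
        sex = Sex(r["sex"])
        b_hg, b_fg, b_ma, b0 = HEAD_VOLUME_COEF[sex]
        hv_pred.append(b_hg * r["true_hg_mm"] / 10 + b_fg * r["true_fg_mm"] / 10
                       + b_ma * r["mass_kg"] + b0)
        tlc_pred.append(predict_tlc(sex, r["height_cm"] / 100))
        rv_pred.append(predict_rv(sex, r["height_cm"] / 100, r["age_yr"]))
    n = len(raw)
    hv_true = np.array(hv_pred) + config.hv_bias_l + (
        rng.normal(0.0, config.hv_sd_l, n) if config.hv_sd_l > 0 else 0.0
    )

    truth = pd.DataFrame(
        {
            "participant_id": raw["participant_id"],
            "sex": raw["sex"],
            "true_pbf": raw["true_pbf"],
            "true_db": db,
            "body_volume_l": body_volume,
            "true_hv_l": hv_true,
            "true_tlc_l": np.array(tlc_pred) + config.tlc_offset_l,
            "true_rv_l": np.array(rv_pred) + config.rv_offset_l,
            "true_hg_mm": raw["true_hg_mm"],
            "true_fg_mm": raw["true_fg_mm"],
        }
    )
    return participants, truth


def _simulate_girth_series(rng, true_mm: float, noise_mm: float, tolerance_mm: float = 5.0):
    """Emulate the two-technician protocol: 2 readings, a 3rd on >5 mm
    disagreement, a 4th if still no agreeing pair."""
    def reading():
        return float(np.round(true_mm + (rng.normal(0.0, noise_mm) if noise_mm > 0 else 0.0)))

    m = [reading(), reading()]
    if abs(m[0] - m[1]) > tolerance_mm:
        m.append(reading())
        if not any(abs(m[i] - m[j]) <= tolerance_mm for i in range(3) for j in range(i + 1, 3)):
            m.append(reading())
    return m


def simulate_weighing(
    truth_row: pd.Series,
    mass_kg: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> Dict[Condition, List[float]]:
    """Forward-simulate per-trial in-water masses for one participant.

    Archimedes run forwards: the submerged volume is the body volume plus
    lung gas plus GI gas, minus the true head volume when the head stays
    above water, so

        MW = MA - DW * V_submerged

    plus iid trial noise.  Negative in-water masses (buoyant participants)
    are passed through.
    """
    dw = water_density(config.water_temp_c)
    vb = float(truth_row["body_volume_l"])
    hv = float(truth_row["true_hv_l"])
    tlc = float(truth_row["true_tlc_l"])
    rv = float(truth_row["true_rv_l"])
    submerged = {
        Condition.HAW_TLC: vb - hv + tlc + GI_GAS_L,
        Condition.HBW_TLC: vb + tlc + GI_GAS_L,
        Condition.HBW_RV: vb + rv + GI_GAS_L,
    }
    out: Dict[Condition, List[float]] = {}
    for cond, vol in submerged.items():
        n_tr = config.n_trials_rv if cond is Condition.HBW_RV else config.n_trials_tlc
        mw = mass_kg - dw * vol
        noise = rng.normal(0.0, config.trial_noise_kg, n_tr) if config.trial_noise_kg > 0 else np.zeros(n_tr)
        out[cond] = [float(mw + e) for e in noise]
    return out


def simulate_streams(
    trial_weights: Dict[Condition, List[float]],
    config: CohortConfig,
    rng: np.random.Generator,
) -> Dict[Condition, List[np.ndarray]]:
    """Optional raw load-cell streams whose steadiest window mean is the trial weight."""
    out: Dict[Condition, List[np.ndarray]] = {}
    for cond, weights in trial_weights.items():
        streams = []
        for w in weights:
            s = w + (rng.normal(0.0, config.sample_noise_kg, config.stream_length)
                     if config.sample_noise_kg > 0 else np.zeros(config.stream_length))
            streams.append(s)
        out[cond] = streams
    return out


def simulate_cohort_measurements(
    participants: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate girth series and weighing trials for a whole cohort.

    Returns long-format ``girths`` (participant_id, site, trial_index,
    value_mm) and ``trials`` (participant_id, condition, trial_index,
    weight_kg) tables matching the pipeline's CSV schemas.
    """
    girth_rows, trial_rows = [], []
    tmap = truth.set_index("participant_id")
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        t = tmap.loc[pid]
        for site, col in (("HG", "true_hg_mm"), ("FG", "true_fg_mm")):
            series = _simulate_girth_series(rng, float(t[col]), config.girth_noise_mm)
            for k, v in enumerate(series, start=1):
                girth_rows.append({"participant_id": pid, "site": site,
                                   "trial_index": k, "value_mm": v})
        weights = simulate_weighing(t, float(p["mass_kg"]), config, rng)
        for cond, ws in weights.items():
            for k, w in enumerate(ws, start=1):
                trial_rows.append({"participant_id": pid, "condition": cond.value,
                                   "trial_index": k, "weight_kg": w})
    girth_cols = ["participant_id", "site", "trial_index", "value_mm"]
    trial_cols = ["participant_id", "condition", "trial_index", "weight_kg"]
    return (
        pd.DataFrame(girth_rows, columns=girth_cols),
        pd.DataFrame(trial_rows, columns=trial_cols),
    )


def make_study_fixture(
    out_dir, config: CohortConfig = CohortConfig(), seed: Optional[int] = None
) -> Dict[str, Path]:
    """Write a complete runnable fixture bundle (CSVs + config YAML).

    Files: participants.csv, girths.csv, trials.csv, truth.csv, config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([use_seed, 1]))
    participants, truth = generate_cohort(config, seed=use_seed)
    girths, trials = simulate_cohort_measurements(participants, truth, config, rng)

    paths = {}
    for name, df in (
        ("participants", participants),
        ("girths", girths),
        ("trials", trials),
        ("truth", truth),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    cfg = asdict(config)
    cfg["seed"] = use_seed
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths["config"] = cfg_path
    return paths
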