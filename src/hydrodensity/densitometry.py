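"""Body density and percent body fat from in-water weighings.

Archimedes' principle turns the difference between dry mass (MA) and
in-water mass (MW) into body volume: the water displaced by the submerged
body weighs MA - MW, so the submerged volume is (MA - MW) / DW with DW the
water density at tank temperature.  Subtracting the gas in the lungs (TLC
or RV depending on the trial) and a 0.1 L gastrointestinal-gas allowance
gives tissue volume; for head-above-water trials the out-of-water head
volume (predicted from girths) is added back.  Density Db = MA / volume,
and percent body fat follows from the Brozek two-compartment transform

    PBF = (4.570 / Db - 4.142) * 100.

Trial handling mirrors the weighing protocol: each trial's raw load-cell
stream is summarised by the most stable window of 100 +/- 2 samples, at
most 7 trials are taken per head-position condition at TLC and 5 at RV,
and the condition's weight is the mean of the three (failing that, two)
trials that agree within 100 g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .anthropometry import (
    GIRTH_TOLERANCE_MM,
    GirthQC,
    GirthSeries,
    Site,
    predict_head_volume,
    qc_girth,
)
from .lung_volumes import predict_rv, predict_tlc
from .participants import Participant

#: gastrointestinal gas allowance subtracted in every density equation, litres
GI_GAS_L = 0.1

#: Brozek transform constants: PBF = (BROZEK_A / Db - BROZEK_B) * 100
BROZEK_A = 4.570
BROZEK_B = 4.142


class Condition(str, Enum):
    """Weighing condition: head position at a given lung volume."""

    HAW_TLC = "HAW_TLC"  # head above water, total lung capacity
    HBW_TLC = "HBW_TLC"  # head below water, total lung capacity
    HBW_RV = "HBW_RV"    # head below water, residual volume (gold standard)

    @property
    def uses_head_volume(self) -> bool:
        return self is Condition.HAW_TLC

    @property
    def lung_volume_is_tlc(self) -> bool:
        return self in (Condition.HAW_TLC, Condition.HBW_TLC)


#: protocol caps on the number of weighing trials per condition
TRIAL_CAPS: Dict[Condition, int] = {
    Condition.HAW_TLC: 7,
    Condition.HBW_TLC: 7,
    Condition.HBW_RV: 5,
}


class TrialQuality(str, Enum):
    TRIPLE = "triple"  # three trials within tolerance
    PAIR = "pair"      # only two trials within tolerance
    NONE = "none"      # no consistent subset


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol constants, defaulting to the printed weighing protocol.

    ``belt_correction`` subtracts the net in-water weight of the 2.1 kg
    belt, ``belt_mass_kg * (1 - dw / belt_density_kg_l)``, from TLC-condition
    readings for acquisition systems that do not tare the belt; default off
    (the scale is assumed tared).
    """

    girth_tolerance_mm: float = GIRTH_TOLERANCE_MM
    trial_tolerance_kg: float = 0.100
    sample_target: int = 100
    sample_slack: int = 2
    max_trials_tlc: int = 7
    max_trials_rv: int = 5
    water_temp_c: float = 32.5
    gi_gas_l: float = GI_GAS_L
    include_pairs: bool = True
    belt_correction: bool = False
    belt_mass_kg: float = 2.1
    belt_density_kg_l: float = 7.8  # steel shot

    def __post_init__(self):
        if self.girth_tolerance_mm <= 0 or self.trial_tolerance_kg <= 0:
            raise ValueError("tolerances must be > 0")
        if self.sample_slack < 0 or self.sample_target <= 0:
            raise ValueError("sample window parameters must be positive")
        if self.max_trials_tlc > TRIAL_CAPS[Condition.HBW_TLC]:
            warnings.warn("max_trials_tlc above the protocol cap of 7", stacklevel=2)
        if self.max_trials_rv > TRIAL_CAPS[Condition.HBW_RV]:
            warnings.warn("max_trials_rv above the protocol cap of 5", stacklevel=2)

    def cap_for(self, condition: Condition) -> int:
        return self.max_trials_rv if condition is Condition.HBW_RV else self.max_trials_tlc


def water_density(temp_c: float) -> float:
    """Density of pure water in kg/L at ``temp_c`` degrees Celsius.

    Kell's (1975) rational polynomial for air-free water at 1 atm, valid
    well beyond the 0-40 degC range enforced here; maximal near 4 degC and
    monotonically decreasing above it.
    """
    t = float(temp_c)
    if not (0.0 < t < 40.0):
        raise ValueError(f"water temperature {t} degC outside the supported range (0, 40)")
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.879850e-3 * t) / 1000.0


@dataclass(frozen=True)
class WindowSelection:
    """Chosen load-cell sample window and its mean weight."""

    mean_kg: float
    start: int
    length: int


def select_sample_window(
    samples: Sequence[float], target_n: int = 100, slack: int = 2
) -> WindowSelection:
    """Pick the steadiest contiguous window of ``target_n +/- slack`` samples.

    Among all contiguous windows whose length lies in
    ``[target_n - slack, target_n + slack]``, returns the one with the
    smallest within-window standard deviation — the stretch that best
    represents the mean weight.  Ties prefer the longer window, then the
    earlier start.  The window's mean is the trial weight.
    """
    x = np.asarray(samples, dtype=float)
    min_len = target_n - slack
    if x.ndim != 1 or x.size < min_len:
        raise ValueError(f"stream of {x.size} samples is shorter than the minimum window {min_len}")
    best: Optional[Tuple[float, int, int]] = None  # (sd, start, length)
    max_len = min(target_n + slack, x.size)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    for length in range(max_len, min_len - 1, -1):
        s = csum[length:] - csum[:-length]
        s2 = csum2[length:] - csum2[:-length]
        var = np.maximum(s2 / length - (s / length) ** 2, 0.0)
        start = int(np.argmin(var))  # argmin takes the earliest on ties
        sd = float(np.sqrt(var[start]))
        if best is None or sd < best[0]:
            best = (sd, start, length)
    _, start, length = best
    mean = float(np.mean(x[start : start + length]))
    return WindowSelection(mean_kg=mean, start=start, length=length)


@dataclass(frozen=True)
class TrialSelection:
    """Outcome of the within-100 g consistency rule for one condition."""

    indices: Tuple[int, ...]
    mean_kg: Optional[float]
    quality: TrialQuality


def select_consistent_trials(
    weights: Sequence[float], tolerance_kg: float = 0.100
) -> TrialSelection:
    """Average the tightest subset of trial weights agreeing within tolerance.

    All 3-subsets are enumerated; among those whose range (max - min) is
    within ``tolerance_kg`` the subset with the smallest range wins (ties
    broken by the lexicographically earliest index triple).  If no triple
    qualifies the same search runs over 2-subsets (quality ``pair``); if no
    pair qualifies either, the condition yields no weight (quality ``none``).
    """
    w = [float(x) for x in weights]
    if len(w) == 0:
        raise ValueError("no trial weights supplied")
    if tolerance_kg <= 0:
        raise ValueError("tolerance_kg must be > 0")
    for size, quality in ((3, TrialQuality.TRIPLE), (2, TrialQuality.PAIR)):
        if len(w) < size:
            continue
        best: Optional[Tuple[int, ...]] = None
        best_range = float("inf")
        for idx in combinations(range(len(w)), size):
            vals = [w[i] for i in idx]
            r = max(vals) - min(vals)
            if r <= tolerance_kg and r < best_range:
                best, best_range = idx, r
        if best is not None:
            mean = sum(w[i] for i in best) / size
            return TrialSelection(indices=best, mean_kg=mean, quality=quality)
    return TrialSelection(indices=(), mean_kg=None, quality=TrialQuality.NONE)


@dataclass(frozen=True)
class TrialSeries:
    """Per-condition ordered in-water weights with their selection outcome."""

    condition: Condition
    weights: Tuple[float, ...]
    selection: TrialSelection

    def __post_init__(self):
        cap = TRIAL_CAPS[self.condition]
        if len(self.weights) > cap:
            raise ValueError(
                f"{self.condition.value}: {len(self.weights)} trials exceeds the protocol cap of {cap}"
            )


class DensityComputationError(ValueError):
    """Raised when the displaced-volume budget is non-physical."""


def body_density(
    condition: Condition,
    ma_kg: float,
    mw_kg: float,
    dw_kg_l: float,
    lung_volume_l: float,
    hv_pred_l: Optional[float] = None,
    gi_gas_l: float = GI_GAS_L,
) -> float:
    """Whole-body density (kg/L) by Archimedes inversion for one condition.

    Head below water::

        Db = MA / ((MA - MW) / DW - V_lung - 0.1)

    Head above water (the un-submerged head volume is added back)::

        Db = MA / ((MA - MW) / DW + HV_pred - V_lung - 0.1)

    ``hv_pred_l`` is required for the head-above-water condition and must be
    absent otherwise.
    """
    condition = Condition(condition)
    if ma_kg <= 0:
        raise ValueError("dry mass must be > 0")
    if mw_kg >= ma_kg:
        raise ValueError(f"in-water mass {mw_kg} kg must be below dry mass {ma_kg} kg")
    if dw_kg_l <= 0:
        raise ValueError("water density must be > 0")
    if lung_volume_l <= 0:
        raise ValueError("lung volume must be > 0")
    if condition.uses_head_volume:
        if hv_pred_l is None:
            raise ValueError(f"{condition.value} requires a predicted head volume")
    elif hv_pred_l is not None:
        raise ValueError(f"{condition.value} must not be given a head volume")

    displaced = (ma_kg - mw_kg) / dw_kg_l
    volume = displaced - lung_volume_l - gi_gas_l
    if condition.uses_head_volume:
        volume += hv_pred_l
    if volume <= 0:
        raise DensityComputationError(
            f"{condition.value}: non-positive tissue volume {volume:.4f} L "
            f"(displaced {displaced:.4f} L, lung {lung_volume_l:.4f} L, "
            f"GI gas {gi_gas_l:.4f} L"
            + (f", head {hv_pred_l:.4f} L)" if hv_pred_l is not None else ")")
        )
    return ma_kg / volume


def percent_body_fat(db_kg_l: float) -> float:
    """Percent body fat from body density via the Brozek transform."""
    if db_kg_l <= 0:
        raise ValueError("body density must be > 0")
    return (BROZEK_A / db_kg_l - BROZEK_B) * 100.0


def density_from_pbf(pbf_pct: float) -> float:
    """Exact inverse of :func:`percent_body_fat`."""
    return BROZEK_A / (pbf_pct / 100.0 + BROZEK_B)


@dataclass(frozen=True)
class BodyComposition:
    """Condition-specific density and fat estimate with all intermediates."""

    participant_id: str
    condition: Condition
    db_kg_l: float
    pbf_pct: float
    dw_kg_l: float
    lung_volume_l: float
    hv_pred_l: Optional[float]
    gi_gas_l: float
    mw_kg: float
    n_trials: int
    quality: TrialQuality
    selected_indices: Tuple[int, ...] = field(default=())


class ParticipantComputationError(ValueError):
    """A stage failure wrapped with participant context."""


def compute_participant(
    participant: Participant,
    girths: Mapping[Site, Sequence[float]],
    trials: Mapping[Condition, Sequence[float]],
    config: ProtocolConfig = ProtocolConfig(),
) -> List[BodyComposition]:
    """Run the full densitometric chain for one participant.

    Girth series (mm) are QC-averaged and fed to the head-volume
    prediction; lung volumes come from the height/age reference equations;
    each condition's trial weights go through the 100 g consistency rule
    and then the Archimedes inversion.  Conditions whose trials yield no
    consistent subset (quality ``none``) are omitted; ``pair``-quality
    conditions are omitted too when ``config.include_pairs`` is false.

    Returns one :class:`BodyComposition` per retained condition (possibly
    an empty list).  Girth series are only required when a head-above-water
    condition is present.
    """
    pid = participant.participant_id
    try:
        temp = participant.water_temp_c if participant.water_temp_c is not None else config.water_temp_c
        dw = water_density(temp)

        conditions = {Condition(c): list(w) for c, w in trials.items()}
        hv_pred: Optional[float] = None
        if any(c.uses_head_volume for c in conditions):
            qcs: Dict[Site, GirthSeries] = {}
            for site in (Site.HG, Site.FG):
                if site not in girths:
                    raise ValueError(f"missing {site.value} girth series (needed for head-above-water)")
                qcs[site] = qc_girth(girths[site], site=site, tolerance_mm=config.girth_tolerance_mm)
                if qcs[site].status is not GirthQC.OK:
                    raise ValueError(f"{site.value} girth QC {qcs[site].status.value}")
            hv_pred = predict_head_volume(
                participant.sex,
                hg_cm=qcs[Site.HG].qc_value_cm,
                fg_cm=qcs[Site.FG].qc_value_cm,
                ma_kg=participant.mass_kg,
            ).hv_pred_l

        tlc = predict_tlc(participant.sex, participant.height_m)
        rv = predict_rv(participant.sex, participant.height_m, participant.age_yr)

        results: List[BodyComposition] = []
        for condition, weights in conditions.items():
            cap = config.cap_for(condition)
            if len(weights) > cap:
                raise ValueError(
                    f"{condition.value}: {len(weights)} trials exceeds the cap of {cap}"
                )
            sel = select_consistent_trials(weights, tolerance_kg=config.trial_tolerance_kg)
            if sel.quality is TrialQuality.NONE:
                continue
            if sel.quality is TrialQuality.PAIR and not config.include_pairs:
                continue
            mw = sel.mean_kg
            if config.belt_correction and condition.lung_volume_is_tlc:
                mw -= config.belt_mass_kg * (1.0 - dw / config.belt_density_kg_l)
            lung = tlc if condition.lung_volume_is_tlc else rv
            db = body_density(
                condition,
                ma_kg=participant.mass_kg,
                mw_kg=mw,
                dw_kg_l=dw,
                lung_volume_l=lung,
                hv_pred_l=hv_pred if condition.uses_head_volume else None,
                gi_gas_l=config.gi_gas_l,
            )
            results.append(
                BodyComposition(
                    participant_id=pid,
                    condition=condition,
                    db_kg_l=db,
                    pbf_pct=percent_body_fat(db),
                    dw_kg_l=dw,
                    lung_volume_l=lung,
                    hv_pred_l=hv_pred if condition.uses_head_volume else None,
                    gi_gas_l=config.gi_gas_l,
                    mw_kg=mw,
                    n_trials=len(weights),
                    quality=sel.quality,
                    selected_indices=sel.indices,
                )
            )
        return results
    except ParticipantComputationError:
        raise
    except ValueError as exc:
        raise ParticipantComputationError(f"participant {pid}: {exc}") from exc
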