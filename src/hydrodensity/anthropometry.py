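"""Head/face girth quality control and predicted head volume.

Two technicians each take one circumference measurement (head girth HG or
face girth FG) to the nearest millimetre.  If the two disagree by more than
5 mm a third measurement is taken, and on the rare occasion no two agree a
fourth; the average of the closest agreeing pair is used.  The QC'd girths
feed a sex-specific linear head-volume prediction (litres), which stands in
for head submersion when weighing with the head above water.

Girths are carried in millimetres (the measurement resolution) and
converted to centimetres only at equation entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Optional, Sequence, Tuple

from .participants import Sex, as_sex

#: default technician-agreement tolerance, millimetres
GIRTH_TOLERANCE_MM = 5.0

#: protocol cap on repeated girth measurements per site
MAX_GIRTH_MEASUREMENTS = 4

#: sex-specific head-volume coefficients: (HG cm, FG cm, MA kg, intercept) -> litres
HEAD_VOLUME_COEF = {
    Sex.MALE: (0.1294, 0.0299, 0.0055, -5.7506),
    Sex.FEMALE: (0.1314, 0.0504, 0.0094, -7.3181),
}


class Site(str, Enum):
    HG = "HG"  # head girth: maximal horizontal circumference of the head
    FG = "FG"  # face girth: under the chin over the vertex


class GirthQC(str, Enum):
    OK = "ok"
    NEEDS_MORE = "needs_more"  # no pair within tolerance yet, <4 measurements
    FAILED = "failed"          # 4 measurements, no pair within tolerance


@dataclass(frozen=True)
class GirthSeries:
    """Ordered repeated girth measurements for one site with the QC outcome."""

    site: Site
    measurements: Tuple[float, ...]   # mm, acquisition order
    status: GirthQC
    qc_pair: Optional[Tuple[int, int]] = None
    qc_value_mm: Optional[float] = None

    @property
    def qc_value_cm(self) -> Optional[float]:
        return None if self.qc_value_mm is None else self.qc_value_mm / 10.0


def qc_girth(
    measurements: Sequence[float],
    site: Site = Site.HG,
    tolerance_mm: float = GIRTH_TOLERANCE_MM,
) -> GirthSeries:
    """Select and average the closest agreeing pair of girth measurements.

    Among all pairs, the pair with the smallest absolute difference that is
    within ``tolerance_mm`` is averaged (ties broken by acquisition order,
    i.e. the earliest pair).  With fewer than four measurements and no
    qualifying pair the series is flagged ``NEEDS_MORE``; with four and no
    qualifying pair it is a QC failure.

    Parameters
    ----------
    measurements : sequence of float
        2-4 circumference readings in millimetres, acquisition order.
    site : Site
        Which girth this series measures (carried through to the result).
    tolerance_mm : float
        Maximum technician disagreement for a pair to qualify.
    """
    m = tuple(float(x) for x in measurements)
    if len(m) < 2:
        raise ValueError(f"{site.value}: need at least 2 girth measurements, got {len(m)}")
    if len(m) > MAX_GIRTH_MEASUREMENTS:
        raise ValueError(f"{site.value}: at most {MAX_GIRTH_MEASUREMENTS} girth measurements, got {len(m)}")
    if any(x <= 0 for x in m):
        raise ValueError(f"{site.value}: girth measurements must be positive, got {m}")
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be > 0")

    best: Optional[Tuple[int, int]] = None
    best_diff = float("inf")
    for i, j in combinations(range(len(m)), 2):
        d = abs(m[i] - m[j])
        if d <= tolerance_mm and d < best_diff:
            best, best_diff = (i, j), d
    if best is None:
        status = GirthQC.FAILED if len(m) == MAX_GIRTH_MEASUREMENTS else GirthQC.NEEDS_MORE
        return GirthSeries(site=site, measurements=m, status=status)
    i, j = best
    return GirthSeries(
        site=site,
        measurements=m,
        status=GirthQC.OK,
        qc_pair=best,
        qc_value_mm=(m[i] + m[j]) / 2.0,
    )


@dataclass(frozen=True)
class HeadVolume:
    """Predicted head volume with the inputs that produced it."""

    hv_pred_l: float
    hg_cm: float
    fg_cm: float
    ma_kg: float
    sex: Sex


def predict_head_volume(sex, hg_cm: float, fg_cm: float, ma_kg: float) -> HeadVolume:
    """Predict head volume (litres) from head girth, face girth and dry mass.

    The prediction is a sex-specific linear combination of head girth (cm),
    face girth (cm) and dry body mass in air (kg).  Typical adult head
    volumes are 2-7 L; values outside that band trigger a warning but are
    returned.
    """
    sex = as_sex(sex)
    if hg_cm <= 0 or fg_cm <= 0 or ma_kg <= 0:
        raise ValueError(
            f"head-volume inputs must be positive: HG={hg_cm}, FG={fg_cm}, MA={ma_kg}"
        )
    b_hg, b_fg, b_ma, b0 = HEAD_VOLUME_COEF[sex]
    hv = b_hg * hg_cm + b_fg * fg_cm + b_ma * ma_kg + b0
    if not (2.0 <= hv <= 7.0):
        warnings.warn(
            f"predicted head volume {hv:.3f} L outside the typical adult range 2-7 L",
            stacklevel=2,
        )
    return HeadVolume(hv_pred_l=hv, hg_cm=hg_cm, fg_cm=fg_cm, ma_kg=ma_kg, sex=sex)
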