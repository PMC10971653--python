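"""Participant records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Sex(str, Enum):
    """Self-reported sex, the key for all sex-specific prediction equations."""

    MALE = "male"
    FEMALE = "female"


def as_sex(value) -> Sex:
    """Coerce a string or Sex into a Sex, with a clear error."""
    if isinstance(value, Sex):
        return value
    try:
        return Sex(str(value).strip().lower())
    except ValueError:
        raise ValueError(f"unknown sex {value!r}; expected 'male' or 'female'") from None


@dataclass(frozen=True)
class Participant:
    """Demographics plus dry mass; the anchor for every prediction.

    Attributes
    ----------
    participant_id : str
        Unique identifier, used in error context and output tables.
    sex : Sex
        Self-reported sex.
    age_yr : float
        Age in years (adults only, >= 18).
    height_cm : float
        Stature in centimetres (stadiometer convention).
    mass_kg : float
        Dry body mass in air (MA), kilograms.
    water_temp_c : float, optional
        Tank water temperature for this participant's session; falls back
        to the run-level default when absent.
    sgpals : int, optional
        Saltin-Grimby physical activity level (stored, not used).
    """

    participant_id: str
    sex: Sex
    age_yr: float
    height_cm: float
    mass_kg: float
    water_temp_c: Optional[float] = None
    sgpals: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", as_sex(self.sex))
        if self.mass_kg <= 0:
            raise ValueError(f"{self.participant_id}: mass_kg must be > 0")
        if self.height_cm <= 0:
            raise ValueError(f"{self.participant_id}: height_cm must be > 0")

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0
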