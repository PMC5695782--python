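"""MET computation from indirect calorimetry and reference intensity labels.

The criterion ("reference") classification of each one-minute gas sample
follows the four-rule scheme: the minute's MET value — activity VO2
divided by the participant's resting VO2 (REE), both in ml·kg⁻¹·min⁻¹ —
plus the observed posture decide the class:

=====  ==========================  ==========
rule   condition                   class
=====  ==========================  ==========
1      MET ≤ 1.5 and not upright   Sedentary
2      MET ≤ 1.5 and upright       Standing
3      1.5 < MET < 3               LIPA
4      MET ≥ 3                     MVPA
=====  ==========================  ==========

All six 10-s windows of a minute inherit the minute's label.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CalorimetrySample",
    "ParticipantBaseline",
    "ReferenceLabel",
    "compute_met",
    "classify_reference",
]


@dataclass(frozen=True)
class CalorimetrySample:
    """One one-minute expired-gas sample (STPD-corrected VO2)."""

    participant_id: str
    activity_code: int
    minute_id: int
    vo2: float  # ml·kg⁻¹·min⁻¹

    def __post_init__(self) -> None:
        if not self.vo2 > 0:
            raise ValueError(f"vo2 must be positive, got {self.vo2}")


@dataclass(frozen=True)
class ParticipantBaseline:
    """Participant characteristics used for MET normalisation and robustness."""

    participant_id: str
    age: float
    sex: str
    body_mass: float  # kg
    body_height: float  # m
    bmi: float  # kg·m⁻²
    prandial_state: str  # fasting | non-fasting
    ree: float  # resting VO2, ml·kg⁻¹·min⁻¹
    prosthetic_joints: bool = False
    cv_medication: bool = False
    fitness_level: str = ""
    preferred_walking_speed: float = float("nan")  # km·h⁻¹
    falls_risk: str = "low"

    def __post_init__(self) -> None:
        if self.age < 60:
            raise ValueError("study population is aged >= 60 years")
        if not self.ree > 0:
            raise ValueError("REE must be positive")
        if abs(self.bmi - self.body_mass / self.body_height**2) > 0.1:
            raise ValueError("BMI inconsistent with mass and height")


@dataclass(frozen=True)
class ReferenceLabel:
    minute_id: int
    met: float
    observed_posture: str  # upright | not_upright
    intensity_class: str


def compute_met(sample: CalorimetrySample, baseline: ParticipantBaseline) -> float:
    """MET of a one-minute activity sample: VO2 / participant REE."""
    if not baseline.ree > 0:
        raise ValueError("REE must be positive")
    return sample.vo2 / baseline.ree


def classify_reference(met: float, posture: str) -> str:
    """Reference intensity class from the minute MET and observed posture."""
    if not met > 0:
        raise ValueError(f"MET must be positive, got {met}")
    if posture not in ("upright", "not_upright"):
        raise ValueError(f"unknown posture {posture!r}")
    if met <= 1.5:
        return "Standing" if posture == "upright" else "Sedentary"
    if met < 3:
        return "LIPA"
    return "MVPA"


def label_minute(
    sample: CalorimetrySample, baseline: ParticipantBaseline, posture: str
) -> ReferenceLabel:
    """Compute MET and class for one gas-sampling minute."""
    met = compute_met(sample, baseline)
    return ReferenceLabel(
        minute_id=sample.minute_id,
        met=met,
        observed_posture=posture,
        intensity_class=classify_reference(met, posture),
    )
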