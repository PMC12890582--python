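"""Domain types for phonocardiogram screening cohorts.

A patient is characterised by an echocardiographic report (a grade for each
of the eight valve-lesion slots plus heart rhythm), demographics, and one or
more heart-sound recordings per auscultation site.  The binary screening
label -- *clinically significant* valvular heart disease -- is derived from
the echo report: at least mild stenosis or at least moderate regurgitation
in any valve.  Mild regurgitation alone does not qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "SeverityGrade",
    "Valve",
    "LesionKind",
    "Lesion",
    "Site",
    "Rhythm",
    "Sex",
    "AgeBand",
    "Setting",
    "EchoReport",
    "Recording",
    "PatientRecord",
    "classify_significance",
    "dominant_lesion",
    "STENOSIS_SLOTS",
    "REGURGITATION_SLOTS",
]


class SeverityGrade(IntEnum):
    """Echocardiographic lesion severity on the standard four-level ordinal scale."""

    NONE_TRACE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class Valve(str, Enum):
    AORTIC = "aortic"
    PULMONARY = "pulmonary"
    TRICUSPID = "tricuspid"
    MITRAL = "mitral"


class LesionKind(str, Enum):
    STENOSIS = "stenosis"
    REGURGITATION = "regurgitation"


class Lesion(str, Enum):
    """The eight valve-lesion slots: {A,M,P,T} x {stenosis, regurgitation}."""

    AS = "AS"
    AR = "AR"
    MS = "MS"
    MR = "MR"
    PS = "PS"
    PR = "PR"
    TS = "TS"
    TR = "TR"

    @property
    def valve(self) -> Valve:
        return {
            "A": Valve.AORTIC,
            "M": Valve.MITRAL,
            "P": Valve.PULMONARY,
            "T": Valve.TRICUSPID,
        }[self.value[0]]

    @property
    def kind(self) -> LesionKind:
        return LesionKind.STENOSIS if self.value[1] == "S" else LesionKind.REGURGITATION


STENOSIS_SLOTS = (Lesion.AS, Lesion.MS, Lesion.PS, Lesion.TS)
REGURGITATION_SLOTS = (Lesion.AR, Lesion.MR, Lesion.PR, Lesion.TR)


class Site(str, Enum):
    """Standard auscultation locations."""

    A = "A"  # aortic: right 2nd intercostal space
    P = "P"  # pulmonary: left 2nd intercostal space
    T = "T"  # tricuspid: left lower sternal border
    M = "M"  # mitral: apex


class Rhythm(str, Enum):
    SINUS = "sinus"
    ATRIAL_FIBRILLATION = "atrial_fibrillation"
    PACED = "paced"
    OTHER = "other"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class AgeBand(str, Enum):
    UNDER_45 = "<45"
    FROM_45_TO_65 = "45-65"
    FROM_65_TO_80 = "65-80"
    OVER_80 = "80+"


class Setting(str, Enum):
    ACUTE_HOSPITAL = "acute_hospital"
    PRIMARY_CARE = "primary_care"


@dataclass(frozen=True)
class EchoReport:
    """Echocardiographic grading grid: one severity grade per lesion slot, plus rhythm."""

    grades: dict[Lesion, SeverityGrade]
    rhythm: Rhythm = Rhythm.SINUS

    def __post_init__(self) -> None:
        missing = [s for s in Lesion if s not in self.grades]
        if missing:
            raise ValueError(f"echo report missing lesion slots: {missing}")
        extra = [s for s in self.grades if not isinstance(s, Lesion)]
        if extra:
            raise ValueError(f"unknown lesion slots: {extra}")

    def grade(self, lesion: Lesion) -> SeverityGrade:
        return self.grades[lesion]

    @staticmethod
    def from_grades(rhythm: Rhythm = Rhythm.SINUS, **grades: SeverityGrade | int) -> "EchoReport":
        """Build a report from keyword grades (e.g. ``AS=SeverityGrade.SEVERE``);
        unspecified slots default to none/trace."""
        full = {s: SeverityGrade.NONE_TRACE for s in Lesion}
        for name, g in grades.items():
            full[Lesion(name)] = SeverityGrade(g)
        return EchoReport(grades=full, rhythm=rhythm)


def classify_significance(echo: EchoReport) -> bool:
    """Primary screening outcome: clinically significant VHD.

    True iff any valve shows at least mild stenosis or at least moderate
    regurgitation.  Mild regurgitation alone is expected in a large part of
    an elderly population and does not warrant referral.
    """
    for slot in STENOSIS_SLOTS:
        if echo.grades[slot] >= SeverityGrade.MILD:
            return True
    for slot in REGURGITATION_SLOTS:
        if echo.grades[slot] >= SeverityGrade.MODERATE:
            return True
    return False


def _qualifies(lesion: Lesion, grade: SeverityGrade) -> bool:
    """Does this single lesion at this grade meet the significance rule on its own?"""
    if lesion.kind is LesionKind.STENOSIS:
        return grade >= SeverityGrade.MILD
    return grade >= SeverityGrade.MODERATE


def significant_lesions(echo: EchoReport) -> list[Lesion]:
    """Lesion slots whose grade individually meets the significance rule."""
    return [s for s in Lesion if _qualifies(s, echo.grades[s])]


def dominant_lesion(echo: EchoReport) -> tuple[str, SeverityGrade]:
    """Most severe lesion slot and its grade (used as allocation factors).

    Ties on grade are broken by a fixed slot order (stenoses first).  Returns
    ``("none", NONE_TRACE)`` when no slot qualifies as significant.
    """
    sig = significant_lesions(echo)
    if not sig:
        return "none", SeverityGrade.NONE_TRACE
    order = list(STENOSIS_SLOTS) + list(REGURGITATION_SLOTS)
    best = max(sig, key=lambda s: (echo.grades[s], -order.index(s)))
    return best.value, echo.grades[best]


@dataclass
class Recording:
    """A single-channel heart-sound recording at one auscultation site."""

    site: Site
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("recording must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.duration > 15.0 + 1e-9:
            raise ValueError("recordings are capped at 15 s")
        if self.samples.size and self.samples.size < 0.5 * self.fs:
            raise ValueError("recordings shorter than 0.5 s are rejected")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class PatientRecord:
    """The unit of allocation, training and evaluation."""

    id: str
    sex: Sex
    age_band: AgeBand
    setting: Setting
    echo: EchoReport
    recordings: dict[Site, list[Recording]] = field(default_factory=dict)
    murmur_truth: dict[Site, bool] = field(default_factory=dict)
    heart_rate: float | None = None
    stethoscope: int = 0

    @property
    def significant(self) -> bool:
        return classify_significance(self.echo)

    def sites_with_audio(self) -> list[Site]:
        return [s for s in Site if self.recordings.get(s)]
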