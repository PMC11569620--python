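"""Record types shared across the cohort generator and the analysis stages.

One pregnancy contributes five streams: a baseline participant record,
timestamped mood reports (1-5 Likert), symptom reports in four severity
classes, free-text entries, and EPDS administrations (total 0-30 plus a
suicidal-ideation indicator from item 10). Days are integer offsets from
enrollment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

RACE_LEVELS = ("white", "Black", "Hispanic/Latinx", "Asian", "other")
SEVERITY_CLASSES = ("critical", "significant", "common", "open_ended")
TEXT_SOURCES = ("journal", "prompt", "covid_screener", "other_symptom")


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    age_years: int
    race_ethnicity: str
    income_low: bool
    education_low: bool
    history_depression: bool
    history_anxiety: bool
    parity: int

    def __post_init__(self) -> None:
        if self.age_years < 14:
            raise ValueError(f"age_years must be >= 14, got {self.age_years}")
        if self.race_ethnicity not in RACE_LEVELS:
            raise ValueError(f"unknown race/ethnicity {self.race_ethnicity!r}")
        if self.parity < 0:
            raise ValueError("parity must be nonnegative")


@dataclass(frozen=True)
class MoodReport:
    participant_id: str
    day: int
    mood: int

    def __post_init__(self) -> None:
        if not 1 <= self.mood <= 5:
            raise ValueError(f"mood must be in 1..5, got {self.mood}")


@dataclass(frozen=True)
class SymptomReport:
    participant_id: str
    day: int
    severity_class: str
    symptom_label: str

    def __post_init__(self) -> None:
        if self.severity_class not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity class {self.severity_class!r}")


@dataclass(frozen=True)
class TextEntry:
    participant_id: str
    day: int
    source: str
    raw_text: str

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError("raw_text must be non-empty at generation")
        if self.source not in TEXT_SOURCES:
            raise ValueError(f"unknown text source {self.source!r}")


@dataclass(frozen=True)
class EpdsResponse:
    participant_id: str
    day: int
    total: int
    suicidal_ideation: bool

    def __post_init__(self) -> None:
        if not 0 <= self.total <= 30:
            raise ValueError(f"EPDS total must be in 0..30, got {self.total}")


def record_to_dict(rec) -> dict:
    return asdict(rec)
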