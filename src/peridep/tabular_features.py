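"""Covariate blocks and design-matrix assembly.

Four named blocks compose the candidate set: personal history (9 columns),
mood aggregates (3), symptom-class indicators (4), and language features
(429 with the default composition), for up to 445 candidates when all four
are included. The 15 possible non-empty block subsets define the stepwise
model grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .records import ParticipantRecord, RACE_LEVELS
from .windowing import ObservationWindow

BLOCK_ORDER = ("history", "mood", "symptoms", "language")

HISTORY_COLUMNS = [
    "hist.age",
    "hist.race_black",
    "hist.race_hispanic_latinx",
    "hist.race_asian",
    "hist.race_other",
    "hist.income_low",
    "hist.education_low",
    "hist.history_depression",
    "hist.history_anxiety",
]
MOOD_COLUMNS = ["mood.min", "mood.max", "mood.mean"]
SYMPTOM_COLUMNS = ["symp.critical", "symp.significant", "symp.common", "symp.open"]


def encode_history(p: ParticipantRecord) -> np.ndarray:
    """9-vector: age in years (standardized downstream on the training
    split), one-hot race/ethnicity with white as the reference level, and
    the four binary history indicators."""
    if p.race_ethnicity not in RACE_LEVELS:
        raise ValueError(f"unknown race/ethnicity {p.race_ethnicity!r}")
    race = [float(p.race_ethnicity == lvl) for lvl in RACE_LEVELS[1:]]
    return np.array(
        [float(p.age_years)]
        + race
        + [
            float(p.income_low),
            float(p.education_low),
            float(p.history_depression),
            float(p.history_anxiety),
        ]
    )


def mood_block(window: ObservationWindow) -> np.ndarray:
    """(min, max, mean) daily mood over the window's look-back interval."""
    if window.mood_min is None:
        raise ValueError("mood aggregates not attached; run attach_covariates")
    return np.array([window.mood_min, window.mood_max, window.mood_mean])


def symptom_block(window: ObservationWindow) -> np.ndarray:
    """Four 0/1 columns: critical, significant, common, open-ended."""
    return np.array(
        [
            float(window.symptom_critical),
            float(window.symptom_significant),
            float(window.symptom_common),
            float(window.symptom_open),
        ]
    )


@dataclass(frozen=True)
class ModelSpec:
    """A non-empty subset of the four blocks."""

    blocks: frozenset

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a model spec must include at least one block")
        unknown = self.blocks - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown blocks {sorted(unknown)}")

    @property
    def ordered(self) -> tuple[str, ...]:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)

    def label(self) -> str:
        names = {
            "history": "Personal history",
            "mood": "Mood",
            "symptoms": "Pregnancy-related symptoms",
            "language": "Language features",
        }
        return " + ".join(names[b] for b in self.ordered)


def all_model_specs() -> list[ModelSpec]:
    """The 15 block subsets, ordered singles / pairs / triples / full, with
    language-feature models leading each tier they appear in (the
    conventional presentation order for this stepwise grid)."""
    order = [
        ("language",),
        ("history",),
        ("mood",),
        ("symptoms",),
        ("history", "language"),
        ("mood", "language"),
        ("symptoms", "language"),
        ("history", "mood"),
        ("history", "symptoms"),
        ("mood", "symptoms"),
        ("history", "mood", "language"),
        ("history", "symptoms", "language"),
        ("mood", "symptoms", "language"),
        ("history", "mood", "symptoms"),
        ("history", "mood", "symptoms", "language"),
    ]
    specs = [ModelSpec(frozenset(t)) for t in order]
    assert len(specs) == sum(
        1 for r in range(1, 5) for _ in combinations(BLOCK_ORDER, r)
    )
    return specs


class FeatureBlockSet:
    """Row-aligned named blocks: block name -> (column names, matrix)."""

    def __init__(self, blocks: dict[str, tuple[list[str], np.ndarray]]):
        n_rows = {m.shape[0] for _, m in blocks.values()}
        if len(n_rows) > 1:
            raise ValueError("blocks must be row-aligned")
        all_names = [c for names, _ in blocks.values() for c in names]
        if len(set(all_names)) != len(all_names):
            raise ValueError("duplicated column names across blocks")
        for name, (names, m) in blocks.items():
            if m.shape[1] != len(names):
                raise ValueError(f"block {name!r}: {m.shape[1]} columns, "
                                 f"{len(names)} names")
        self.blocks = blocks
        self.n_rows = n_rows.pop() if n_rows else 0

    def width(self, spec: ModelSpec) -> int:
        return sum(self.blocks[b][1].shape[1] for b in spec.ordered)


def build_blocks(
    windows: Sequence[ObservationWindow],
    participants: dict[str, ParticipantRecord],
    language_matrix: np.ndarray,
    language_names: list[str],
    mood_missing_indicator: bool = False,
) -> FeatureBlockSet:
    """Assemble the four canonical blocks for a window list.

    ``mood_missing_indicator`` appends a fourth mood column marking windows
    whose look-back interval held no mood report (imputed with the
    participant mean); off by default to keep the canonical 3-column block.
    """
    hist = np.array([encode_history(participants[w.participant_id]) for w in windows])
    mood = np.array([mood_block(w) for w in windows])
    mood_names = list(MOOD_COLUMNS)
    if mood_missing_indicator:
        mood = np.column_stack(
            [mood, [float(w.mood_missing) for w in windows]]
        )
        mood_names.append("mood.missing")
    symp = np.array([symptom_block(w) for w in windows])
    if language_matrix.shape[0] != len(windows):
        raise ValueError("language matrix not row-aligned with windows")
    return FeatureBlockSet(
        {
            "history": (list(HISTORY_COLUMNS), hist),
            "mood": (mood_names, mood),
            "symptoms": (list(SYMPTOM_COLUMNS), symp),
            "language": (list(language_names), language_matrix),
        }
    )


def assemble(
    windows: Sequence[ObservationWindow],
    spec: ModelSpec,
    blocks: FeatureBlockSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Horizontal concatenation of the spec's blocks in canonical order.

    Returns (X, y, flag labels, column names) with y the averaged EPDS
    outcome and labels the moderate-to-severe flag.
    """
    if blocks.n_rows != len(windows):
        raise ValueError("blocks not row-aligned with windows")
    mats, names = [], []
    for b in spec.ordered:
        bnames, m = blocks.blocks[b]
        mats.append(m)
        names.extend(bnames)
    X = np.hstack(mats)
    y = np.array([w.outcome_mean_epds for w in windows])
    labels = np.array([w.flag_label for w in windows], dtype=bool)
    return X, y, labels, names
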