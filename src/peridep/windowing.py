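"""Data structuring: usable-entry filtering, temporal grouping, text-to-EPDS
matching, outcome construction, and the moderate-to-severe flag rule.

The modeling unit is an observation window: a run of free-text entries in
close temporal proximity, concatenated and matched to the average of all
EPDS scores that (a) fall strictly after the window's last entry day, (b)
fall within ``window_days`` of it, and (c) occur strictly before any newer
text entry. EPDS scores with no preceding text, and text groups with no
following EPDS, are dropped.

Grouping rule: consecutive usable entries form one group as long as no EPDS
response falls strictly between them and the gap between adjacent entries is
at most ``window_days``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._stem import porter_stem
from .records import EpdsResponse, MoodReport, SymptomReport, TextEntry

logger = logging.getLogger(__name__)

FLAG_THRESHOLD = 14  # EPDS >= 14, or < 14 with suicidal ideation, flags a window

# The sklearn list plus the removal examples ("i", "be", "did") and common
# contraction remnants left after punctuation stripping.
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS) | {
    "i", "be", "did", "im", "ive", "id", "ill", "dont", "didnt", "cant",
    "wont", "isnt", "wasnt", "couldnt", "wouldnt", "shouldnt", "its", "thats",
}
DEFAULT_COMMON_SINGLE_WORDS = frozenset(
    {"yes", "no", "yeah", "yep", "ok", "okay", "na", "none", "nothing", "idk"}
)

_TOKEN_RE = re.compile(r"[a-z]+")

STEMMERS: dict[str, Callable[[str], str]] = {
    "porter": porter_stem,
    "identity": lambda w: w,
}


@dataclass(frozen=True)
class WindowConfig:
    window_days: int = 30
    stopword_list: frozenset = DEFAULT_STOPWORDS
    common_single_words: frozenset = DEFAULT_COMMON_SINGLE_WORDS
    stemmer_name: str = "porter"

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.window_days not in (30, 60):
            logger.warning(
                "window_days=%d is outside the standard {30, 60} frames",
                self.window_days,
            )
        if self.stemmer_name not in STEMMERS:
            raise ValueError(f"unknown stemmer {self.stemmer_name!r}")

    @property
    def stemmer(self) -> Callable[[str], str]:
        return STEMMERS[self.stemmer_name]


@dataclass
class ObservationWindow:
    """One concatenated-text group matched to an averaged EPDS outcome."""

    participant_id: str
    entry_days: list[int]
    tokens: list[str]
    last_entry_day: int
    matched_epds_days: list[int]
    outcome_mean_epds: float
    any_suicidal_ideation: bool
    flag_label: bool
    mood_min: float | None = None
    mood_max: float | None = None
    mood_mean: float | None = None
    mood_missing: bool = True
    symptom_critical: bool = False
    symptom_significant: bool = False
    symptom_common: bool = False
    symptom_open: bool = False


def process_entry(raw_text: str, config: WindowConfig | None = None) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords and common single-response
    words, and stem what remains, preserving order."""
    config = config or WindowConfig()
    text = raw_text.lower().replace("'", "").replace("’", "")
    stem = config.stemmer
    removed = config.stopword_list | config.common_single_words
    return [stem(t) for t in _TOKEN_RE.findall(text) if t not in removed]


def is_usable(tokens: Sequence[str]) -> bool:
    """An entry (or concatenated group) is usable iff >= 1 token survives."""
    return len(tokens) >= 1


@dataclass(frozen=True)
class ProcessedEntry:
    participant_id: str
    day: int
    tokens: tuple[str, ...]


def prepare_entries(
    entries: Iterable[TextEntry], config: WindowConfig
) -> list[ProcessedEntry]:
    """Tokenize raw entries and keep the usable ones, sorted by day."""
    out = []
    for e in entries:
        toks = process_entry(e.raw_text, config)
        if is_usable(toks):
            out.append(ProcessedEntry(e.participant_id, e.day, tuple(toks)))
    out.sort(key=lambda p: (p.participant_id, p.day))
    return out


def flag_epds(mean_total: float, any_suicidal: bool) -> bool:
    """Moderate-to-severe rule: score >= 14, or < 14 with suicidal ideation."""
    if not 0 <= mean_total <= 30:
        raise ValueError(f"EPDS score out of range: {mean_total}")
    return mean_total >= FLAG_THRESHOLD or bool(any_suicidal)


def _check_sorted(days: Sequence[int], what: str) -> None:
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError(f"{what} must be sorted by day within participant")


def _group_entries(
    entries: Sequence[ProcessedEntry], epds_days: Sequence[int], window_days: int
) -> list[list[ProcessedEntry]]:
    groups: list[list[ProcessedEntry]] = []
    for e in entries:
        if groups:
            prev_day = groups[-1][-1].day
            intervening = any(prev_day < d < e.day for d in epds_days)
            if e.day - prev_day <= window_days and not intervening:
                groups[-1].append(e)
                continue
        groups.append([e])
    return groups


def build_windows(
    entries: Iterable[ProcessedEntry],
    epds: Iterable[EpdsResponse],
    config: WindowConfig | None = None,
) -> list[ObservationWindow]:
    """Group usable entries, match each group to its qualifying EPDS scores,
    and build one window per surviving group.

    A response at day ``e`` qualifies for a group whose last entry is at day
    ``t`` iff ``t < e <= t + window_days`` and ``e`` is strictly before the
    next text entry day. Groups with no qualifying EPDS are dropped, as are
    EPDS responses never matched to any group.
    """
    config = config or WindowConfig()
    L = config.window_days

    by_pid_entries: dict[str, list[ProcessedEntry]] = {}
    for e in entries:
        by_pid_entries.setdefault(e.participant_id, []).append(e)
    by_pid_epds: dict[str, list[EpdsResponse]] = {}
    for r in epds:
        by_pid_epds.setdefault(r.participant_id, []).append(r)

    windows: list[ObservationWindow] = []
    for pid in sorted(by_pid_entries):
        p_entries = by_pid_entries[pid]
        p_epds = by_pid_epds.get(pid, [])
        _check_sorted([e.day for e in p_entries], "text entries")
        _check_sorted([r.day for r in p_epds], "EPDS responses")
        epds_days = [r.day for r in p_epds]

        groups = _group_entries(p_entries, epds_days, L)
        for gi, group in enumerate(groups):
            t_last = group[-1].day
            next_entry_day = (
                groups[gi + 1][0].day if gi + 1 < len(groups) else None
            )
            matched = [
                r
                for r in p_epds
                if t_last < r.day <= t_last + L
                and (next_entry_day is None or r.day < next_entry_day)
            ]
            if not matched:
                continue
            tokens = [t for e in group for t in e.tokens]
            mean_total = sum(r.total for r in matched) / len(matched)
            any_si = any(r.suicidal_ideation for r in matched)
            win = ObservationWindow(
                participant_id=pid,
                entry_days=[e.day for e in group],
                tokens=tokens,
                last_entry_day=t_last,
                matched_epds_days=[r.day for r in matched],
                outcome_mean_epds=mean_total,
                any_suicidal_ideation=any_si,
                flag_label=flag_epds(mean_total, any_si),
            )
            for d in win.matched_epds_days:
                assert t_last < d <= t_last + L
                assert next_entry_day is None or d < next_entry_day
            windows.append(win)
    return windows


def attach_covariates(
    window: ObservationWindow,
    moods: Sequence[MoodReport],
    symptoms: Sequence[SymptomReport],
    window_days: int = 30,
    neutral_mood: float = 3.0,
) -> ObservationWindow:
    """Attach mood and symptom aggregates over the look-back interval
    ``(last_entry_day - window_days, last_entry_day]``.

    Windows with no mood report in the interval carry the participant-level
    mean mood (all of that participant's reports) with ``mood_missing=True``;
    a participant with no mood reports at all falls back to the scale
    midpoint (such participants fail the study's inclusion rule and are
    normally filtered upstream).
    """
    _check_sorted([m.day for m in moods], "mood reports")
    _check_sorted([s.day for s in symptoms], "symptom reports")
    lo = window.last_entry_day - window_days
    hi = window.last_entry_day
    in_win = [m.mood for m in moods if lo < m.day <= hi]
    if in_win:
        mood_min, mood_max = float(min(in_win)), float(max(in_win))
        mood_mean = sum(in_win) / len(in_win)
        missing = False
    else:
        overall = [m.mood for m in moods]
        fallback = sum(overall) / len(overall) if overall else neutral_mood
        mood_min = mood_max = mood_mean = float(fallback)
        missing = True
    classes = {s.severity_class for s in symptoms if lo < s.day <= hi}
    return replace(
        window,
        mood_min=mood_min,
        mood_max=mood_max,
        mood_mean=mood_mean,
        mood_missing=missing,
        symptom_critical="critical" in classes,
        symptom_significant="significant" in classes,
        symptom_common="common" in classes,
        symptom_open="open_ended" in classes,
    )
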