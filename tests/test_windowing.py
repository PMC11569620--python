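"""Text processing, window matching, and the moderate-to-severe flag rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peridep.records import EpdsResponse, MoodReport, SymptomReport
from peridep.windowing import (
    ObservationWindow,
    ProcessedEntry,
    WindowConfig,
    attach_covariates,
    build_windows,
    flag_epds,
    is_usable,
    process_entry,
)


class TestProcessEntry:
    def test_empty_input_gives_empty_list(self):
        assert process_entry("") == []

    def test_removal_example_words_all_dropped(self):
        # "I", "be", "did" are stopwords; "yes" is a common single-response word
        assert process_entry("I did be yes") == []

    def test_stemming_after_custom_stopword_removal(self):
        config = WindowConfig(
            stopword_list=frozenset({"it", "gets"}),
            common_single_words=frozenset(),
        )
        assert process_entry("Hoping it gets better", config) == ["hope", "better"]

    def test_punctuation_and_case_are_stripped(self):
        config = WindowConfig(stopword_list=frozenset({"the"}),
                              common_single_words=frozenset())
        assert process_entry("The BABY kicked!", config) == ["babi", "kick"]

    def test_order_preserved(self, themes):
        config = WindowConfig(stopword_list=frozenset(),
                              common_single_words=frozenset())
        toks = process_entry("doctor visit tomorrow morning", config)
        assert toks == ["doctor", "visit", "tomorrow", "morn"]


@pytest.mark.parametrize(
    "tokens,expected",
    [([], False), (["hope"], True), (["tok"] * 1000, True)],
)
def test_is_usable_means_at_least_one_token(tokens, expected):
    assert is_usable(tokens) is expected


class TestFlagRule:
    @pytest.mark.parametrize(
        "total,si,expected",
        [(14, False, True), (13, True, True), (0, False, False),
         (13.9, False, False), (30, False, True), (0, True, True)],
    )
    def test_threshold_and_ideation(self, total, si, expected):
        assert flag_epds(total, si) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            flag_epds(31, False)
        with pytest.raises(ValueError):
            flag_epds(-1, False)

    @given(
        a=st.floats(0, 30), b=st.floats(0, 30),
        si=st.booleans(), si2=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_score_and_ideation(self, a, b, si, si2):
        lo, hi = min(a, b), max(a, b)
        assert flag_epds(lo, si) <= flag_epds(hi, si)
        assert flag_epds(a, si and si2) <= flag_epds(a, si or si2)


def _entries(pid, days):
    return [ProcessedEntry(pid, d, ("tok",)) for d in days]


def _epds(pid, days_scores, si=()):
    return [
        EpdsResponse(pid, d, s, d in si) for d, s in days_scores
    ]


class TestBuildWindowsHandWorked:
    def test_score_outside_frame_is_dropped(self):
        # text day 0; EPDS day 10 (8) and day 40 (20); 30-day frame
        wins = build_windows(
            _entries("p", [0]), _epds("p", [(10, 8), (40, 20)]),
            WindowConfig(window_days=30))
        assert len(wins) == 1
        assert wins[0].matched_epds_days == [10]
        assert wins[0].outcome_mean_epds == 8.0

    def test_epds_without_preceding_text_contributes_nothing(self):
        wins = build_windows(
            _entries("p", [10]), _epds("p", [(5, 12)]),
            WindowConfig(window_days=30))
        assert wins == []

    def test_newer_entry_blocks_earlier_group(self):
        # texts day 0+10 (one group); EPDS day 15; new text day 20; EPDS day 25
        wins = build_windows(
            _entries("p", [0, 10, 20]),
            _epds("p", [(15, 10), (25, 16)]),
            WindowConfig(window_days=30))
        assert len(wins) == 2
        assert wins[0].entry_days == [0, 10]
        assert wins[0].outcome_mean_epds == 10.0
        assert wins[1].entry_days == [20]
        assert wins[1].outcome_mean_epds == 16.0

    def test_same_day_epds_not_matched(self):
        wins = build_windows(
            _entries("p", [5]), _epds("p", [(5, 20)]),
            WindowConfig(window_days=30))
        assert wins == []

    def test_duplicate_same_day_epds_both_averaged(self):
        wins = build_windows(
            _entries("p", [0]), _epds("p", [(10, 8), (10, 12)]),
            WindowConfig(window_days=30))
        assert len(wins) == 1
        assert wins[0].outcome_mean_epds == 10.0

    def test_suicidal_ideation_ors_over_matched(self):
        wins = build_windows(
            _entries("p", [0]),
            _epds("p", [(5, 4), (10, 6)], si={10}),
            WindowConfig(window_days=30))
        assert wins[0].any_suicidal_ideation is True
        assert wins[0].flag_label is True  # score < 14 but ideation present

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            build_windows(_entries("p", [10, 0]), _epds("p", [(20, 5)]),
                          WindowConfig(window_days=30))


def brute_force_windows(entries, epds, window_days):
    """Independent enumeration of the matching rules: every candidate group
    is a maximal run of entries with no strictly-intervening EPDS and
    adjacent gaps <= window_days; every (group, response) pair is tested
    against the three conditions explicitly against the raw entry list."""
    out = []
    if not entries:
        return out
    # group boundaries from pairwise conditions
    breaks = [0]
    for i in range(1, len(entries)):
        gap = entries[i].day - entries[i - 1].day
        between = [r for r in epds
                   if entries[i - 1].day < r.day < entries[i].day]
        if gap > window_days or between:
            breaks.append(i)
    breaks.append(len(entries))
    all_days = [e.day for e in entries]
    for a, b in zip(breaks, breaks[1:]):
        group = entries[a:b]
        last = group[-1].day
        matched = []
        for r in epds:
            after_last = r.day > last
            within = r.day <= last + window_days
            # "before a newer entry": strictly earlier than every later
            # entry day (a same-day entry and response cannot be ordered,
            # so the response is not credited to the older group)
            newer = [d for d in all_days if last < d <= r.day]
            if after_last and within and not newer:
                matched.append(r)
        if matched:
            out.append(
                (
                    [e.day for e in group],
                    sorted(r.day for r in matched),
                    sum(r.total for r in matched) / len(matched),
                    any(r.suicidal_ideation for r in matched),
                )
            )
    return out


class TestMatchingOracle:
    @pytest.mark.parametrize("window_days", [30, 60])
    def test_equals_brute_force_on_random_timelines(self, window_days):
        rng = np.random.default_rng(202)
        config = WindowConfig(window_days=window_days)
        for case in range(200):
            n_e = rng.integers(1, 11)
            n_r = rng.integers(0, 11)
            e_days = sorted(int(d) for d in rng.integers(0, 100, n_e))
            r_days = sorted(int(d) for d in rng.integers(0, 100, n_r))
            entries = _entries("p", e_days)
            epds = [
                EpdsResponse("p", d, int(rng.integers(0, 31)),
                             bool(rng.random() < 0.2))
                for d in r_days
            ]
            got = [
                (w.entry_days, sorted(w.matched_epds_days),
                 w.outcome_mean_epds, w.any_suicidal_ideation)
                for w in build_windows(entries, epds, config)
            ]
            assert got == brute_force_windows(entries, epds, window_days), (
                f"case {case}: entries {e_days}, epds {r_days}")

    def test_matched_scores_never_precede_last_entry_or_follow_newer(self):
        rng = np.random.default_rng(303)
        config = WindowConfig(window_days=30)
        for _ in range(50):
            e_days = sorted(int(d) for d in rng.integers(0, 80, rng.integers(1, 8)))
            r_days = sorted(int(d) for d in rng.integers(0, 80, rng.integers(1, 8)))
            entries = _entries("p", e_days)
            epds = _epds("p", [(d, 5) for d in r_days])
            for w in build_windows(entries, epds, config):
                for d in w.matched_epds_days:
                    assert w.last_entry_day < d <= w.last_entry_day + 30
                    assert not any(w.last_entry_day < ed < d for ed in e_days)

    def test_doubling_window_never_loses_matches_per_surviving_window(self):
        rng = np.random.default_rng(404)
        for _ in range(50):
            e_days = sorted(int(d) for d in rng.integers(0, 120, rng.integers(1, 8)))
            r_days = sorted(int(d) for d in rng.integers(0, 120, rng.integers(1, 8)))
            entries = _entries("p", e_days)
            epds = _epds("p", [(d, 5) for d in r_days])
            w30 = {tuple(w.entry_days): len(w.matched_epds_days)
                   for w in build_windows(entries, epds, WindowConfig(window_days=30))}
            w60 = {tuple(w.entry_days): len(w.matched_epds_days)
                   for w in build_windows(entries, epds, WindowConfig(window_days=60))}
            for key, n30 in w30.items():
                if key in w60:
                    assert w60[key] >= n30


def _window(pid="p", last=20):
    return ObservationWindow(
        participant_id=pid, entry_days=[last], tokens=["tok"],
        last_entry_day=last, matched_epds_days=[last + 5],
        outcome_mean_epds=5.0, any_suicidal_ideation=False, flag_label=False)


class TestAttachCovariates:
    def test_single_mood_report(self):
        w = attach_covariates(_window(), [MoodReport("p", 15, 3)], [])
        assert (w.mood_min, w.mood_max, w.mood_mean) == (3, 3, 3.0)
        assert not w.mood_missing

    def test_mood_aggregates(self):
        moods = [MoodReport("p", d, m) for d, m in [(1, 1), (10, 5), (20, 3)]]
        w = attach_covariates(_window(), moods, [])
        assert (w.mood_min, w.mood_max, w.mood_mean) == (1, 5, 3.0)

    def test_lookback_is_half_open_on_the_left(self):
        # last=20, 30-day look-back: day -10 excluded, day 20 included
        moods = [MoodReport("p", -10, 1), MoodReport("p", 20, 5)]
        w = attach_covariates(_window(), moods, [], window_days=30)
        assert (w.mood_min, w.mood_max) == (5, 5)

    def test_symptom_class_membership(self):
        symptoms = [
            SymptomReport("p", 5, "critical", "fever"),
            SymptomReport("p", 6, "common", "nausea"),
            SymptomReport("p", 7, "common", "fatigue"),
        ]
        w = attach_covariates(_window(), [MoodReport("p", 15, 3)], symptoms)
        assert (w.symptom_critical, w.symptom_significant,
                w.symptom_common, w.symptom_open) == (True, False, True, False)

    def test_missing_mood_imputes_participant_mean(self):
        moods = [MoodReport("p", 100, 4), MoodReport("p", 110, 2)]
        w = attach_covariates(_window(last=20), moods, [])
        assert w.mood_missing
        assert w.mood_mean == 3.0
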