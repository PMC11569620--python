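"""Synthetic app-user cohorts with the statistical structure the analysis
assumes.

Each pregnancy carries a latent depression trait ``z`` (time-constant by
default, optionally AR(1)-varying). The trait drives every stream:

* mood reports: ``clip(round(3.9 - beta_mood * z + noise), 1, 5)``;
* EPDS totals: ``clip(round(7 + 5 * z + noise), 0, 30)``, with the
  suicidal-ideation item turning positive with probability increasing in z;
* free text: tokens drawn from a mixture over valence/theme word pools whose
  weight on negative-valence and mental-health/finances vocabulary rises
  monotonically with z, scaled by ``text_valence_link`` / ``theme_link``.

Default reporting rates reproduce the per-pregnancy intensities of the kind
of prenatal-app cohort this emulates: about 8 text entries of mean raw
length 19 words, 5.8 mood reports, and 2.5 EPDS completions per pregnancy
over roughly 34 followed weeks. Identical config and seed give
byte-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .records import (
    EpdsResponse,
    MoodReport,
    ParticipantRecord,
    SymptomReport,
    TextEntry,
    RACE_LEVELS,
    record_to_dict,
)
from ._stem import porter_stem
from .text_features import EmbeddingTable, ThemeLexicon, ValenceLexicon


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int = 500
    days_followed: int = 238           # ~34 gestational weeks of app use
    trait_sd: float = 1.0
    beta_mood: float = 0.5             # Likert units per trait SD (sign: worse mood)
    beta_history: float = 0.8          # trait shift for depression/anxiety history
    beta_age: float = 0.4              # trait shift for age < 25
    beta_income: float = 0.4           # trait shift for income < $50k
    text_valence_link: float = 0.6     # in [0,1]: negative-valence tilt with trait
    theme_link: float = 0.6            # in [0,1]: mental-health/finances tilt
    epds_noise_sd: float = 3.0
    mood_noise_sd: float = 0.8
    entries_per_week: float = 0.25
    moods_per_week: float = 0.17
    symptoms_per_week: float = 0.10
    epds_per_trimester: float = 0.85
    mean_text_len: int = 19            # raw words; SD follows a lognormal fit
    trait_ar1: float = 0.0             # >0 switches on an AR(1) day-varying component
    debug_traits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.days_followed <= 0 or self.trait_sd <= 0:
            raise ValueError("days_followed and trait_sd must be positive")
        for name in ("entries_per_week", "moods_per_week", "symptoms_per_week",
                     "epds_per_trimester"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("text_valence_link", "theme_link"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.epds_noise_sd <= 0 or self.mood_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.mean_text_len <= 0:
            raise ValueError("mean_text_len must be positive")

    def null(self) -> "SyntheticConfig":
        """Copy with every structural effect switched off."""
        return SyntheticConfig(
            **{
                **asdict(self),
                "beta_mood": 0.0,
                "beta_history": 0.0,
                "beta_age": 0.0,
                "beta_income": 0.0,
                "text_valence_link": 0.0,
                "theme_link": 0.0,
            }
        )


@dataclass
class CohortData:
    participants: list[ParticipantRecord]
    moods: list[MoodReport]
    symptoms: list[SymptomReport]
    texts: list[TextEntry]
    epds: list[EpdsResponse]
    traits: dict[str, float] | None = None
    config: SyntheticConfig | None = None


# Surface vocabulary the text generator samples from. Pools (positive,
# negative, mental health, finances, covid, pregnancy, neutral) are derived
# at run time by scoring these words against the supplied lexicons, so
# generated text and the analysis lexicons stay consistent by construction.
WORD_POOL: tuple[str, ...] = (
    # positive valence
    "good", "great", "happy", "love", "wonderful", "beautiful", "nice",
    "sweet", "calm", "perfect", "amazing", "excited", "glad", "thankful",
    "grateful", "blessed", "hopeful", "proud", "cheerful", "relieved",
    "relaxed", "fun", "laughed", "smile", "supportive", "comfortable",
    "cute", "lovely", "lucky", "enjoyed", "peaceful", "pleased",
    # negative valence
    "sad", "miserable", "terrible", "horrible", "awful", "worst", "worried",
    "anxious", "nervous", "afraid", "scared", "panicked", "stressed",
    "overwhelmed", "exhausted", "tired", "drained", "angry", "mad",
    "frustrated", "upset", "hurt", "painful", "sore", "cramping",
    "headache", "migraine", "nauseous", "crying", "lonely", "hopeless",
    "guilty", "ashamed", "struggling", "rough", "crippling", "hated",
    # mental health / services
    "depressed", "depression", "anxiety", "stress", "therapist", "therapy",
    "counseling", "psychiatrist", "medication", "meds", "mental",
    "breakdown", "panic",
    # finances / work
    "money", "rent", "mortgage", "bills", "paycheck", "job", "jobless",
    "unemployed", "layoff", "debt", "broke", "afford", "budget", "evicted",
    "pay", "work",
    # covid
    "covid", "pandemic", "mask", "booster", "vaccine", "quarantine",
    "lockdown",
    # pregnancy
    "pregnant", "pregnancy", "trimester", "ultrasound", "contractions",
    "doula", "midwife", "prenatal", "bump", "kick", "fetal", "nursery",
    # neutral daily life
    "baby", "home", "family", "friend", "partner", "husband", "doctor",
    "appointment", "morning", "night", "week", "today", "dinner", "food",
    "sleep", "nap", "walk", "book", "movie", "music", "weather", "car",
    "dog", "cat", "room", "house", "kitchen", "school", "phone", "shower",
    "coffee", "tea", "garden", "sister", "brother", "mom", "dad", "visit",
    "weekend", "sandwich", "shopping", "clothes", "laundry", "cleaning",
)

_SYMPTOM_LABELS = {
    "critical": ("leaking fluid", "fever", "moderate-to-severe cramping",
                 "heavy bleeding", "decreased fetal movement"),
    "significant": ("frequent dizziness", "swelling in face",
                    "vision problems", "severe headache"),
    "common": ("fatigue", "heartburn", "nausea", "back pain", "insomnia"),
    "open_ended": ("hot flashes", "back pain", "restless legs", "itchy skin"),
}
_SEVERITY_PROBS = {  # proportions of report-days by class in the emulated cohort
    "critical": 0.037, "significant": 0.122, "common": 0.816, "open_ended": 0.025,
}
_TEXT_SOURCE_PROBS = {
    "journal": 0.3, "prompt": 0.5, "covid_screener": 0.1, "other_symptom": 0.1,
}

_BASE_POOL_WEIGHTS = {
    "neutral": 0.40, "positive": 0.25, "negative": 0.12,
    "mental_health": 0.06, "finances": 0.06, "covid": 0.05, "pregnancy": 0.06,
}

_pool_cache: dict[tuple[int, int], dict[str, list[str]]] = {}
_cache_refs: list = []  # keep lexicons alive so id() keys stay valid


def _word_pools(
    valence: ValenceLexicon, themes: ThemeLexicon
) -> dict[str, list[str]]:
    key = (id(valence), id(themes))
    if key in _pool_cache:
        return _pool_cache[key]
    name_idx = {n: i for i, n in enumerate(themes.names)}
    pools: dict[str, list[str]] = {k: [] for k in _BASE_POOL_WEIGHTS}
    for word in WORD_POOL:
        stem = porter_stem(word)
        p, n = valence.scores.get(stem, (0.0, 0.0))
        placed = False
        for theme, pool in (
            ("mental_health", "mental_health"),
            ("finances", "finances"),
            ("covid19", "covid"),
            ("pregnancy_terms", "pregnancy"),
        ):
            i = name_idx.get(theme)
            if i is not None and themes.matches(stem, i):
                pools[pool].append(word)
                placed = True
        if n - p > 0.2:
            pools["negative"].append(word)
            placed = True
        elif p - n > 0.2:
            pools["positive"].append(word)
            placed = True
        if not placed:
            pools["neutral"].append(word)
    pools = {k: v for k, v in pools.items() if v}
    _pool_cache[key] = pools
    _cache_refs.append((valence, themes))
    return pools


def generate_text(
    trait: float,
    valence_lexicon: ValenceLexicon,
    theme_lexicon: ThemeLexicon,
    length: int,
    rng: np.random.Generator,
    text_valence_link: float = 0.6,
    theme_link: float = 0.6,
) -> str:
    """Sample one raw text entry of ``length`` words.

    Pool weights tilt exponentially with the trait: negative-valence words by
    ``exp(text_valence_link * trait)``, positive by its reciprocal, and
    mental-health/finances vocabulary by ``exp(theme_link * trait)``, then
    renormalize — a strictly monotone tilt whenever the link is positive and
    exact trait-independence when it is zero. ``length == 0`` returns the
    empty string (the caller emits no entry).
    """
    if len(valence_lexicon) == 0:
        raise ValueError("valence lexicon must be non-empty")
    if len(theme_lexicon) == 0:
        raise ValueError("theme lexicon must be non-empty")
    if length == 0:
        return ""
    pools = _word_pools(valence_lexicon, theme_lexicon)
    names = sorted(pools)
    w = np.array([_BASE_POOL_WEIGHTS[k] for k in names])
    tilt = {
        "negative": np.exp(text_valence_link * trait),
        "positive": np.exp(-text_valence_link * trait),
        "mental_health": np.exp(theme_link * trait),
        "finances": np.exp(theme_link * trait),
    }
    w = w * np.array([tilt.get(k, 1.0) for k in names])
    w /= w.sum()
    sizes = np.array([len(pools[k]) for k in names])
    ks = rng.choice(len(names), size=length, p=w)
    idx = rng.integers(0, sizes[ks])
    return " ".join(pools[names[k]][i] for k, i in zip(ks, idx))


def _sample_participant(i: int, rng: np.random.Generator) -> ParticipantRecord:
    age = int(np.clip(round(rng.normal(29.5, 5.5)), 14, 50))
    race = RACE_LEVELS[
        rng.choice(5, p=(0.795, 0.108, 0.020, 0.034, 0.043))
    ]
    hist = rng.choice(4, p=(0.031, 0.093, 0.196, 0.680))  # dep / anx / both / none
    parity = 0 if rng.random() < 0.497 else 1 + rng.poisson(0.3)
    return ParticipantRecord(
        participant_id=f"p{i:05d}",
        age_years=age,
        race_ethnicity=race,
        income_low=bool(rng.random() < 0.38),
        education_low=bool(rng.random() < 0.32),
        history_depression=hist in (0, 2),
        history_anxiety=hist in (1, 2),
        parity=int(parity),
    )


def _text_length(mean_len: int, rng: np.random.Generator) -> int:
    # lognormal matched to mean ~= mean_len with coefficient of variation ~1.5
    # (means the heavy right tail of journal-style entries)
    sigma2 = np.log(1.0 + 1.5**2)
    mu = np.log(mean_len) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))


def generate_cohort(
    config: SyntheticConfig,
    valence_lexicon: ValenceLexicon | None = None,
    theme_lexicon: ThemeLexicon | None = None,
) -> CohortData:
    """Generate all five record streams for one cohort.

    Every participant has at least one EPDS response (one is forced at a
    uniform random day if the trimester prompts all go unanswered). The
    latent trait is discarded unless ``config.debug_traits`` is set.
    """
    valence_lexicon = valence_lexicon or ValenceLexicon.default()
    theme_lexicon = theme_lexicon or ThemeLexicon.default()
    rng = np.random.default_rng(config.seed)
    c = config

    participants, moods, symptoms, texts, epds = [], [], [], [], []
    traits: dict[str, float] = {}
    p_day = {k: v / 7.0 for k, v in (
        ("entry", c.entries_per_week),
        ("mood", c.moods_per_week),
        ("symptom", c.symptoms_per_week),
    )}
    sev_names = tuple(_SEVERITY_PROBS)
    sev_p = np.array([_SEVERITY_PROBS[k] for k in sev_names])
    sev_p = sev_p / sev_p.sum()
    src_names = tuple(_TEXT_SOURCE_PROBS)
    src_p = np.array([_TEXT_SOURCE_PROBS[k] for k in src_names])

    for i in range(c.n_participants):
        p = _sample_participant(i, rng)
        participants.append(p)
        z0 = rng.normal(0.0, c.trait_sd)
        z0 += c.beta_history * float(p.history_depression or p.history_anxiety)
        z0 += c.beta_age * float(p.age_years < 25)
        z0 += c.beta_income * float(p.income_low)
        traits[p.participant_id] = z0

        if c.trait_ar1 > 0:
            # AR(1) day-level wobble around the pregnancy-constant trait
            eps = rng.normal(0.0, c.trait_sd * 0.3, size=c.days_followed)
            wobble = np.empty(c.days_followed)
            prev = 0.0
            for d in range(c.days_followed):
                prev = c.trait_ar1 * prev + np.sqrt(1 - c.trait_ar1**2) * eps[d]
                wobble[d] = prev
        else:
            wobble = np.zeros(c.days_followed)

        def z_at(day: int) -> float:
            return z0 + wobble[min(day, c.days_followed - 1)]

        D = c.days_followed
        mood_days = np.flatnonzero(rng.random(D) < p_day["mood"])
        if mood_days.size:
            zs = z0 + wobble[mood_days]
            vals = np.clip(
                np.round(3.9 - c.beta_mood * zs
                         + rng.normal(0.0, c.mood_noise_sd, mood_days.size)),
                1, 5).astype(int)
            moods.extend(
                MoodReport(p.participant_id, int(d), int(v))
                for d, v in zip(mood_days, vals))

        symp_days = np.flatnonzero(rng.random(D) < p_day["symptom"])
        if symp_days.size:
            sevs = rng.choice(len(sev_names), size=symp_days.size, p=sev_p)
            for d, si_ in zip(symp_days, sevs):
                sev = sev_names[si_]
                label = _SYMPTOM_LABELS[sev][
                    rng.integers(len(_SYMPTOM_LABELS[sev]))]
                symptoms.append(
                    SymptomReport(p.participant_id, int(d), sev, label))

        entry_days = np.flatnonzero(rng.random(D) < p_day["entry"])
        for d in entry_days:
            length = _text_length(c.mean_text_len, rng)
            raw = generate_text(
                z_at(int(d)), valence_lexicon, theme_lexicon, length, rng,
                c.text_valence_link, c.theme_link)
            if raw:
                src = src_names[rng.choice(len(src_names), p=src_p)]
                texts.append(TextEntry(p.participant_id, int(d), src, raw))

        p_epds_days: list[int] = []
        third = c.days_followed / 3.0
        for t in range(3):
            k = rng.poisson(c.epds_per_trimester)
            for _ in range(k):
                p_epds_days.append(int(rng.integers(int(t * third),
                                                    max(int((t + 1) * third), int(t * third) + 1))))
        if not p_epds_days:
            p_epds_days.append(int(rng.integers(c.days_followed)))
        for day in sorted(p_epds_days):
            z = z_at(day)
            total = int(np.clip(
                round(7.0 + 5.0 * z + rng.normal(0.0, c.epds_noise_sd)), 0, 30))
            si = bool(rng.random() < expit(-5.5 + 1.5 * z))
            epds.append(EpdsResponse(p.participant_id, day, total, si))

    return CohortData(
        participants=participants,
        moods=moods,
        symptoms=symptoms,
        texts=texts,
        epds=epds,
        traits=traits if c.debug_traits else None,
        config=c,
    )


# ---------------------------------------------------------------------------
# Synthetic embedding table

def synthetic_embedding_table(
    valence_lexicon: ValenceLexicon | None = None,
    theme_lexicon: ThemeLexicon | None = None,
    dim: int = 300,
    seed: int = 0,
    anchor_noise: float = 0.5,
) -> EmbeddingTable:
    """Deterministic theme-anchored embeddings over the generator vocabulary.

    Each word pool gets a Gaussian anchor direction; a word's vector is its
    pool anchor plus independent noise, so words sharing a pool cluster in
    embedding space the way distributionally trained vectors would. Keys are
    stemmed, matching processed window tokens.
    """
    valence_lexicon = valence_lexicon or ValenceLexicon.default()
    theme_lexicon = theme_lexicon or ThemeLexicon.default()
    pools = _word_pools(valence_lexicon, theme_lexicon)
    rng = np.random.default_rng(seed)
    anchors = {k: rng.normal(0, 1.0 / np.sqrt(dim), size=dim)
               for k in sorted(pools)}
    vectors: dict[str, np.ndarray] = {}
    for name in sorted(pools):
        for word in pools[name]:
            stem = porter_stem(word)
            if stem not in vectors:
                vectors[stem] = anchors[name] + rng.normal(
                    0, anchor_noise / np.sqrt(dim), size=dim)
    return EmbeddingTable(vectors)


# ---------------------------------------------------------------------------
# JSONL round-trip

_STREAMS = ("participants", "moods", "symptoms", "texts", "epds")
_RECORD_TYPES = {
    "participants": ParticipantRecord,
    "moods": MoodReport,
    "symptoms": SymptomReport,
    "texts": TextEntry,
    "epds": EpdsResponse,
}


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Write five JSONL streams plus a manifest (config echo, seed, content
    hash). Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256()
    for stream in _STREAMS:
        path = out / f"{stream}.jsonl"
        with open(path, "w") as fh:
            for rec in getattr(cohort, stream):
                line = json.dumps(record_to_dict(rec), sort_keys=True)
                fh.write(line + "\n")
                digest.update(line.encode())
    manifest = {
        "config": asdict(cohort.config) if cohort.config else None,
        "seed": cohort.config.seed if cohort.config else None,
        "content_sha256": digest.hexdigest(),
        "counts": {s: len(getattr(cohort, s)) for s in _STREAMS},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_cohort(in_dir: str | Path) -> CohortData:
    src = Path(in_dir)
    streams = {}
    for stream in _STREAMS:
        cls = _RECORD_TYPES[stream]
        records = []
        for line in (src / f"{stream}.jsonl").read_text().splitlines():
            records.append(cls(**json.loads(line)))
        streams[stream] = records
    config = None
    mpath = src / "manifest.json"
    if mpath.exists():
        raw = json.loads(mpath.read_text()).get("config")
        if raw:
            config = SyntheticConfig(**raw)
    return CohortData(config=config, **streams)
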