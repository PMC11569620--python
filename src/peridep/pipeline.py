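"""Orchestration: participant-level splitting, evaluation metrics,
descriptive summaries, and the 15-model stepwise comparison.

Each of the 15 non-empty block subsets is fit as a lasso on the training
split, its penalty chosen by validation MSE, selective inference run on the
training fit, and discrimination evaluated on the held-out test split as the
AUC of the predicted (continuous) averaged EPDS against the binary
moderate-to-severe flag, with a stratified-bootstrap CI and the test R^2.
Splitting is by participant, never by window, so no participant's windows
straddle partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import si_lasso, text_features
from .records import ParticipantRecord
from .synthetic_cohort import CohortData, synthetic_embedding_table
from .tabular_features import (
    FeatureBlockSet,
    ModelSpec,
    all_model_specs,
    assemble,
    build_blocks,
)
from .text_features import (
    EmbeddingTable,
    ThemeLexicon,
    TopicModel,
    ValenceLexicon,
    fit_topics,
    language_block,
    rotate_embeddings,
)
from .windowing import (
    ObservationWindow,
    WindowConfig,
    attach_covariates,
    build_windows,
    prepare_entries,
)

logger = logging.getLogger(__name__)

EPDS_BANDS = ((0, 7), (7, 14), (14, 20), (20, 31))  # none/mild/moderate/severe


@dataclass(frozen=True)
class SplitConfig:
    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_participants(
    ids, config: SplitConfig
) -> tuple[set[str], set[str], set[str]]:
    """Seeded shuffle then proportional cut by participant.

    Validation and test sizes are floored; remainder participants go to the
    training set.
    """
    ids = sorted(set(ids))
    if len(ids) < 10:
        raise ValueError("need at least 10 participants to split")
    rng = np.random.default_rng(config.seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_val = int(np.floor(config.validation * n))
    n_test = int(np.floor(config.test * n))
    n_train = n - n_val - n_test
    return (
        set(order[:n_train]),
        set(order[n_train : n_train + n_val]),
        set(order[n_train + n_val :]),
    )


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one-half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci(scores, labels, B: int = 2000, seed: int = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Percentile CI from a class-stratified bootstrap."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = np.flatnonzero(labels), np.flatnonzero(~labels)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC CI undefined: both classes must be present")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        take = np.concatenate(
            [rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        vals[b] = auc(scores[take], labels[take])
    lo, hi = np.quantile(vals, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def r_squared(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class Descriptives:
    band_proportions: np.ndarray   # EPDS 0-6 / 7-13 / 14-19 / 20-30
    mood_mean: float
    mood_min: float
    mood_max: float
    text_len_epds_r: float
    text_len_epds_p: float
    flag_rate: float
    n_windows: int


def descriptives(windows: list[ObservationWindow]) -> Descriptives:
    """Severity-band proportions, mood summaries, and the token-count /
    outcome Pearson correlation."""
    if not windows:
        raise ValueError("need at least one window")
    y = np.array([w.outcome_mean_epds for w in windows])
    props = np.array([np.mean((y >= lo) & (y < hi)) for lo, hi in EPDS_BANDS])
    lens = np.array([len(w.tokens) for w in windows], dtype=float)
    if lens.std() > 0 and y.std() > 0:
        r, p = stats.pearsonr(lens, y)
    else:
        r, p = 0.0, 1.0
    moods = [w for w in windows if w.mood_mean is not None]
    return Descriptives(
        band_proportions=props,
        mood_mean=float(np.mean([w.mood_mean for w in moods])) if moods else np.nan,
        mood_min=float(np.mean([w.mood_min for w in moods])) if moods else np.nan,
        mood_max=float(np.mean([w.mood_max for w in moods])) if moods else np.nan,
        text_len_epds_r=float(r),
        text_len_epds_p=float(p),
        flag_rate=float(np.mean([w.flag_label for w in windows])),
        n_windows=len(windows),
    )


# ---------------------------------------------------------------------------
# End-to-end data preparation

_embedding_cache: dict = {}


def _default_embeddings(valence, themes, dim, seed, rotate) -> EmbeddingTable:
    """Synthetic pretrained-table stand-in, rotated once and memoized: like
    a downloaded embedding file, it is fixed across runs."""
    key = (id(valence), id(themes), dim, seed, rotate)
    table = _embedding_cache.get(key)
    if table is None:
        table = synthetic_embedding_table(valence, themes, dim=dim, seed=seed)
        if rotate:
            table = table.with_matrix(rotate_embeddings(table).rotated)
        _embedding_cache[key] = table
    return table


@dataclass(frozen=True)
class PipelineConfig:
    window_days: int = 30
    seed: int = 0
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    n_topics: int = text_features.DEFAULT_N_TOPICS
    embed_dim: int = text_features.DEFAULT_EMBED_DIM
    embed_seed: int = 0       # the embedding table is a study-fixed input,
    rotate: bool = True       # decoupled from the run seed
    n_lambda: int = 50
    lambda_ratio: float = 1e-3
    bootstrap_B: int = 2000
    alpha: float = 0.05
    mood_missing_indicator: bool = False
    participant_level_auc: bool = False


@dataclass
class ModelingData:
    windows: list[ObservationWindow]
    participants: dict[str, ParticipantRecord]
    blocks: FeatureBlockSet
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray
    split: tuple[set[str], set[str], set[str]]
    topic_model: TopicModel
    embeddings: EmbeddingTable
    language_names: list[str] = field(default_factory=list)


def prepare_modeling_data(
    cohort: CohortData,
    config: PipelineConfig,
    valence: ValenceLexicon | None = None,
    themes: ThemeLexicon | None = None,
    embeddings: EmbeddingTable | None = None,
) -> ModelingData:
    """Windows, covariates, language features, blocks, and the
    participant-level split, with training-only fitting wherever a stage
    learns from data (topic model; later, standardization and the penalty)."""
    valence = valence or ValenceLexicon.default()
    themes = themes or ThemeLexicon.default()
    wconf = WindowConfig(window_days=config.window_days)

    entries = prepare_entries(cohort.texts, wconf)
    epds = sorted(cohort.epds, key=lambda r: (r.participant_id, r.day))
    windows = build_windows(entries, epds, wconf)

    moods_by_pid: dict[str, list] = {}
    for m in sorted(cohort.moods, key=lambda m: (m.participant_id, m.day)):
        moods_by_pid.setdefault(m.participant_id, []).append(m)
    symp_by_pid: dict[str, list] = {}
    for s in sorted(cohort.symptoms, key=lambda s: (s.participant_id, s.day)):
        symp_by_pid.setdefault(s.participant_id, []).append(s)

    # inclusion: >=1 usable windowed text (implied), >=1 mood report
    windows = [w for w in windows if w.participant_id in moods_by_pid]
    if not windows:
        raise ValueError("no modeling-eligible windows in cohort")
    windows = [
        attach_covariates(
            w,
            moods_by_pid[w.participant_id],
            symp_by_pid.get(w.participant_id, []),
            window_days=config.window_days,
        )
        for w in windows
    ]
    logger.info("windows after matching and inclusion: %d", len(windows))

    pids = {w.participant_id for w in windows}
    split = split_participants(
        pids,
        SplitConfig(config.train_frac, config.val_frac, config.test_frac,
                    seed=config.seed),
    )
    train_ids, val_ids, test_ids = split
    train_mask = np.array([w.participant_id in train_ids for w in windows])
    val_mask = np.array([w.participant_id in val_ids for w in windows])
    test_mask = np.array([w.participant_id in test_ids for w in windows])

    corpus_train = [w.tokens for w, m in zip(windows, train_mask) if m]
    topic_model = fit_topics(corpus_train, config.n_topics, seed=config.seed)

    if embeddings is None:
        embeddings = _default_embeddings(
            valence, themes, config.embed_dim, config.embed_seed,
            config.rotate)
    elif config.rotate:
        rot = rotate_embeddings(embeddings)
        embeddings = embeddings.with_matrix(rot.rotated)

    lang, lang_names = language_block(
        [w.tokens for w in windows], valence, themes, topic_model, embeddings)
    participants = {p.participant_id: p for p in cohort.participants}
    blocks = build_blocks(
        windows, participants, lang, lang_names,
        mood_missing_indicator=config.mood_missing_indicator)
    return ModelingData(
        windows=windows,
        participants=participants,
        blocks=blocks,
        train_mask=train_mask,
        val_mask=val_mask,
        test_mask=test_mask,
        split=split,
        topic_model=topic_model,
        embeddings=embeddings,
        language_names=lang_names,
    )


# ---------------------------------------------------------------------------
# The stepwise grid


@dataclass
class FitResult:
    spec: ModelSpec
    n_candidates: int
    n_selected: int
    selected: list[str]
    coefficients: np.ndarray
    summary: si_lasso.SelectiveSummary | None
    lam: float
    test_auc: float
    auc_ci: tuple[float, float]
    test_r2: float
    failed: bool = False
    failure: str | None = None


def _fit_and_evaluate(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    names: list[str],
    pids: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: PipelineConfig,
    bootstrap_seed: int,
) -> FitResult:
    tr, va, te = masks
    grid = si_lasso.lambda_grid(X[tr], y[tr], config.n_lambda,
                                config.lambda_ratio)
    lam, fit = si_lasso.select_lambda(X[tr], y[tr], X[va], y[va], grid)
    summary = None
    if fit.active_set.size:
        try:
            sigma = si_lasso.estimate_sigma(X[tr], y[tr], fit)
            if sigma > 0:
                summary = si_lasso.polyhedral_inference(
                    X[tr], y[tr], fit, sigma, alpha=config.alpha, names=names)
        except ValueError as exc:
            logger.warning("selective inference failed for %s: %s",
                           spec.label(), exc)
    scores = fit.predict(X[te])
    y_te, lab_te = y[te], labels[te]
    if config.participant_level_auc:
        agg = pd.DataFrame({"pid": pids[te], "s": scores, "l": lab_te,
                            "y": y_te})
        g = agg.groupby("pid").agg(s=("s", "mean"), l=("l", "max"),
                                   y=("y", "mean"))
        scores = g["s"].values
        lab_te = g["l"].values.astype(bool)
        y_te = g["y"].values
    try:
        a = auc(scores, lab_te)
        ci = auc_ci(scores, lab_te, B=config.bootstrap_B, seed=bootstrap_seed)
    except ValueError as exc:
        return FitResult(spec, X.shape[1], int(fit.active_set.size),
                         [names[i] for i in fit.active_set],
                         fit.coef, summary, lam, np.nan, (np.nan, np.nan),
                         np.nan, failed=True, failure=str(exc))
    return FitResult(
        spec=spec,
        n_candidates=X.shape[1],
        n_selected=int(fit.active_set.size),
        selected=[names[i] for i in fit.active_set],
        coefficients=fit.coef,
        summary=summary,
        lam=lam,
        test_auc=a,
        auc_ci=ci,
        test_r2=r_squared(y_te, scores),
    )


def fit_one_model(
    data: ModelingData,
    spec: ModelSpec,
    config: PipelineConfig,
    bootstrap_seed: int = 0,
) -> FitResult:
    X, y, labels, names = assemble(data.windows, spec, data.blocks)
    pids = np.array([w.participant_id for w in data.windows])
    return _fit_and_evaluate(
        spec, X, y, labels, names, pids,
        (data.train_mask, data.val_mask, data.test_mask),
        config, bootstrap_seed)


def run_stepwise(
    data: ModelingData, config: PipelineConfig
) -> list[FitResult]:
    """Fit all 15 block subsets; a failed model is logged and reported with
    zero retained covariates rather than aborting the run."""
    results = []
    for i, spec in enumerate(all_model_specs()):
        try:
            res = fit_one_model(data, spec, config,
                                bootstrap_seed=config.seed * 1000 + i)
        except Exception as exc:  # noqa: BLE001 - keep the grid running
            logger.exception("model %s failed", spec.label())
            res = FitResult(spec, data.blocks.width(spec), 0, [],
                            np.zeros(0), None, np.nan, 0.5, (0.5, 0.5),
                            0.0, failed=True, failure=str(exc))
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Flat-file path (CLI featurize -> fit)

META_COLUMNS = ("participant_id", "y", "label")
_PREFIX_TO_BLOCK = {"hist.": "history", "mood.": "mood", "symp.": "symptoms",
                    "lang.": "language"}


def features_frame(data: ModelingData) -> pd.DataFrame:
    """Flatten a prepared dataset into one row per window: meta columns
    (participant id, outcome, flag) then every block column."""
    full = all_model_specs()[-1]
    X, y, labels, names = assemble(data.windows, full, data.blocks)
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", labels)
    df.insert(0, "y", y)
    df.insert(0, "participant_id",
              [w.participant_id for w in data.windows])
    return df


def run_stepwise_frame(
    df: pd.DataFrame, config: PipelineConfig
) -> list[FitResult]:
    """Run the 15-model grid from a features table (see features_frame)."""
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    by_block: dict[str, list[str]] = {b: [] for b in _PREFIX_TO_BLOCK.values()}
    for c in feature_cols:
        for prefix, block in _PREFIX_TO_BLOCK.items():
            if c.startswith(prefix):
                by_block[block].append(c)
                break
        else:
            raise ValueError(f"feature column {c!r} has no block prefix")
    pids = df["participant_id"].to_numpy()
    split = split_participants(
        pids, SplitConfig(config.train_frac, config.val_frac,
                          config.test_frac, seed=config.seed))
    masks = tuple(np.isin(pids, sorted(s)) for s in split)
    y = df["y"].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=bool)
    results = []
    for i, spec in enumerate(all_model_specs()):
        names = [c for b in spec.ordered for c in by_block[b]]
        X = df[names].to_numpy(dtype=float)
        try:
            res = _fit_and_evaluate(spec, X, y, labels, names, pids, masks,
                                    config, config.seed * 1000 + i)
        except Exception as exc:  # noqa: BLE001
            logger.exception("model %s failed", spec.label())
            res = FitResult(spec, len(names), 0, [], np.zeros(0), None,
                            np.nan, 0.5, (0.5, 0.5), 0.0, failed=True,
                            failure=str(exc))
        results.append(res)
    return results


def results_table(results: list[FitResult]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results, start=1):
        rows.append(
            {
                "#": i,
                "Model description": r.spec.label(),
                "No. of covariates retained": f"{r.n_selected}/{r.n_candidates}",
                "Test set AUC value [CI]": (
                    f"{r.test_auc:.2f} [{r.auc_ci[0]:.2f}, {r.auc_ci[1]:.2f}]"
                    if np.isfinite(r.test_auc) else "failed"
                ),
                "Test set R2": f"{r.test_r2:.2f}" if np.isfinite(r.test_r2) else "",
            }
        )
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame) -> str:
    cols = list(table.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"
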