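"""Language feature families for windowed token lists.

Four families are extracted per observation window:

* sentiment — average positive and negative lexicon valence and their
  difference (the "fluctuation" of emotional content across the window);
* themes — proportions of tokens matching each category of a LIWC-style
  theme lexicon (119 categories by default, including the study-specific
  ``covid19`` and ``pregnancy_terms`` categories);
* topics — posterior topic proportions from a latent Dirichlet allocation
  model fit on the windowed corpus;
* embeddings — the mean word vector of in-vocabulary tokens, optionally
  after an orthogonal varimax-style rotation of the embedding table that
  concentrates mass into a few large entries per row and per column while
  preserving all pairwise geometry.

With the defaults (3 sentiment + 119 themes + 7 topics + 300 embedding
dimensions) the language block is 429 columns wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from ._stem import porter_stem

logger = logging.getLogger(__name__)

try:  # optional JIT for the rotation sweep
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_N_TOPICS = 7
DEFAULT_EMBED_DIM = 300


def _data_path(name: str) -> Path:
    return Path(str(resources.files("peridep").joinpath("data", name)))


# ---------------------------------------------------------------------------
# Sentiment


@dataclass(frozen=True)
class SentimentProfile:
    avg_pos: float
    avg_neg: float
    fluctuation: float


class ValenceLexicon:
    """Stem -> (positive, negative) valence scores, both in [0, 1]."""

    def __init__(self, scores: dict[str, tuple[float, float]]):
        for stem, (p, n) in scores.items():
            if not (0.0 <= p <= 1.0 and 0.0 <= n <= 1.0):
                raise ValueError(f"valence scores out of [0,1] for {stem!r}")
        self.scores = dict(scores)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, stem: str) -> bool:
        return stem in self.scores

    @classmethod
    def load(cls, path: str | Path, stem_keys: bool = True) -> "ValenceLexicon":
        """Read a ``word<TAB>pos<TAB>neg`` table. With ``stem_keys`` the words
        are Porter-stemmed on load and duplicate stems averaged, so the file
        may list surface forms."""
        acc: dict[str, list[tuple[float, float]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            word, pos, neg = line.split("\t")
            key = porter_stem(word.strip().lower()) if stem_keys else word.strip()
            acc.setdefault(key, []).append((float(pos), float(neg)))
        return cls(
            {
                k: (
                    sum(p for p, _ in v) / len(v),
                    sum(n for _, n in v) / len(v),
                )
                for k, v in acc.items()
            }
        )

    _default: "ValenceLexicon | None" = None

    @classmethod
    def default(cls) -> "ValenceLexicon":
        if cls._default is None:
            cls._default = cls.load(_data_path("valence_lexicon.tsv"))
        return cls._default


def sentiment_profile(
    tokens: Sequence[str],
    lexicon: ValenceLexicon,
    all_token_denominator: bool = True,
) -> SentimentProfile:
    """Average positive/negative valence over a window's tokens.

    Out-of-lexicon tokens contribute (0, 0) with the denominator counting
    every token; set ``all_token_denominator=False`` to average over lexicon
    hits only. Empty input yields the all-zero profile.
    """
    if not tokens:
        logger.warning("sentiment_profile called on an empty token list")
        return SentimentProfile(0.0, 0.0, 0.0)
    pos = neg = 0.0
    hits = 0
    for t in tokens:
        sc = lexicon.scores.get(t)
        if sc is not None:
            pos += sc[0]
            neg += sc[1]
            hits += 1
    denom = len(tokens) if all_token_denominator else max(hits, 1)
    avg_pos, avg_neg = pos / denom, neg / denom
    return SentimentProfile(avg_pos, avg_neg, avg_pos - avg_neg)


# ---------------------------------------------------------------------------
# Themes


class ThemeLexicon:
    """Ordered list of (theme name, pattern set).

    A pattern is either an exact stem or a prefix written with a trailing
    ``*``. A token may match any number of themes.
    """

    def __init__(self, themes: Sequence[tuple[str, Sequence[str]]]):
        if not themes:
            raise ValueError("theme lexicon must be non-empty")
        names = [n for n, _ in themes]
        if len(set(names)) != len(names):
            raise ValueError("theme names must be unique")
        self.names: list[str] = names
        self._exact: list[frozenset[str]] = []
        self._prefixes: list[tuple[str, ...]] = []
        self._token_cache: dict[str, np.ndarray] = {}
        for _, patterns in themes:
            ex, pre = set(), []
            for p in patterns:
                p = p.strip()
                if not p:
                    continue
                if p.endswith("*"):
                    pre.append(p[:-1])
                else:
                    ex.add(p)
            self._exact.append(frozenset(ex))
            self._prefixes.append(tuple(pre))

    def __len__(self) -> int:
        return len(self.names)

    def matches(self, token: str, i: int) -> bool:
        return token in self._exact[i] or any(
            token.startswith(p) for p in self._prefixes[i]
        )

    def themes_of(self, token: str) -> list[str]:
        return [n for i, n in enumerate(self.names) if self.matches(token, i)]

    def indicator(self, token: str) -> np.ndarray:
        """0/1 vector of theme membership for one token (memoized)."""
        vec = self._token_cache.get(token)
        if vec is None:
            vec = np.array(
                [float(self.matches(token, i)) for i in range(len(self))])
            self._token_cache[token] = vec
        return vec

    @classmethod
    def load(cls, path: str | Path) -> "ThemeLexicon":
        themes = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, patterns = line.split("\t")
            themes.append((name.strip(), [p.strip() for p in patterns.split(",")]))
        return cls(themes)

    _default: "ThemeLexicon | None" = None

    @classmethod
    def default(cls) -> "ThemeLexicon":
        if cls._default is None:
            cls._default = cls.load(_data_path("theme_lexicon.tsv"))
        return cls._default


def theme_counts(tokens: Sequence[str], lexicon: ThemeLexicon) -> np.ndarray:
    counts = np.zeros(len(lexicon), dtype=float)
    for t in tokens:
        counts += lexicon.indicator(t)
    return counts


def theme_profile(
    tokens: Sequence[str], lexicon: ThemeLexicon, proportions: bool = True
) -> np.ndarray:
    """Per-theme token-match counts, divided by token count by default."""
    counts = theme_counts(tokens, lexicon)
    if proportions and tokens:
        counts /= len(tokens)
    return counts


# ---------------------------------------------------------------------------
# Topics (LDA)


@dataclass
class TopicModel:
    k: int
    topic_word: np.ndarray  # (k, V), rows sum to 1
    vocabulary: dict[str, int]
    seed: int
    _lda: LatentDirichletAllocation = field(repr=False, default=None)

    def __post_init__(self) -> None:
        row_sums = self.topic_word.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError("topic-word rows must sum to 1")


def _doc_term(
    corpus: Iterable[Sequence[str]], vocabulary: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    n_docs = 0
    for i, doc in enumerate(corpus):
        n_docs = i + 1
        seen: dict[int, int] = {}
        for t in doc:
            j = vocabulary.get(t)
            if j is not None:
                seen[j] = seen.get(j, 0) + 1
        for j, c in seen.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_docs, len(vocabulary)), dtype=float
    )


def fit_topics(
    corpus: Sequence[Sequence[str]], k: int, seed: int = 0
) -> TopicModel:
    """Fit a k-topic LDA on tokenized documents (seeded variational fit)."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    vocab_words = sorted({t for doc in corpus for t in doc})
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(vocab_words):
        raise ValueError(
            f"k={k} exceeds vocabulary size {len(vocab_words)}"
        )
    vocabulary = {w: j for j, w in enumerate(vocab_words)}
    X = _doc_term(corpus, vocabulary)
    lda = LatentDirichletAllocation(
        n_components=k, random_state=seed, learning_method="batch"
    )
    lda.fit(X)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(k=k, topic_word=topic_word, vocabulary=vocabulary,
                      seed=seed, _lda=lda)


def topic_profile(tokens: Sequence[str], model: TopicModel) -> np.ndarray:
    """Posterior topic proportions for one document (sums to 1)."""
    return topic_profiles([tokens], model)[0]


def topic_profiles(
    corpus: Sequence[Sequence[str]], model: TopicModel
) -> np.ndarray:
    """Posterior topic proportions for a batch of documents."""
    X = _doc_term(corpus, model.vocabulary)
    theta = model._lda.transform(X)
    return theta / theta.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Embeddings


class EmbeddingTable:
    """word -> d-dimensional vector, word2vec text format on disk."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table must be non-empty")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError("all embedding vectors must share one dimension")
        self.dim = dims.pop()
        self.words: list[str] = list(vectors)
        self.matrix = np.asarray([vectors[w] for w in self.words], dtype=float)
        self._index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self._index[word]]

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        lines = Path(path).read_text().splitlines()
        n, d = (int(x) for x in lines[0].split())
        vectors: dict[str, np.ndarray] = {}
        for line in lines[1 : n + 1]:
            parts = line.rstrip().split(" ")
            vectors[parts[0]] = np.asarray([float(x) for x in parts[1 : d + 1]])
        return cls(vectors)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, row in zip(self.words, self.matrix):
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in row) + "\n")

    def with_matrix(self, matrix: np.ndarray) -> "EmbeddingTable":
        return EmbeddingTable(
            {w: matrix[i] for i, w in enumerate(self.words)}
        )


def embed_window(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Mean vector of in-vocabulary tokens; zero vector when all are OOV."""
    vecs = [table.vector(t) for t in tokens if t in table]
    if not vecs:
        logger.warning("embed_window: no in-vocabulary token; zero vector")
        return np.zeros(table.dim)
    return np.mean(vecs, axis=0)


# ---------------------------------------------------------------------------
# Rotation


@dataclass
class RotationResult:
    rotation: np.ndarray          # (d, d) orthogonal
    rotated: np.ndarray           # (n, d) = E @ rotation
    criterion_trace: list[float]
    converged: bool


def _varimax_criterion(L: np.ndarray) -> float:
    n = L.shape[0]
    sq = L**2
    return float((L**4).sum() - (sq.sum(axis=0) ** 2).sum() / n)


def _varimax_pair_sweep(L, R, n):
    """One sweep of closed-form planar rotations over all column pairs;
    rotates L and accumulates into R in place."""
    d = L.shape[1]
    for p in range(d - 1):
        for q in range(p + 1, d):
            x = L[:, p].copy()
            y = L[:, q].copy()
            u = x**2 - y**2
            v = 2.0 * x * y
            A = u.sum()
            B = v.sum()
            C = (u**2 - v**2).sum()
            D = 2.0 * (u * v).sum()
            num = D - 2.0 * A * B / n
            den = C - (A**2 - B**2) / n
            phi = 0.25 * np.arctan2(num, den)
            if abs(phi) < 1e-12:
                continue
            c, s = np.cos(phi), np.sin(phi)
            L[:, p] = c * x + s * y
            L[:, q] = -s * x + c * y
            rp = R[:, p].copy()
            rq = R[:, q].copy()
            R[:, p] = c * rp + s * rq
            R[:, q] = -s * rp + c * rq


if _HAVE_NUMBA:
    _varimax_pair_sweep_jit = _njit(cache=False)(_varimax_pair_sweep)
else:  # pragma: no cover
    _varimax_pair_sweep_jit = _varimax_pair_sweep


def rotate_embeddings(
    table: EmbeddingTable | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    kaiser: bool = True,
) -> RotationResult:
    """Orthogonal rotation concentrating the embedding matrix into a few
    large values per row and per column.

    Maximizes the (Kaiser row-normalized) varimax criterion by sweeps of
    pairwise planar rotations; each planar step is the closed-form optimum
    for its column pair, so the criterion is non-decreasing. Right-
    multiplication by an orthogonal matrix leaves every pairwise inner
    product of word vectors unchanged.
    """
    E = table.matrix if isinstance(table, EmbeddingTable) else np.asarray(table)
    if E.shape[0] < 2:
        raise ValueError("need at least two vocabulary rows to rotate")
    n, d = E.shape

    if kaiser:
        norms = np.linalg.norm(E, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        L = E / norms
    else:
        L = E.copy()
    L = np.ascontiguousarray(L)
    R = np.eye(d)
    trace = [_varimax_criterion(L)]
    converged = False
    for _ in range(max_iter):
        _varimax_pair_sweep_jit(L, R, float(n))
        trace.append(_varimax_criterion(L))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("rotation did not converge within max_iter=%d", max_iter)
    return RotationResult(
        rotation=R, rotated=E @ R, criterion_trace=trace, converged=converged
    )


# ---------------------------------------------------------------------------
# Assembled language block


def language_block(
    token_lists: Sequence[Sequence[str]],
    valence: ValenceLexicon,
    themes: ThemeLexicon,
    topics: TopicModel,
    embeddings: EmbeddingTable,
) -> tuple[np.ndarray, list[str]]:
    """Stack the four language families into one matrix with namespaced
    column names (``lang.sent.*``, ``lang.theme.*``, ``lang.lda.*``,
    ``lang.emb.*``)."""
    theta = topic_profiles(token_lists, topics)
    rows = []
    for toks, th in zip(token_lists, theta):
        sent = sentiment_profile(toks, valence)
        rows.append(
            np.concatenate(
                [
                    [sent.avg_pos, sent.avg_neg, sent.fluctuation],
                    theme_profile(toks, themes),
                    th,
                    embed_window(toks, embeddings),
                ]
            )
        )
    names = (
        ["lang.sent.avg_pos", "lang.sent.avg_neg", "lang.sent.fluct"]
        + [f"lang.theme.{n}" for n in themes.names]
        + [f"lang.lda.{i}" for i in range(topics.k)]
        + [f"lang.emb.r{i:03d}" for i in range(embeddings.dim)]
    )
    return np.asarray(rows), names
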