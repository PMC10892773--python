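"""Symbolic bag construction: per-activity k-means codebooks, per-subject
chronological word documents, topic-model fitting, and fused bag vectors.

Each window becomes a word qualified by its activity (cluster 2 of activity
3 is a different word from cluster 2 of activity 5); a subject's document is
the chronological word sequence across in-scope activities; the bag vector
concatenates the word-count histogram with the document-topic posterior.
Fitting happens strictly on training-fold subjects; transforming held-out
subjects never touches fitted parameters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import psi
from sklearn.cluster import KMeans
from sklearn.decomposition import LatentDirichletAllocation

from pdseverity.features import WindowFeature

logger = logging.getLogger(__name__)

DEFAULT_K = 8
DEFAULT_T = 4
DEFAULT_BETA = 0.01
LDA_MAX_ITER = 60


class CodebookError(ValueError):
    """Raised when codebook fitting or lookup is impossible."""


@dataclass(frozen=True)
class Word:
    """An (activity, cluster) symbol with its position in the global vocabulary."""

    activity_id: int
    cluster_id: int
    global_word_id: int


@dataclass
class Document:
    """A subject's chronological word sequence — the MIL bag in symbol space."""

    subject_id: str
    words: List[Word]
    label: Optional[int] = None
    parents: Tuple[str, ...] = ()  # non-empty for augmentation-synthesized bags

    def __len__(self) -> int:
        return len(self.words)

    def word_ids(self) -> List[int]:
        return [w.global_word_id for w in self.words]

    def activity_blocks(self) -> Dict[int, List[Word]]:
        """Words grouped by activity, preserving chronological order."""
        blocks: Dict[int, List[Word]] = {}
        for w in self.words:
            blocks.setdefault(w.activity_id, []).append(w)
        return blocks


@dataclass
class ActivityCodebook:
    activity_id: int
    k: int
    centroids: np.ndarray  # (k, n_features), in standardized space
    fit_subject_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise CodebookError(f"k must be >= 2, got {self.k}")
        if not np.all(np.isfinite(self.centroids)):
            raise CodebookError("non-finite centroids")


@dataclass
class BagVector:
    """Fused per-subject classifier input: [word counts || topic posterior]."""

    subject_id: str
    counts: np.ndarray
    topics: Optional[np.ndarray]
    fused: np.ndarray
    label: Optional[int] = None


@dataclass
class Standardizer:
    """Per-dimension z-score fitted on training windows only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Standardizer":
        std = matrix.std(axis=0)
        std = np.where(std == 0.0, 1.0, std)
        return cls(mean=matrix.mean(axis=0), std=std)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.std


def group_by_subject(
    features: Iterable[WindowFeature],
) -> Dict[str, List[WindowFeature]]:
    grouped: Dict[str, List[WindowFeature]] = {}
    for f in features:
        grouped.setdefault(f.subject_id, []).append(f)
    return grouped


def fit_activity_codebooks(
    features: Sequence[WindowFeature],
    k: int,
    seed: int,
    subjects: Sequence[str],
    activities: Optional[Sequence[int]] = None,
    n_init: int = 10,
) -> Tuple[Dict[int, ActivityCodebook], Standardizer]:
    """Fit one k-means codebook per activity on training subjects' windows.

    Features are standardized (z-score per dimension over the pooled
    training windows); standardization parameters are returned for
    transform-time use on held-out subjects.
    """
    if k < 2:
        raise CodebookError(f"k must be >= 2, got {k}")
    subjects = set(subjects)
    train = [f for f in features if f.subject_id in subjects]
    if not train:
        raise CodebookError("no training windows for the requested subjects")
    if activities is None:
        activities = sorted({f.activity_id for f in train})
    matrix = np.stack([f.vector for f in train])
    standardizer = Standardizer.fit(matrix)

    codebooks: Dict[int, ActivityCodebook] = {}
    for activity_id in sorted(activities):
        rows = [f for f in train if f.activity_id == activity_id]
        if len(rows) < k:
            raise CodebookError(
                f"activity {activity_id} has only {len(rows)} training windows; "
                f"need at least k={k}"
            )
        x = standardizer.transform(np.stack([f.vector for f in rows]))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + activity_id)
        km.fit(x)
        codebooks[activity_id] = ActivityCodebook(
            activity_id=activity_id,
            k=k,
            centroids=km.cluster_centers_,
            fit_subject_ids=tuple(sorted({f.subject_id for f in rows})),
        )
    return codebooks, standardizer


def _activity_rank(activities: Sequence[int]) -> Dict[int, int]:
    return {a: r for r, a in enumerate(sorted(activities))}


def build_document(
    subject_features: Sequence[WindowFeature],
    codebooks: Mapping[int, ActivityCodebook],
    standardizer: Standardizer,
    label: Optional[int] = None,
) -> Document:
    """Map a subject's windows to words and order them chronologically.

    Nearest centroid by Euclidean distance in the codebooks' standardized
    space; ties go to the lowest cluster id.  Works for subjects unseen at
    fit time.  Activities with no windows simply contribute no words.
    """
    if not subject_features:
        return Document(subject_id="", words=[], label=label)
    subject_id = subject_features[0].subject_id
    ranks = _activity_rank(list(codebooks.keys()))
    k = next(iter(codebooks.values())).k

    words: List[Word] = []
    ordered = sorted(
        subject_features, key=lambda f: (ranks.get(f.activity_id, -1), f.window_index)
    )
    for f in ordered:
        if f.activity_id not in codebooks:
            raise CodebookError(
                f"no codebook for activity {f.activity_id} "
                f"(subject {f.subject_id})"
            )
        cb = codebooks[f.activity_id]
        x = standardizer.transform(f.vector[None])
        distances = cdist(x, cb.centroids)[0]
        cluster = int(np.argmin(distances))  # argmin -> lowest id on ties
        words.append(
            Word(
                activity_id=f.activity_id,
                cluster_id=cluster,
                global_word_id=ranks[f.activity_id] * k + cluster,
            )
        )
    present = {w.activity_id for w in words}
    missing = set(codebooks.keys()) - present
    if missing:
        logger.info(
            "subject %s has no windows for activities %s", subject_id, sorted(missing)
        )
    return Document(subject_id=subject_id, words=words, label=label)


def word_count_vector(document: Document, vocabulary_size: int) -> np.ndarray:
    """Integer word-count histogram over the global vocabulary."""
    counts = np.zeros(vocabulary_size, dtype=int)
    for w in document.words:
        if not 0 <= w.global_word_id < vocabulary_size:
            raise ValueError(
                f"word id {w.global_word_id} outside vocabulary of size "
                f"{vocabulary_size}"
            )
        counts[w.global_word_id] += 1
    return counts


def fit_topic_model(
    doc_word_matrix: np.ndarray,
    t: int,
    seed: int,
    alpha: Optional[float] = None,
    beta: float = DEFAULT_BETA,
    max_iter: int = LDA_MAX_ITER,
) -> LatentDirichletAllocation:
    """Fit a t-topic LDA with symmetric Dirichlet priors (variational EM)."""
    if t < 2:
        raise ValueError(f"topic count t must be >= 2, got {t}")
    doc_word_matrix = np.asarray(doc_word_matrix)
    if doc_word_matrix.shape[0] < t:
        raise ValueError(
            f"need at least t={t} training documents, got {doc_word_matrix.shape[0]}"
        )
    if np.any(doc_word_matrix < 0):
        raise ValueError("document-word matrix must be non-negative")
    model = LatentDirichletAllocation(
        n_components=t,
        doc_topic_prior=alpha if alpha is not None else 1.0 / t,
        topic_word_prior=beta,
        max_iter=max_iter,
        random_state=seed,
    )
    model.fit(doc_word_matrix)
    return model


def topic_vector(model: LatentDirichletAllocation, counts: np.ndarray) -> np.ndarray:
    """Posterior document-topic distribution for one count vector.

    All-zero documents get the uniform distribution with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    t = model.n_components
    if counts.sum() == 0:
        warnings.warn("all-zero document; returning uniform topic vector", stacklevel=2)
        return np.full(t, 1.0 / t)
    theta = model.transform(counts[None])[0]
    return theta / theta.sum()


def fuse_bag_vector(
    counts: np.ndarray,
    topics: Optional[np.ndarray],
    counts_norm: str = "raw",
) -> np.ndarray:
    """Horizontally bind the count histogram and the topic posterior.

    ``topics=None`` (the counts-only ablation) emits the histogram alone.
    """
    counts = np.asarray(counts, dtype=float)
    if counts_norm == "relative":
        total = counts.sum()
        counts = counts / total if total > 0 else counts
    elif counts_norm != "raw":
        raise ValueError(f"counts_norm must be 'raw' or 'relative', got {counts_norm!r}")
    if topics is None:
        return counts
    return np.concatenate([counts, np.asarray(topics, dtype=float)])


class BagModel:
    """Fitted bundle: standardizer + per-activity codebooks + topic model.

    ``fit`` sees only the given training subjects; ``transform`` is pure and
    applies to any subject, seen or unseen.
    """

    def __init__(
        self,
        k: int = DEFAULT_K,
        t: int = DEFAULT_T,
        seed: int = 0,
        use_lda: bool = True,
        counts_norm: str = "raw",
        alpha: Optional[float] = None,
        beta: float = DEFAULT_BETA,
        kmeans_restarts: int = 10,
    ) -> None:
        self.k = k
        self.t = t
        self.seed = seed
        self.use_lda = use_lda
        self.counts_norm = counts_norm
        self.alpha = alpha
        self.beta = beta
        self.kmeans_restarts = kmeans_restarts
        self.codebooks: Dict[int, ActivityCodebook] = {}
        self.standardizer: Optional[Standardizer] = None
        self.topic_model: Optional[LatentDirichletAllocation] = None
        self.activities: Tuple[int, ...] = ()

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        features: Sequence[WindowFeature],
        labels: Mapping[str, int],
        subjects: Sequence[str],
        activities: Optional[Sequence[int]] = None,
    ) -> "BagModel":
        self.codebooks, self.standardizer = fit_activity_codebooks(
            features,
            k=self.k,
            seed=self.seed,
            subjects=subjects,
            activities=activities,
            n_init=self.kmeans_restarts,
        )
        self.activities = tuple(sorted(self.codebooks.keys()))
        if self.use_lda:
            grouped = group_by_subject(
                [f for f in features if f.subject_id in set(subjects)]
            )
            matrix = np.stack(
                [
                    word_count_vector(
                        build_document(
                            grouped[s], self.codebooks, self.standardizer,
                            label=labels.get(s),
                        ),
                        self.vocabulary_size,
                    )
                    for s in sorted(grouped)
                ]
            )
            self.topic_model = fit_topic_model(
                matrix, t=self.t, seed=self.seed, alpha=self.alpha, beta=self.beta
            )
        return self

    @property
    def vocabulary_size(self) -> int:
        return len(self.activities) * self.k

    # -- transforming -----------------------------------------------------

    def document(
        self, subject_features: Sequence[WindowFeature], label: Optional[int] = None
    ) -> Document:
        self._check_fitted()
        return build_document(
            subject_features, self.codebooks, self.standardizer, label=label
        )

    def vector_from_document(self, document: Document) -> BagVector:
        self._check_fitted()
        counts = word_count_vector(document, self.vocabulary_size)
        topics = None
        if self.use_lda:
            topics = topic_vector(self.topic_model, counts)
        fused = fuse_bag_vector(counts, topics, counts_norm=self.counts_norm)
        return BagVector(
            subject_id=document.subject_id,
            counts=counts,
            topics=topics,
            fused=fused,
            label=document.label,
        )

    def transform(
        self,
        features: Sequence[WindowFeature],
        labels: Mapping[str, int],
        subjects: Optional[Sequence[str]] = None,
    ) -> List[BagVector]:
        grouped = group_by_subject(features)
        if subjects is None:
            subjects = sorted(grouped)
        return [
            self.vector_from_document(
                self.document(grouped.get(s, []), label=labels.get(s))
            )
            for s in subjects
        ]

    def _check_fitted(self) -> None:
        if self.standardizer is None or not self.codebooks:
            raise RuntimeError("BagModel is not fitted")
        if self.use_lda and self.topic_model is None:
            raise RuntimeError("BagModel is not fitted (missing topic model)")

    # -- serialization ----------------------------------------------------

    def save(self, directory) -> Path:
        """Serialize the fitted bundle as plain-text files in a directory."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "k": self.k,
            "t": self.t,
            "seed": self.seed,
            "use_lda": self.use_lda,
            "counts_norm": self.counts_norm,
            "alpha": self.alpha,
            "beta": self.beta,
            "kmeans_restarts": self.kmeans_restarts,
            "activities": list(self.activities),
            "codebooks": {
                str(a): {"fit_subject_ids": list(cb.fit_subject_ids)}
                for a, cb in self.codebooks.items()
            },
        }
        (directory / "config.json").write_text(json.dumps(config, indent=1))
        np.savetxt(directory / "standardizer_mean.txt", self.standardizer.mean)
        np.savetxt(directory / "standardizer_std.txt", self.standardizer.std)
        for a, cb in self.codebooks.items():
            np.savetxt(directory / f"codebook_{a}.txt", cb.centroids)
        if self.use_lda:
            np.savetxt(directory / "topic_components.txt", self.topic_model.components_)
        return directory

    @classmethod
    def load(cls, directory) -> "BagModel":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        model = cls(
            k=config["k"],
            t=config["t"],
            seed=config["seed"],
            use_lda=config["use_lda"],
            counts_norm=config["counts_norm"],
            alpha=config["alpha"],
            beta=config["beta"],
            kmeans_restarts=config["kmeans_restarts"],
        )
        model.activities = tuple(config["activities"])
        model.standardizer = Standardizer(
            mean=np.loadtxt(directory / "standardizer_mean.txt"),
            std=np.loadtxt(directory / "standardizer_std.txt"),
        )
        for a in model.activities:
            centroids = np.loadtxt(directory / f"codebook_{a}.txt")
            model.codebooks[a] = ActivityCodebook(
                activity_id=a,
                k=config["k"],
                centroids=np.atleast_2d(centroids),
                fit_subject_ids=tuple(
                    config["codebooks"][str(a)]["fit_subject_ids"]
                ),
            )
        if model.use_lda:
            components = np.atleast_2d(np.loadtxt(directory / "topic_components.txt"))
            lda = LatentDirichletAllocation(
                n_components=config["t"],
                doc_topic_prior=(
                    config["alpha"] if config["alpha"] is not None else 1.0 / config["t"]
                ),
                topic_word_prior=config["beta"],
                random_state=config["seed"],
            )
            lda.components_ = components
            lda.exp_dirichlet_component_ = np.exp(
                psi(components) - psi(components.sum(axis=1))[:, None]
            )
            lda.doc_topic_prior_ = lda.doc_topic_prior
            lda.topic_word_prior_ = lda.topic_word_prior
            lda.n_features_in_ = components.shape[1]
            lda.n_iter_ = 0
            model.topic_model = lda
        return model


def export_documents(documents: Sequence[Document], path) -> Path:
    """Whitespace-separated word ids, one subject per line, for inspection."""
    path = Path(path)
    lines = [
        f"{d.subject_id}\t" + " ".join(str(i) for i in d.word_ids())
        for d in documents
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
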