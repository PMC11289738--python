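"""Task primitives shared by the link- and attribute-prediction pipelines.

The scoring chain for link prediction is: node embeddings Z -> hyperedge
embedding r_e by average readout over the reaction's member nodes -> per-node
connection probability phi[v] = sigmoid(r_e . z_v) -> ranked candidate list
with known members excluded.  Attribute prediction replaces the readout/dot
product with a linear classifier m_v = sigmoid(W z_v + b) over attributes.

Training loops live in :mod:`pathpred.estimators`; the module-level
``train_*`` / ``predict_*`` functions there remain thin wrappers around the
estimator classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import sigmoid

PROB_EPS = 1e-12  # probabilities are clamped to [eps, 1-eps] before logs


def readout(Z: np.ndarray, members: Sequence[int]) -> np.ndarray:
    """Average readout: mean of the member rows of Z.

    An empty member set returns the zero vector, which makes every
    downstream sigmoid score 0.5; this convention anchors the empty
    coalition of the Shapley explainer.
    """
    members = list(members)
    if not members:
        return np.zeros(Z.shape[1], dtype=np.float64)
    return np.asarray(Z[members].mean(axis=0), dtype=np.float64)


def readout_matrix(columns: "np.ndarray", fallback: "np.ndarray | None" = None
                   ) -> np.ndarray:
    """Row-normalised membership matrix M (|E|x|V|) such that M @ Z yields
    all hyperedge readouts at once.

    ``columns`` is a dense |V|x|E| indicator (e.g. H_s for the input task).
    Reactions whose column is empty fall back to the rows of ``fallback``
    (e.g. the full H) when given; a reaction empty in both gets a zero row.
    """
    M = np.asarray(columns, dtype=np.float64).T.copy()
    if fallback is not None:
        empty = M.sum(axis=1) == 0
        M[empty] = np.asarray(fallback, dtype=np.float64).T[empty]
    counts = M.sum(axis=1)
    nz = counts > 0
    M[nz] /= counts[nz, None]
    return M


def score_links(r_e: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """phi[v] = sigmoid(r_e . z_v): connection probability per node."""
    return sigmoid(Z @ np.asarray(r_e, dtype=np.float64))


@dataclass(frozen=True)
class RankingResult:
    """Ordered candidate list for one query, known positives excluded.

    Scores are non-increasing; ties are broken by ascending candidate index
    (declaration order), so rankings are deterministic.
    """

    query_id: str
    candidate_ids: tuple[str, ...]
    scores: tuple[float, ...]
    k: int
    excluded_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.candidate_ids)

    def rank_of(self, candidate_id: str) -> int | None:
        """1-based rank of a candidate, or None if not in the list."""
        try:
            return self.candidate_ids.index(candidate_id) + 1
        except ValueError:
            return None


def rank_candidates(
    query_id: str,
    ids: Sequence[str],
    scores: np.ndarray,
    excluded: Sequence[str] = (),
    k: int = 10,
) -> RankingResult:
    """Sort candidates by score (descending, ties by ascending index).

    ``ids`` and ``scores`` are aligned with the network's declaration order.
    Excluded ids (known positives) are removed before ranking; if k exceeds
    the candidate pool the full pool is returned unpadded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=np.float64)
    if len(ids) != scores.shape[0]:
        raise ValueError("ids and scores length mismatch")
    excluded = frozenset(excluded)
    keep = np.array([i for i, cid in enumerate(ids) if cid not in excluded],
                    dtype=np.int64)
    # stable sort on -score keeps ascending original index among ties
    order = keep[np.argsort(-scores[keep], kind="stable")][:k]
    return RankingResult(
        query_id=query_id,
        candidate_ids=tuple(ids[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        k=k,
        excluded_ids=excluded,
    )


def cross_entropy_loss(predicted: np.ndarray, labels: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Mean elementwise binary cross-entropy.

    The targets here are binary incidence/assignment cells (multi-label
    columns, not one-hot distributions), so generic cross-entropy
    instantiates as -[y log q + (1-y) log(1-q)] averaged over cells.
    Predictions are clamped to [1e-12, 1-1e-12] before the logs.  An
    optional binary ``mask`` restricts the mean to a subset of cells
    (used to keep held-out assignment cells out of the attribute loss).
    """
    q = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if q.shape != y.shape:
        raise ValueError(f"shape mismatch: {q.shape} vs {y.shape}")
    q = np.clip(q, PROB_EPS, 1.0 - PROB_EPS)
    cell = -(y * np.log(q) + (1.0 - y) * np.log1p(-q))
    if mask is None:
        return float(cell.mean())
    mask = np.asarray(mask, dtype=np.float64)
    total = mask.sum()
    if total == 0:
        raise ValueError("empty loss mask")
    return float((cell * mask).sum() / total)


@dataclass
class TrainConfig:
    """Hyperparameters for one training run.

    Defaults follow the benchmarked settings: embedding dimension from
    {64, 128, 256} (default 128), learning rate from {0.05, 0.01, 0.005}
    (default 5e-3), 200 epochs of Adam; the entry-minibatch size applies to
    the MF link models only.
    """

    model: str = "hgnn"
    task: str = "input_link"
    embedding_dim: int = 128
    learning_rate: float = 5e-3
    epochs: int = 200
    n_layers: int = 2
    batch_size: int = 128
    train_edge_weights: bool = True
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("hgnn", "hgnn_plus", "gcn", "mf"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.task not in ("input_link", "output_link", "attribute"):
            raise ValueError(f"unknown task: {self.task!r}")
        for name in ("embedding_dim", "epochs", "n_layers", "batch_size"):
            if getattr(self, name) < 0 or (name != "epochs" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def direction(self) -> str:
        if self.task == "input_link":
            return "input"
        if self.task == "output_link":
            return "output"
        raise ValueError("attribute task has no link direction")
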