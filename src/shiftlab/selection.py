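"""Information-theoretic representative-sample selection.

Each tile's latent feature vector is mapped to a probability distribution
over the feature domain (softmax row normalization); a candidate subset S of
the full tile set X is summarized by the mean distribution of its member
tiles, and its representativeness is the Kullback-Leibler divergence of that
summary from the whole-dataset distribution, weighted by |X|/|S| so that,
under minimization, subsets contributing many tiles are preferred. The
greedy search grows the selected set one sample at a time, at each step
adding the sample whose union with the current selection minimizes the
weighted divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .datatypes import InvalidSpecError
from .representation import FeatureTable


@dataclass
class ProbabilityTable:
    """Tiles x features table of per-tile distributions over the feature domain.

    Row i is P(A | T = x_i): the conditional distribution of the feature
    random variable A given that the tile random variable T picked tile x_i.
    """

    probs: np.ndarray
    sample_ids: np.ndarray
    tile_ids: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidSpecError("rows must sum to 1")
        if np.any(p <= 0):
            raise InvalidSpecError("entries must be strictly positive")
        self.probs = p

    @property
    def n_tiles(self) -> int:
        return self.probs.shape[0]

    def rows_of(self, sample_id) -> np.ndarray:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if idx.size == 0:
            raise InvalidSpecError(f"unknown sample {sample_id!r}")
        return idx


@dataclass
class SelectionResult:
    """Greedy selection sequence with per-step weighted-KL scores."""

    order: List[str]
    scores: List[float]
    subset_sizes: Dict[str, int]
    n_total: int
    per_step_candidates: List[Dict[str, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "scores": self.scores,
                "subset_sizes": self.subset_sizes,
                "n_total": self.n_total,
                "per_step_candidates": self.per_step_candidates,
            },
            indent=2,
        )


def normalize_rows(table: FeatureTable, method: str = "softmax") -> ProbabilityTable:
    """Map each (signed) feature row onto the probability simplex.

    ``softmax`` exponentiates then normalizes (order-preserving, strictly
    positive); ``shift`` subtracts the row minimum, adds a small epsilon and
    renormalizes.
    """
    x = np.asarray(table.features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidSpecError("feature table contains non-finite entries")
    if method == "softmax":
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
    elif method == "shift":
        z = x - x.min(axis=1, keepdims=True) + 1e-6
        p = z / z.sum(axis=1, keepdims=True)
    else:
        raise InvalidSpecError(f"unknown normalization {method!r}")
    return ProbabilityTable(probs=p, sample_ids=np.asarray(table.sample_ids),
                            tile_ids=np.asarray(table.tile_ids))


def subset_distribution(table: ProbabilityTable, subset) -> np.ndarray:
    """P(A|S) = mean of member rows; ``subset`` is a sample id or index array."""
    if isinstance(subset, (str, np.str_)):
        idx = table.rows_of(subset)
    else:
        idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise InvalidSpecError("empty subset has no distribution")
    return table.probs[idx].mean(axis=0)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats; terms with p == 0 contribute 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InvalidSpecError("p and q must have the same length")
    if np.any(q[p > 0] <= 0):
        raise InvalidSpecError("q has zero mass where p > 0")
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def representativeness_score(table: ProbabilityTable, subset_idx: np.ndarray,
                             full_dist: np.ndarray | None = None) -> float:
    """Size-weighted divergence (|X|/|S|) * KL(P(A|S) || P(A|X)).

    Lower is more representative; at equal divergence a larger subset scores
    lower, prioritizing subsets that contribute many tiles.
    """
    idx = np.asarray(subset_idx, dtype=int)
    if idx.size == 0:
        raise InvalidSpecError("empty subset cannot be scored")
    if full_dist is None:
        full_dist = table.probs.mean(axis=0)
    p_s = table.probs[idx].mean(axis=0)
    return (table.n_tiles / idx.size) * kl_divergence(p_s, full_dist)


def select_representative_sequence(table: ProbabilityTable, k: int) -> SelectionResult:
    """Greedy sample sequence: step j adds the sample minimizing the weighted
    KL of (already selected + candidate); ties break on the smaller sample id."""
    sample_order = sorted({str(s) for s in table.sample_ids})
    if not 1 <= k <= len(sample_order):
        raise InvalidSpecError(f"k={k} out of range 1..{len(sample_order)}")
    full_dist = table.probs.mean(axis=0)
    sizes = {s: int(table.rows_of(s).size) for s in sample_order}

    chosen: List[str] = []
    chosen_idx = np.empty(0, dtype=int)
    scores: List[float] = []
    per_step: List[Dict[str, float]] = []
    for _ in range(k):
        step_scores: Dict[str, float] = {}
        for s in sample_order:
            if s in chosen:
                continue
            idx = np.concatenate([chosen_idx, table.rows_of(s)])
            step_scores[s] = representativeness_score(table, idx, full_dist)
        best = min(step_scores, key=lambda s: (step_scores[s], s))
        chosen.append(best)
        chosen_idx = np.concatenate([chosen_idx, table.rows_of(best)])
        scores.append(step_scores[best])
        per_step.append(step_scores)
    return SelectionResult(order=chosen, scores=scores, subset_sizes=sizes,
                           n_total=table.n_tiles, per_step_candidates=per_step)
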