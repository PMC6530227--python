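"""Similarity/dissimilarity statistics against a group representative.

Two statistics compare a sequence's adjacency vector A with a group
representative GR:

* magnitude  D = ||A - GR||        (Euclidean norm of the difference)
* angle      theta = arccos( A.GR / (||A|| ||GR||) )   in radians

theta is scale-invariant; D is computed on raw count vectors by default.
Two exploratory normalization modes exist for D (``unit``: each vector
divided by its Euclidean norm; ``length``: each vector divided by its total
pair count) but neither is the default, since the raw Euclidean difference
is the statistic as defined.

A *similarity vector* holds one (D, theta) entry per family member against
the family's representative — n statistic evaluations per metric for a
family of n, versus the n(n-1)/2 of the conventional all-pairs matrix,
which is provided as a contrast mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .adjacency import AdjacencyVector, compute_adjacency
from .representative import GroupRepresentative
from .seq_io import GroupSample

NORMALIZE_MODES = ("none", "unit", "length")


class ZeroVectorError(ValueError):
    """Raised when an angle is requested for a zero-norm vector."""


@dataclass(frozen=True)
class SimilarityEntry:
    """Per-sequence statistics against one representative."""

    sequence_id: str
    group_name: str
    D: float
    theta: float


@dataclass(frozen=True)
class SimilarityVector:
    """One entry per family member, in input order.

    ``sample_name`` is the family the sequences came from and ``group_name``
    the representative's family; they differ in a cross-group comparison.
    """

    group_name: str
    entries: tuple[SimilarityEntry, ...]
    sample_name: str
    representative_ref: str = ""

    def thetas(self) -> np.ndarray:
        return np.array([e.theta for e in self.entries])

    def rows(self) -> list[dict[str, object]]:
        return [
            {
                "id": e.sequence_id,
                "group": self.sample_name,
                "gr_group": self.group_name,
                "D": e.D,
                "theta": e.theta,
            }
            for e in self.entries
        ]


def _as_values(x: AdjacencyVector | GroupRepresentative | np.ndarray) -> np.ndarray:
    if isinstance(x, AdjacencyVector):
        return x.counts.astype(np.float64)
    if isinstance(x, GroupRepresentative):
        return x.values
    return np.asarray(x, dtype=np.float64)


def _name_of(x) -> str:
    if isinstance(x, AdjacencyVector):
        return x.source_id
    if isinstance(x, GroupRepresentative):
        return f"GR[{x.group_name}]"
    return "vector"


def _normalized(u: np.ndarray, mode: str, name: str) -> np.ndarray:
    if mode == "none":
        return u
    if mode == "unit":
        n = np.linalg.norm(u)
        if n == 0:
            raise ZeroVectorError(f"{name}: cannot unit-normalize a zero vector")
        return u / n
    if mode == "length":
        s = u.sum()
        if s == 0:
            raise ZeroVectorError(f"{name}: cannot length-normalize a zero vector")
        return u / s
    raise ValueError(f"unknown normalization {mode!r}; expected one of {NORMALIZE_MODES}")


def magnitude_D(a, gr, normalize: str = "none") -> float:
    """Euclidean norm of the elementwise difference between two descriptors."""
    u, v = _as_values(a), _as_values(gr)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    u = _normalized(u, normalize, _name_of(a))
    v = _normalized(v, normalize, _name_of(gr))
    return float(np.linalg.norm(u - v))


def angle_theta(a, gr) -> float:
    """Angle in radians between two descriptors.

    The cosine is clamped to [-1, 1] before arccos to absorb floating-point
    overshoot, so parallel vectors give exactly 0 and antiparallel exactly pi.
    """
    u, v = _as_values(a), _as_values(gr)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0:
        raise ZeroVectorError(f"{_name_of(a)}: zero-norm vector has no direction")
    if nv == 0:
        raise ZeroVectorError(f"{_name_of(gr)}: zero-norm vector has no direction")
    if np.array_equal(u, v):
        return 0.0  # identical descriptors: exact zero, no rounding residue
    cos = float(np.dot(u, v) / (nu * nv))
    return math.acos(max(-1.0, min(1.0, cos)))


def similarity_vector(
    sample: GroupSample,
    gr: GroupRepresentative,
    normalize: str = "none",
) -> SimilarityVector:
    """One (D, theta) entry per sample member against ``gr``, input order.

    Exactly n evaluations of each statistic for a sample of n.
    """
    entries = []
    for rec in sample.records:
        av = compute_adjacency(rec)
        entries.append(
            SimilarityEntry(
                sequence_id=rec.id,
                group_name=gr.group_name,
                D=magnitude_D(av, gr, normalize=normalize),
                theta=angle_theta(av, gr),
            )
        )
    return SimilarityVector(
        group_name=gr.group_name,
        entries=tuple(entries),
        sample_name=sample.name,
        representative_ref=f"{gr.group_name} (n={gr.n_sequences})",
    )


def cross_group(
    sample: GroupSample,
    foreign_gr: GroupRepresentative,
    normalize: str = "none",
) -> SimilarityVector:
    """Score one family's sequences against another family's representative.

    The computation is identical to :func:`similarity_vector`; the output is
    tagged with both the sample's and the representative's group names.  A
    family scored against a well-separated foreign representative shows a
    marked increase in every member's angle.
    """
    return similarity_vector(sample, foreign_gr, normalize=normalize)


@dataclass(frozen=True)
class PairwiseMatrix:
    """Conventional all-pairs distance matrix (contrast mode)."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    metric: str
    n_evaluations: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def pairwise_matrix(
    sample: GroupSample,
    metric: str = "theta",
    normalize: str = "none",
) -> PairwiseMatrix:
    """Square symmetric matrix of the chosen statistic over all member pairs.

    No representative is involved.  Exactly n(n-1)/2 statistic evaluations
    are performed (symmetry and the zero diagonal are filled in), and the
    count is recorded in ``n_evaluations``.
    """
    if metric not in ("D", "theta"):
        raise ValueError(f"metric must be 'D' or 'theta', got {metric!r}")
    if len(sample) < 2:
        raise ValueError("pairwise matrix needs at least 2 records")
    vectors = [compute_adjacency(r) for r in sample.records]
    n = len(vectors)
    out = np.zeros((n, n), dtype=np.float64)
    n_evals = 0
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "D":
                val = magnitude_D(vectors[i], vectors[j], normalize=normalize)
            else:
                val = angle_theta(vectors[i], vectors[j])
            n_evals += 1
            out[i, j] = out[j, i] = val
    return PairwiseMatrix(
        ids=tuple(sample.ids()), values=out, metric=metric, n_evaluations=n_evals
    )


def write_phylip(matrix: PairwiseMatrix, path) -> None:
    """Export a pairwise matrix in PHYLIP square distance format, usable as
    input to neighbor-joining and related tree tools."""
    ids = matrix.ids
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for name, row in zip(ids, matrix.values):
            label = name[:10].ljust(10)
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
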