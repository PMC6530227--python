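"""Group representative vector: the elementwise median of a family's
adjacency vectors.

The median is chosen over the mean for robustness: one aberrant family
member shifts each element by at most one order statistic.  With an even
number of members the standard convention (mean of the two central order
statistics) applies, so representative values may be half-integers; they are
kept exact and never rounded because the similarity statistics consume them
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adjacency import N_ELEMENTS, PAIR_LABELS, AdjacencyVector, compute_adjacency
from .seq_io import GroupSample, warn_singleton


@dataclass(frozen=True)
class GroupRepresentative:
    """Elementwise-median descriptor of a sequence family."""

    group_name: str
    values: np.ndarray = field(repr=False)
    n_sequences: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_ELEMENTS,):
            raise ValueError(f"representative must have {N_ELEMENTS} elements")
        if (v < 0).any():
            raise ValueError("representative values must be non-negative")
        object.__setattr__(self, "values", v)


def representative_from_vectors(
    vectors: list[AdjacencyVector], group_name: str
) -> GroupRepresentative:
    """Elementwise median of precomputed adjacency vectors."""
    if not vectors:
        raise ValueError("cannot build a representative from zero vectors")
    stack = np.stack([v.counts for v in vectors]).astype(np.float64)
    return GroupRepresentative(
        group_name=group_name,
        values=np.median(stack, axis=0),
        n_sequences=len(vectors),
        member_ids=tuple(v.source_id for v in vectors),
    )


def build_representative(sample: GroupSample, policy_applied: bool = True) -> GroupRepresentative:
    """Build the group representative of a sample.

    Members are taken in input order (the median is order-invariant; the
    recorded ``member_ids`` preserve provenance).  A single-member sample
    yields that member's own vector, with a warning.
    """
    warn_singleton(sample, "its representative equals its own adjacency vector")
    vectors = [compute_adjacency(r) for r in sample.records]
    return representative_from_vectors(vectors, sample.name)


def write_representative(gr: GroupRepresentative, path: str | Path) -> None:
    """Persist a representative as TSV (group_name, n_sequences, then the
    400 labelled median values) so it can be reused for cross-group runs."""
    with open(Path(path), "w") as fh:
        fh.write("group_name\tn_sequences\t" + "\t".join(PAIR_LABELS) + "\n")
        vals = "\t".join(format(v, "g") for v in gr.values)
        fh.write(f"{gr.group_name}\t{gr.n_sequences}\t{vals}\n")


def read_representative(path: str | Path) -> GroupRepresentative:
    """Read back a representative written by :func:`write_representative`."""
    with open(Path(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        row = fh.readline().rstrip("\n").split("\t")
    expected = ["group_name", "n_sequences", *PAIR_LABELS]
    if header != expected:
        raise ValueError(f"{path}: not a representative table (bad header)")
    values = np.array([float(x) for x in row[2:]], dtype=np.float64)
    return GroupRepresentative(
        group_name=row[0],
        values=values,
        n_sequences=int(row[1]),
        member_ids=(),
    )
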