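"""Dipeptide adjacency descriptor.

A protein sequence over the 20 canonical amino acids is summarised by a
400-element integer vector counting every ordered pair of adjacent residues,
read left to right with a sliding window of width 2 and step 1.  A sequence
of length L therefore contributes L - 1 ordered pairs (fewer if a validation
policy masks some windows).  The layout is fixed: with the residues ordered
A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W, Y, V, element
``20*i + j`` counts occurrences of residue ``i`` immediately followed by
residue ``j`` — the first 20 elements are the "A row" (AA, AR, ..., AV), the
next 20 the "R row", and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_io import ProteinRecord

#: Canonical residue ordering defining the 400-element layout.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}

N_ELEMENTS = 400

#: Two-letter labels in canonical order: AA, AR, ..., AV, RA, ..., VV.
PAIR_LABELS: tuple[str, ...] = tuple(
    a + b for a in RESIDUE_ORDER for b in RESIDUE_ORDER
)


def pair_index(first: str, second: str) -> int:
    """Flat index (0..399) of the ordered residue pair ``first -> second``.

    Raises ``KeyError`` with an explicit message for non-canonical symbols.
    """
    try:
        i = RESIDUE_INDEX[first]
        j = RESIDUE_INDEX[second]
    except KeyError as exc:
        raise KeyError(
            f"non-canonical residue {exc.args[0]!r}; expected one of {RESIDUE_ORDER}"
        ) from None
    return 20 * i + j


def pair_label(index: int) -> str:
    """Inverse of :func:`pair_index`: the two-letter label of a flat index."""
    if not 0 <= index < N_ELEMENTS:
        raise IndexError(f"pair index {index} outside 0..{N_ELEMENTS - 1}")
    return PAIR_LABELS[index]


@dataclass(frozen=True)
class AdjacencyVector:
    """400 ordered-pair counts for one sequence.

    ``skipped_pairs`` counts sliding windows discarded because they touched a
    non-canonical residue under the ``mask`` policy; under ``strict`` it is
    always 0, and ``counts.sum() == max(length - 1 - skipped_pairs, 0)``.
    """

    source_id: str
    counts: np.ndarray = field(repr=False)
    length: int
    skipped_pairs: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_ELEMENTS,):
            raise ValueError(f"adjacency vector must have {N_ELEMENTS} elements")
        if (c < 0).any():
            raise ValueError("adjacency counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    def count(self, first: str, second: str) -> int:
        """Count of the ordered pair ``first`` followed by ``second``."""
        return int(self.counts[pair_index(first, second)])

    def as_matrix(self) -> np.ndarray:
        """The same counts viewed as a 20x20 matrix (row = first residue)."""
        return self.counts.reshape(20, 20)


def compute_adjacency(record: ProteinRecord) -> AdjacencyVector:
    """Compute the adjacency vector of a validated protein record.

    Windows containing a residue outside the 20-letter alphabet (possible
    only under the ``mask`` input policy) contribute no count and are
    tallied in ``skipped_pairs``.  A length-1 sequence yields the zero
    vector; downstream angle computations reject zero vectors explicitly.
    """
    seq = record.residues
    if len(seq) == 0:
        raise ValueError(f"record {record.id!r}: empty sequence")

    idx = np.array([RESIDUE_INDEX.get(aa, -1) for aa in seq], dtype=np.int64)
    counts = np.zeros(N_ELEMENTS, dtype=np.int64)
    if len(seq) == 1:
        return AdjacencyVector(record.id, counts, length=1, skipped_pairs=0)

    first, second = idx[:-1], idx[1:]
    valid = (first >= 0) & (second >= 0)
    flat = 20 * first[valid] + second[valid]
    counts = np.bincount(flat, minlength=N_ELEMENTS).astype(np.int64)
    skipped = int((~valid).sum())
    return AdjacencyVector(record.id, counts, length=len(seq), skipped_pairs=skipped)


def adjacency_table(vectors: list[AdjacencyVector]):
    """Tabulate adjacency vectors: one row per sequence, columns id, length,
    then the 400 pair labels in canonical order."""
    import pandas as pd

    rows = []
    for v in vectors:
        row: dict[str, object] = {"id": v.source_id, "length": v.length}
        row.update({lab: int(n) for lab, n in zip(PAIR_LABELS, v.counts)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "length", *PAIR_LABELS])
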