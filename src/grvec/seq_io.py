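"""Protein sequence and table I/O.

FASTA reading goes through Biopython; this module adds the residue
validation policies the descriptor needs.  Three policies govern characters
outside the 20-letter canonical alphabet:

``strict``
    (default) any non-canonical character is an error — the descriptor
    assumes exactly 20 symbols.
``mask``
    the character is kept in the sequence but flagged; downstream pair
    counting skips every window that touches it.
``drop``
    the character is removed before pairing, joining its neighbours.

``*`` (stop) and ``-`` (gap) are never canonical.  Lower-case input is
upper-cased before validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

CANONICAL_RESIDUES = frozenset("ARNDCQEGHILKMFPSTWYV")

POLICIES = ("strict", "mask", "drop")


class FastaParseError(ValueError):
    """Raised when a file is not parseable FASTA."""


class ResidueValidationError(ValueError):
    """Raised when a sequence violates the residue policy."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: id (first header token), full description, and
    upper-cased residues.

    Under ``strict`` and ``drop`` every character of ``residues`` is one of
    the 20 canonical codes; under ``mask`` retained non-canonical characters
    are listed (0-based) in ``non_canonical_positions``.
    """

    id: str
    description: str
    residues: str
    non_canonical_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ResidueValidationError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GroupSample:
    """A named family of protein records, optionally class-labelled."""

    name: str
    records: list[ProteinRecord]
    class_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"group {self.name!r}: needs at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"group {self.name!r}: duplicate record ids {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def apply_policy(seq: str, policy: str, record_id: str) -> tuple[str, tuple[int, ...]]:
    """Upper-case and validate a raw sequence under a residue policy.

    Returns the (possibly modified) sequence and the 0-based positions of
    retained non-canonical characters (non-empty only under ``mask``).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; expected one of {POLICIES}")
    seq = seq.upper()
    bad = [i for i, aa in enumerate(seq) if aa not in CANONICAL_RESIDUES]
    if not bad:
        return seq, ()
    if policy == "strict":
        i = bad[0]
        raise ResidueValidationError(
            f"record {record_id!r}: non-canonical residue {seq[i]!r} "
            f"at position {i + 1} (policy=strict)"
        )
    if policy == "drop":
        kept = "".join(aa for aa in seq if aa in CANONICAL_RESIDUES)
        if not kept:
            raise ResidueValidationError(
                f"record {record_id!r}: empty after dropping non-canonical residues"
            )
        return kept, ()
    return seq, tuple(bad)


def read_fasta(path: str | Path, policy: str = "strict", name: str | None = None) -> GroupSample:
    """Read a FASTA file into a :class:`GroupSample`, applying ``policy``.

    Records are returned in file order.  The sample name defaults to the
    file stem.  Malformed files raise :class:`FastaParseError` naming the
    offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header starting "
                        f"with '>', got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: file contains no FASTA records")

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, flagged = apply_policy(str(rec.seq), policy, rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description,
                residues=seq,
                non_canonical_positions=flagged,
            )
        )
    return GroupSample(name=name if name is not None else path.stem, records=records)


def write_fasta(sample: GroupSample, path: str | Path, width: int = 60) -> None:
    """Write a sample as FASTA (wrapped at ``width`` columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in sample.records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    precision: int = 4,
) -> None:
    """Write keyed records as TSV or JSON with deterministic column order
    (order of keys in the first row) and fixed-precision floats."""
    rows = list(rows)
    path = Path(path)
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown table format {format!r}")

    if rows:
        columns = list(rows[0].keys())
        keysets = {tuple(r.keys()) for r in rows}
        if len({frozenset(k) for k in keysets}) > 1:
            raise ValueError("rows do not share a key set")
    else:
        columns = []

    def render(v: object) -> object:
        if isinstance(v, float):
            return f"{v:.{precision}f}"
        return v

    if format == "json":
        payload = [{k: render(r[k]) for k in columns} for r in rows]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(render(r[k])) for k in columns) + "\n")


def read_group_map(path: str | Path) -> dict[str, tuple[str, str | None]]:
    """Read a group-map TSV (columns: id, group, optional class_label) into
    ``{id: (group, class_label)}``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"group map must have columns {sorted(required)}")
    out: dict[str, tuple[str, str | None]] = {}
    for _, row in df.iterrows():
        label = row["class_label"] if "class_label" in df.columns else None
        if label is not None and pd.isna(label):
            label = None
        out[row["id"]] = (row["group"], label)
    return out


def warn_singleton(sample: GroupSample, context: str) -> None:
    if len(sample) == 1:
        warnings.warn(
            f"group {sample.name!r} has a single sequence; {context}",
            UserWarning,
            stacklevel=3,
        )
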