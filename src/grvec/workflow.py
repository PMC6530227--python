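"""End-to-end runs: group analysis, cross-group comparison, class report.

Every run is deterministic (there is no randomness anywhere in the core);
reruns with an identical configuration produce byte-identical tables.  A
run log records input hashes, policy, normalization and precision so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .adjacency import adjacency_table, compute_adjacency
from .representative import (
    GroupRepresentative,
    build_representative,
    write_representative,
)
from .seq_io import GroupSample, read_fasta, write_table
from .similarity import SimilarityVector, similarity_vector


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    input_fasta: str | Path
    group_name: str | None = None
    policy: str = "strict"
    normalize: str = "none"
    out_dir: str | Path = "grvec_run"
    precision: int = 4
    class_labels: dict[str, str] | None = None
    sort: bool = False
    representative_path: str | Path | None = None  # foreign GR for cross-group

    def __post_init__(self) -> None:
        if self.precision < 1:
            raise ValueError("precision must be >= 1")
        if not Path(self.input_fasta).exists():
            raise FileNotFoundError(f"input FASTA not found: {self.input_fasta}")
        if self.representative_path is not None and not Path(self.representative_path).exists():
            raise FileNotFoundError(
                f"representative table not found: {self.representative_path}"
            )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_log(config: RunConfig, out: Path, stages: list[str]) -> None:
    log = {
        "grvec_version": __version__,
        "input_fasta": str(config.input_fasta),
        "input_sha256": _sha256(config.input_fasta),
        "policy": config.policy,
        "normalize": config.normalize,
        "precision": config.precision,
        "sort": config.sort,
        "stages": stages,
    }
    if config.representative_path is not None:
        log["representative_path"] = str(config.representative_path)
        log["representative_sha256"] = _sha256(config.representative_path)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def _similarity_rows(sv: SimilarityVector, sort: bool) -> list[dict[str, object]]:
    rows = sv.rows()
    if sort:
        rows = sorted(rows, key=lambda r: (r["theta"], r["id"]))
    return rows


def run_group_analysis(
    config: RunConfig,
) -> tuple[GroupRepresentative, SimilarityVector, dict[str, Path]]:
    """Full within-group analysis of one FASTA family.

    Writes the adjacency-vector table, the representative table, the
    similarity-vector table and a run log under ``config.out_dir``.  On a
    stage failure, partial outputs are removed and the error re-raised with
    the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "adjacency": out / "adjacency.tsv",
        "representative": out / "representative.tsv",
        "similarity": out / "similarity.tsv",
        "log": out / "run_log.json",
    }
    stage = "read"
    try:
        sample = read_fasta(config.input_fasta, policy=config.policy, name=config.group_name)
        stage = "adjacency"
        vectors = [compute_adjacency(r) for r in sample.records]
        adjacency_table(vectors).to_csv(paths["adjacency"], sep="\t", index=False)
        stage = "representative"
        gr = build_representative(sample)
        write_representative(gr, paths["representative"])
        stage = "similarity"
        sv = similarity_vector(sample, gr, normalize=config.normalize)
        write_table(
            _similarity_rows(sv, config.sort),
            paths["similarity"],
            precision=config.precision,
        )
        _write_log(config, out, ["read", "adjacency", "representative", "similarity"])
    except Exception as exc:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"group analysis failed at stage {stage!r}: {exc}") from exc
    return gr, sv, paths


@dataclass(frozen=True)
class ClassReport:
    """Theta ranges per labelled class and the sequences that break them.

    The coherence rule (stated here because no canonical rule exists) is a
    two-pass leave-one-out interval test.  Pass 1 marks a sequence *suspect*
    when its theta falls outside the interval spanned by the rest of its own
    class.  Pass 2 computes each class's *core* interval from its
    non-suspect members only (so one genuine outlier cannot inflate its
    class's interval and cascade flags onto healthy members elsewhere) and
    flags every suspect whose theta lands inside another class's core
    interval.  ``ranges`` reports the full per-class intervals.
    """

    ranges: dict[str, tuple[float, float]]
    flagged: tuple[dict[str, object], ...] = field(default_factory=tuple)


def class_report(sv: SimilarityVector, class_labels: dict[str, str]) -> ClassReport:
    """Coherence report over a labelled similarity vector (deterministic)."""
    missing = [e.sequence_id for e in sv.entries if e.sequence_id not in class_labels]
    if missing:
        raise ValueError(f"class labels missing for ids: {missing}")

    by_class: dict[str, list[tuple[str, float]]] = {}
    for e in sv.entries:
        by_class.setdefault(class_labels[e.sequence_id], []).append(
            (e.sequence_id, e.theta)
        )
    ranges = {
        cls: (min(t for _, t in members), max(t for _, t in members))
        for cls, members in by_class.items()
    }

    def is_suspect(e) -> bool:
        own = class_labels[e.sequence_id]
        rest = [t for sid, t in by_class[own] if sid != e.sequence_id]
        return not (rest and min(rest) <= e.theta <= max(rest))

    suspects = {e.sequence_id for e in sv.entries if is_suspect(e)}
    core: dict[str, tuple[float, float]] = {}
    for cls, members in by_class.items():
        kept = [t for sid, t in members if sid not in suspects]
        pool = kept if kept else [t for _, t in members]
        core[cls] = (min(pool), max(pool))

    flagged: list[dict[str, object]] = []
    for e in sv.entries:
        if e.sequence_id not in suspects:
            continue
        own = class_labels[e.sequence_id]
        hits = [
            cls
            for cls, (lo, hi) in core.items()
            if cls != own and lo <= e.theta <= hi
        ]
        if hits:
            flagged.append(
                {
                    "id": e.sequence_id,
                    "class": own,
                    "theta": e.theta,
                    "overlaps": ",".join(sorted(hits)),
                }
            )
    return ClassReport(ranges=ranges, flagged=tuple(flagged))


def run_class_report(config: RunConfig) -> ClassReport:
    """Within-group analysis followed by a class-coherence report.

    Requires ``config.class_labels`` covering every sequence id; writes
    ``class_report.tsv`` (flags) and ``class_ranges.tsv`` alongside the
    group-analysis outputs.
    """
    if config.class_labels is None:
        raise ValueError("class report requires class labels")
    gr, sv, paths = run_group_analysis(config)
    report = class_report(sv, config.class_labels)
    out = Path(config.out_dir)
    write_table(
        list(report.flagged),
        out / "class_report.tsv",
        precision=config.precision,
    )
    write_table(
        [
            {"class": cls, "theta_min": lo, "theta_max": hi}
            for cls, (lo, hi) in sorted(report.ranges.items())
        ],
        out / "class_ranges.tsv",
        precision=config.precision,
    )
    return report
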