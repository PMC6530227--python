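"""Built-in sequences and seeded synthetic families.

Everything here is computable offline: the two 30-residue yeast protein
segments used as the walk-through example, and a seeded generator of
synthetic families (one random ancestor plus mutated copies) that gives the
group structure the method needs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjacency import RESIDUE_ORDER
from .seq_io import GroupSample, ProteinRecord

#: Two 30-residue segments of a yeast (Saccharomyces cerevisiae) protein.
PROTEIN_I = "WTFESRNDPAKDPVILWLNGGPGCSSLTGL"
PROTEIN_II = "WFFESRNDPANDPIILWLNGGPGCSSFTGL"


def worked_example() -> GroupSample:
    """The two-sequence walk-through sample (ids ProteinI, ProteinII)."""
    return GroupSample(
        name="worked_example",
        records=[
            ProteinRecord("ProteinI", "ProteinI yeast segment", PROTEIN_I),
            ProteinRecord("ProteinII", "ProteinII yeast segment", PROTEIN_II),
        ],
    )


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a synthetic protein family.

    A uniform-random ancestor of ``ancestor_length`` residues is drawn, then
    each of the remaining ``n_members - 1`` members substitutes every site
    independently with probability ``substitution_rate`` to a uniformly
    random *different* residue.  The ancestor is member 0.  The uniform
    residue model is deliberate: the fixture provides group structure, not
    evolutionary realism.
    """

    ancestor_length: int = 200
    n_members: int = 8
    substitution_rate: float = 0.1
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.ancestor_length < 2:
            raise ValueError("ancestor_length must be >= 2")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")


def make_family(spec: SyntheticFamilySpec) -> GroupSample:
    """Generate a synthetic family; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(RESIDUE_ORDER.encode(), dtype="S1")
    anc_idx = rng.integers(0, 20, size=spec.ancestor_length)
    ancestor = alphabet[anc_idx].tobytes().decode()

    anc_id = f"{spec.name}_anc"
    records = [ProteinRecord(anc_id, f"{anc_id} ancestor", ancestor)]
    for m in range(1, spec.n_members):
        idx = anc_idx.copy()
        hit = rng.random(spec.ancestor_length) < spec.substitution_rate
        # shift by 1..19 mod 20: uniform over the 19 residues != original
        offsets = rng.integers(1, 20, size=int(hit.sum()))
        idx[hit] = (idx[hit] + offsets) % 20
        seq = alphabet[idx].tobytes().decode()
        member_id = f"{spec.name}_m{m}"
        records.append(
            ProteinRecord(
                member_id,
                f"{member_id} member {m} (rate={spec.substitution_rate})",
                seq,
            )
        )
    return GroupSample(name=spec.name, records=records)
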