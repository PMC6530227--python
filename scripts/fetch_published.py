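#!/usr/bin/env python
"""Fetch the published benchmark sequences from NCBI (NETWORK-DEPENDENT).

Downloads the beta globin, ND5 and spike accessions via NCBI E-utilities
and writes them under data/published/ as plain FASTA, with record ids set
to the species / virus labels the benchmark tables use.  The library and
test suite never fetch anything themselves; run this once on a machine with
internet access:

    python scripts/fetch_published.py [--out data/published]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from grvec.datasets import BETA_GLOBIN, ND5, SPIKE  # noqa: E402

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_fasta(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "protein", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise RuntimeError(f"unexpected efetch response for {accession}")
    return text


def sequence_of(fasta_text: str) -> str:
    return "".join(fasta_text.splitlines()[1:])


def write_family(path: Path, members: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for label, accession in members:
            seq = sequence_of(fetch_fasta(accession))
            fh.write(f">{label} {accession}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            time.sleep(0.4)  # NCBI rate limit
    print(f"wrote {path} ({len(members)} sequences)")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="data/published", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    write_family(
        args.out / "beta_globin.fasta",
        [(species.replace(" ", "_"), acc) for species, acc in BETA_GLOBIN],
    )
    write_family(
        args.out / "nd5.fasta",
        [(species.replace(" ", "_"), acc) for species, acc in ND5],
    )
    write_family(
        args.out / "spike.fasta",
        [(abbr, acc) for abbr, acc, _ in SPIKE],
    )
    with open(args.out / "spike_classes.tsv", "w") as fh:
        fh.write("id\tgroup\tclass_label\n")
        for abbr, _, cls in SPIKE:
            fh.write(f"{abbr}\tspike\t{cls}\n")
    print(f"wrote {args.out / 'spike_classes.tsv'}")


if __name__ == "__main__":
    main()
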