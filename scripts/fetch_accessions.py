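#!/usr/bin/env python
"""Download the two published mitogenome GenBank records used by the optional
sequence-level acceptance test (requires network access).

Usage:  python scripts/fetch_accessions.py [--email you@example.org]

Writes NC_026789.gb and KY594708.gb into tests/data/accessions/; once present,
tests/test_acceptance.py::test_deposited_sequence_values stops skipping.
The offline test suite never requires these files.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez

ACCESSIONS = ("NC_026789", "KY594708")
OUT_DIR = Path(__file__).resolve().parent.parent / "tests" / "data" / "accessions"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org",
                        help="Contact e-mail passed to NCBI Entrez.")
    args = parser.parse_args()
    Entrez.email = args.email
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        target = OUT_DIR / f"{acc}.gb"
        if target.exists():
            print(f"{target} already present, skipping")
            continue
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gb",
                           retmode="text") as handle:
            target.write_text(handle.read(), encoding="utf-8")
        print(f"wrote {target}")


if __name__ == "__main__":
    main()
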