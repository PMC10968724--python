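#!/usr/bin/env python
"""One-time download of the three deposited chloroplast genomes from NCBI.

Fetches OM687473 (HSVM), OM687472 (HS N.M.521) and OM541594 (HS 'Tamra')
as GenBank flat files into ``data/accessions/`` so the accession-dependent
tests in ``tests/test_accessions.py`` can run. The library itself never
touches the network; only this helper does.

Usage:
    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
from pathlib import Path

ACCESSIONS = {
    "OM687473": "HSVM",
    "OM687472": "HS N.M.521",
    "OM541594": "HS 'Tamra'",
}


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default="anonymous@example.org", help="NCBI Entrez contact email")
    ap.add_argument("--out-dir", type=Path, default=Path(__file__).resolve().parent.parent / "data" / "accessions")
    args = ap.parse_args()

    from Bio import Entrez

    Entrez.email = args.email
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for acc, label in ACCESSIONS.items():
        dest = args.out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present ({label}); skipping")
            continue
        print(f"fetching {acc} ({label}) ...")
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gb", retmode="text") as handle:
            dest.write_text(handle.read())
        print(f"wrote {dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
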