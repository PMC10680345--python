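#!/usr/bin/env python
"""Optional helper: download the three deposited GenBank records from NCBI.

Requires network access; nothing in the library or test suite depends on
it. Fetched files can be fed straight to the CLI, e.g.

    python scripts/fetch_accessions.py --out data/accessions
    mitocomp report data/accessions/*.gb --out results/real
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

ACCESSIONS = ("MZ274046", "MZ274047", "NC_045238")
EUTILS = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gb&retmode=text")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/accessions"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        with urllib.request.urlopen(EUTILS.format(acc=acc), timeout=60) as r:
            dest.write_bytes(r.read())
        print(f"fetched {acc} -> {dest}")


if __name__ == "__main__":
    main()
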