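#!/usr/bin/env python
"""Download UniProt records for the accession-anchored checks (needs network).

The package itself is strictly offline; this helper exists so that
``scripts/paper_check.py`` can be run against the real canonical sequences.

    python scripts/fetch_uniprot.py --out-dir data/uniprot

fetches the flat-text records for the four case-study proteins:

    P34080  rat aquaporin-2
    O60500  human nephrin
    Q9NP85  human podocin
    O14791  human apolipoprotein L1
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "P34080": "rat aquaporin-2",
    "O60500": "human nephrin",
    "Q9NP85": "human podocin",
    "O14791": "human apolipoprotein L1",
}

URL = "https://rest.uniprot.org/uniprotkb/{acc}.txt"


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="data/uniprot")
    args = parser.parse_args()
    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc, label in ACCESSIONS.items():
        dest = out_dir / f"{acc}.txt"
        print(f"fetching {acc} ({label}) -> {dest}")
        with urllib.request.urlopen(URL.format(acc=acc), timeout=60) as resp:
            dest.write_bytes(resp.read())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
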