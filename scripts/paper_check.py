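#!/usr/bin/env python
"""Accession-anchored checks against real UniProt records (optional suite).

Run ``scripts/fetch_uniprot.py`` first (needs network), then:

    python scripts/paper_check.py --records data/uniprot

Checks, against the four canonical case-study records:

* each published immunizing peptide occurs in its protein at the published
  start coordinate (nephrin 1039, podocin 366, ApoL1 125);
* the canonical lengths are 1241 (nephrin), 383 (podocin), 398 (ApoL1);
* the rat aquaporin-2 tail peptide EPDTDWEEREVRRRQ scores in the high
  Ig band (>= 7) and ranks second among all 15-mer windows of the full
  protein under the frozen default parameters.

Exit 0 if every check passes, 1 otherwise.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from pepdesign.immunogenicity import DesignParams, score_windows
from pepdesign.sequence_io import read_uniprot_text

PEPTIDES = {
    # accession: (peptide, published start, published canonical length)
    "O60500": ("HQPSGEPEDQLPTEPPSG", 1039, 1241),  # human nephrin
    "Q9NP85": ("PSKPVEPLNPKKKDSPML", 366, 383),    # human podocin
    "O14791": ("KDKNWHDKGQQYRNW", 125, 398),       # human ApoL1
}
AQP2 = ("P34080", "EPDTDWEEREVRRRQ")


def check(label: str, ok: bool, detail: str) -> bool:
    print(f"{'PASS' if ok else 'FAIL'}  {label}: {detail}")
    return ok


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--records", default="data/uniprot",
                        help="directory of fetched UniProt flat-text records")
    args = parser.parse_args()
    rec_dir = Path(args.records)
    all_ok = True

    for acc, (peptide, start, length) in PEPTIDES.items():
        rec = read_uniprot_text(rec_dir / f"{acc}.txt")
        all_ok &= check(f"{acc} length", len(rec.sequence) == length,
                        f"parsed {len(rec.sequence)}, published {length}")
        found = rec.sequence.find(peptide) + 1
        all_ok &= check(f"{acc} peptide start", found == start,
                        f"located at {found}, published {start}")

    acc, peptide = AQP2
    rec = read_uniprot_text(rec_dir / f"{acc}.txt")
    params = DesignParams(peptide_length=len(peptide))
    windows = score_windows(rec, params)
    (target,) = [w for w in windows if w.sequence == peptide]
    all_ok &= check(f"{acc} Ig band",
                    target.ig_score >= params.high_ig_threshold,
                    f"Ig-score {target.ig_score:.3f}, threshold "
                    f"{params.high_ig_threshold}")
    all_ok &= check(f"{acc} rank", target.rank == 2,
                    f"rank {target.rank} among {len(windows)} windows "
                    f"(published: second)")
    return 0 if all_ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
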