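#!/usr/bin/env python
"""Fetch the public reference accessions used for optional validation.

The package builds and tests without these sequences; fetching them
enables the two reference-sequence checks in ``tests/test_acceptance.py``
(G-domain lengths of the human/zebrafish RGK proteins, and the 498-aa
Drosophila RGK1).  Requires network access to NCBI E-utilities:

    python scripts/fetch_accessions.py [--out data/validation/accessions.fasta]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

#: zebrafish Gem/Rad/Rem1/Rem2 and fly RGK1/RGK3 (named in the study),
#: plus the canonical human RefSeq RGK proteins
ACCESSIONS = [
    "NP_001039314",  # dr_Gem
    "NP_956092",     # dr_Rad
    "NP_957468",     # dr_Rem1
    "NP_001116518",  # dr_Rem2
    "NP_005252",     # human GEM
    "NP_004156",     # human RRAD
    "NP_055176",     # human REM1
    "NP_775786",     # human REM2
    "AAF57577",      # dm_RGK1
    "ABV53867",      # dm_RGK3
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).parent.parent / "data" / "validation" / "accessions.fasta",
    )
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    chunks = []
    for acc in ACCESSIONS:
        query = urllib.parse.urlencode(
            {"db": "protein", "id": acc, "rettype": "fasta", "retmode": "text"}
        )
        with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=30) as resp:
            chunks.append(resp.read().decode())
        time.sleep(0.4)  # NCBI rate limit
    args.out.write_text("".join(chunks))
    print(f"wrote {len(ACCESSIONS)} accessions to {args.out}")


if __name__ == "__main__":
    main()
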