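#!/usr/bin/env python
"""Download the deposited halogenase sequences into data/deposited/.

Requires network access to NCBI eutils and RCSB.  Fetches the two
nucleotide-halogenase protein records by accession plus the AdaV sequence
from its crystal structure entry, and writes one FASTA per sequence so the
identity checks in the test suite can run against the real records.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "WP_204007738.1": (  # VaNTH
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        "?db=protein&id=WP_204007738.1&rettype=fasta&retmode=text"),
    "WP_217394979.1": (  # CtNTH
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        "?db=protein&id=WP_217394979.1&rettype=fasta&retmode=text"),
    "AdaV_7W5T": (
        "https://www.rcsb.org/fasta/entry/7W5T"),
}


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "deposited"
    out_dir.mkdir(parents=True, exist_ok=True)
    failures = 0
    for name, url in ACCESSIONS.items():
        dest = out_dir / f"{name}.fasta"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                text = resp.read().decode()
        except OSError as exc:
            print(f"FAILED {name}: {exc}", file=sys.stderr)
            failures += 1
            continue
        if not text.startswith(">"):
            print(f"FAILED {name}: response is not FASTA", file=sys.stderr)
            failures += 1
            continue
        dest.write_text(text)
        print(f"wrote {dest}")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
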