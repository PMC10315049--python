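#!/usr/bin/env python
"""Download the three deposited mitogenomes (GenBank MZ490595-MZ490597)
into data/accessions/ for the deposited-genome checks in the test suite.

Requires network access; the checks skip cleanly when the files are
absent.

Usage: python scripts/fetch_accessions.py [--outdir data/accessions]
"""

import argparse
import os
import sys
import urllib.request

ACCESSIONS = ["MZ490595", "MZ490596", "MZ490597"]
EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=fasta&retmode=text")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default=os.path.join("data", "accessions"))
    args = ap.parse_args(argv)
    os.makedirs(args.outdir, exist_ok=True)
    for acc in ACCESSIONS:
        dest = os.path.join(args.outdir, f"{acc}.fasta")
        if os.path.exists(dest):
            print(f"{dest} already present")
            continue
        url = EFETCH.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            data = resp.read()
        if not data.startswith(b">"):
            print(f"unexpected response for {acc}", file=sys.stderr)
            return 1
        with open(dest, "wb") as fh:
            fh.write(data)
        print(f"wrote {dest} ({len(data)} bytes)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
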