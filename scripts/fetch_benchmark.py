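#!/usr/bin/env python
"""Fetch example monomer/complex PDB pairs from RCSB (network required).

The library itself never downloads; this helper populates a local directory
with a few monomer/complex pairs in which the same protein binds a
nucleotide or cofactor alone and inside a protein-protein complex, for use
with ``examples/benchmark_pairs.py`` or the ``mcdpa armsd`` command.

    python scripts/fetch_benchmark.py --dest data/benchmark
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

#: (monomer id, complex id) pairs; see examples/benchmark_pairs.py for the
#: shared-chain choices used when comparing them
PAIRS = [
    ("1QG4", "1A2K"),
    ("2VAW", "1OFU"),
    ("1MH1", "1E96"),
    ("1CL0", "1F6M"),
]

URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch(pdb_id: str, dest: Path) -> Path:
    path = dest / f"{pdb_id.lower()}.pdb"
    if path.exists():
        print(f"{path} already present")
        return path
    url = URL.format(pdb_id=pdb_id.upper())
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        path.write_bytes(resp.read())
    return path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("data/benchmark"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for mono, cplx in PAIRS:
        fetch(mono, args.dest)
        fetch(cplx, args.dest)


if __name__ == "__main__":
    main()
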