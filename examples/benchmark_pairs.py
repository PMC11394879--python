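"""Ligand ARMSD report for real monomer/complex structure pairs.

Requires PDB files fetched beforehand with ``scripts/fetch_benchmark.py``
(the library never downloads).  For each pair the shared protein is
superposed by residue-number correspondence and every matched ligand is
classified and its ARMSD reported, mirroring the tabular report format
(pair, ligands, ARMSD, category).

Run from the repository root after fetching:

    python scripts/fetch_benchmark.py --dest data/benchmark
    python examples/benchmark_pairs.py data/benchmark
"""

import sys
from pathlib import Path

import mcdpa as m
from mcdpa.cli import build_pair_record
from mcdpa.evaluation import classify_ligand_change

#: (monomer id, shared chain) vs (complex id, shared chain of the same protein)
PAIRS = [
    ("1qg4", "A", "1a2k", "A"),   # GTPase Ran with GDP, alone / with NTF2
    ("2vaw", "A", "1ofu", "X"),   # FtsZ with GDP, alone / with SulA
    ("1mh1", "A", "1e96", "A"),   # Rac1 with GNP, alone / with p67phox (GTP analog)
    ("1cl0", "A", "1f6m", "A"),   # thioredoxin reductase with FAD, alone / with Trx
]


def main(data_dir: Path) -> None:
    print("monomer\tcomplex\tligands\tcategory\tARMSD(A)\tmode")
    for mono_id, mono_chain, cplx_id, cplx_chain in PAIRS:
        mono_path = data_dir / f"{mono_id}.pdb"
        cplx_path = data_dir / f"{cplx_id}.pdb"
        if not (mono_path.exists() and cplx_path.exists()):
            print(f"{mono_id}\t{cplx_id}\t-\tmissing files (run scripts/fetch_benchmark.py)")
            continue
        pair = build_pair_record(m.read_pdb(mono_path), m.read_pdb(cplx_path),
                                 mono_chain, cplx_chain)
        for ch in classify_ligand_change(pair):
            armsd = "-" if ch.armsd is None else f"{ch.armsd.value:.2f}"
            mode = "-" if ch.armsd is None else ch.armsd.mode
            ligs = f"{','.join(ch.monomer_ligands) or 'none'}->" \
                   f"{','.join(ch.complex_ligands) or 'none'}"
            print(f"{mono_id}\t{cplx_id}\t{ligs}\t{ch.category}\t{armsd}\t{mode}")


if __name__ == "__main__":
    main(Path(sys.argv[1]) if len(sys.argv) > 1 else Path("data/benchmark"))
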