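#!/usr/bin/env python
"""Build per-family neighbor-joining trees for the synthetic family.

Multi-domain members contribute their most conserved domain copy to the
alignment (aligning repeat architectures full length can place two
single-domain proteins on different copies, leaving them no shared
columns); then progressive MSA -> p-distance matrix -> NJ, one Newick
tree per family.
"""

from pathlib import Path

import pandas as pd

from immclass.align import DEFAULT_SCHEME
from immclass.domains import scan_ppiase_domains, select_representative_domain
from immclass.phylogeny import neighbor_joining, p_distance_matrix, progressive_msa, write_newick
from immclass.records import ProteinRecord
from immclass.seqio import load_references, read_fasta

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    refs = load_references()
    records = read_fasta(OUT / "synthetic_family.fasta")
    truth = pd.read_csv(OUT / "synthetic_truth.tsv", sep="\t", index_col="id")
    for family in ("FKBP", "CYP"):
        members = [r for r in records if truth.loc[r.id, "family"] == family][:30]
        if len(members) < 3:
            continue
        leaves = []
        for rec in members:
            hits = scan_ppiase_domains(rec, refs, DEFAULT_SCHEME)
            if len(hits) > 1:
                rep = select_representative_domain(hits)
                leaves.append(ProteinRecord(rec.id, rec.sequence[rep.start - 1 : rep.end]))
            else:
                leaves.append(rec)
        msa = progressive_msa(leaves, DEFAULT_SCHEME)
        tree = neighbor_joining(p_distance_matrix(msa))
        path = OUT / f"tree_{family}.nwk"
        path.write_text(write_newick(tree) + "\n")
        print(f"{family}: {len(leaves)} leaves -> {path.name}")


if __name__ == "__main__":
    main()
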