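# immclass

Classification of plant immunophilins — FK506-binding proteins (FKBPs)
and cyclophilins (CYPs), the two families of peptidyl-prolyl cis/trans
isomerases (PPIases) — from protein sequence alone.

Plant genomes carry unusually large immunophilin inventories, with many
members targeted to the chloroplast thylakoid lumen. Building such an
inventory from a proteome is a stereotyped comparative-genomics
workflow, and `immclass` implements it as a tested, reusable pipeline
for people curating these families (or benchmarking tools against
synthetic ones):

1. **PPIase domain scan** — iterative local alignment against human
   FKBP12 and cyclophilin A (the structural references for the two
   folds); each hit is scored as `raw_score / reference self-score`, so
   a verbatim reference copy scores exactly 1.0. Architectures are
   classed single-domain (SD) or multiple-domain (MD) and summarized as
   composition strings like `FKBP×3+TPR+CaM`.
2. **Targeting signals** — heuristics for the twin-arginine (Tat)
   chloroplast-lumen signal (RR pair + hydrophobic stretch, optional
   Ala-x-Ala cleavage site; no cleavage ⇒ thylakoid-membrane anchored),
   ER signal/retention tetrapeptides (KDEL-like, x-[SD]EL), and mono-
   and bipartite nuclear localization signals, combined into one
   compartment call by a fixed precedence rule.
3. **Key-residue conservation** — the inventory's central statistic:
   the residues at the 14 hFKBP12 positions (27, 37, 38, 43, 47, 55,
   56, 57, 60, 82, 83, 88, 92, 100) or the 7 hCypA positions (54, 55,
   60, 111, 113, 121, 126) that govern drug binding and PPIase
   activity, and the percentage conserved. Includes a parser/renderer
   for the compact "ditto" table notation (`"` = reference residue,
   `X/Y` = residue in each of two organisms, `-` = absent).
4. **Nomenclature** — ortholog-based naming (>50% identity + same
   compartment + same architecture ⇒ inherit the ortholog's suffix),
   molecular-weight suffixes otherwise (mature-protein kDa), paralog
   letters a/b/c by similarity rank, and the trigger-factor (TIG)
   exception.
5. **Phylogeny** — progressive multiple alignment (UPGMA guide tree,
   profile–profile affine-gap merges), p-distance matrices, neighbor
   joining, Newick output.
6. **Synthetic families** — a seeded generator of immunophilin-like
   proteins with known domain spans, signals, compartments and
   ancestors, so every stage is benchmarked against ground truth.

## Worked example

```python
from immclass import classify, load_references, ProteinRecord

refs = load_references()
rec = ProteinRecord("query", refs.fkbp_reference.sequence, organism="Hs")
c = classify([rec]).classified[0]
print(c.family, c.architecture.sd_md, c.targeting.compartment,
      c.conservation.percent, c.mature_kda, c.name)
```

prints

```
FKBP SD cytosol 100 12 OsFKBP12
```

— the human FKBP12 reference classifies as a single-domain FKBP with no
targeting signal (cytosolic), retains 100% of its own key residues, and
with no ortholog references supplied falls through to molecular-weight
naming: 11.95 kDa rounds to the suffix 12.

Recomputing the packaged rice/Arabidopsis conservation tables:

```bash
immclass tables --family FKBP
```

reports, per row, the printed Conserved/Similarity values next to the
recomputed ones — e.g. OsFKBP13 prints 86 and recomputes 86 (12 of the
14 positions retained), while OsFKBP58 prints 79 but its own printed
residue row gives 12/14 = 86; such internally inconsistent rows are
flagged, not forced.

The CLI also exposes `classify` (FASTA → inventory, conservation
tables, trees, log), `simulate` (synthetic family + truth table) and
`tree` (Newick from a FASTA). The `analysis/` scripts run the same
steps as a narrated sequence: simulate → classify & score recovery →
recompute tables → family trees, writing their outputs under
`results/`.

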