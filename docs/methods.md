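# Methods

## Scope and model

`immclass` classifies candidate immunophilin proteins from sequence
alone. The unit of analysis is a `ProteinRecord` (uppercase amino-acid
sequence over the 20 standard residues plus `X`). Two packaged human
references anchor everything: FKBP12 (108 aa, itself a lone FKBP
domain) and cyclophilin A (165 aa), together with the fixed key
positions for drug binding / PPIase activity — 14 positions on hFKBP12
and 7 on hCypA, 1-based in each reference's own numbering. The
pipeline does not claim catalytic activity from conservation; it
computes the conservation statistics that such claims are usually read
from.

## Alignment

Pairwise global (Needleman–Wunsch, terminal gaps penalized) and local
(Smith–Waterman) alignment use affine gaps with the convention that a
gap of length L costs `gap_open + L·gap_extend`; defaults BLOSUM62,
gap_open 10, gap_extend 0.5. The dynamic programming is Biopython's
`PairwiseAligner`; scores are verified in the test suite against an
independent brute-force enumeration of all alignments for small
inputs (exhaustive for all pairs up to length 3 over a 4-letter
sub-alphabet, seeded samples at lengths 4–6 — the exhaustive surface at
length 6 would be ~3·10⁷ pairs, which buys no additional DP coverage).
`X` scores the minimum of its partner's matrix row, so unknown or
masked residues never attract an alignment; this is what makes
iterative masking sound. Percent identity uses the aligned-columns
denominator by default (configurable); percent similarity additionally
counts positive-scoring substitutions; p-distance is the mismatch
fraction over gap-free columns and errors when no such column exists.

## Domain scanning

Domains are found greedily: best local hit of either family reference
against the protein, mask the hit span with `X` (coordinates
preserved), repeat until the normalized score (raw / reference
self-score) falls below `min_normalized` (default 0.3) or `max_copies`
(default 4) is reached. Families compete per round, so hits never
overlap and a protein's family is read from its best hit. The
representative ("most conserved") domain is the hit with maximal
normalized score, ties to the earliest start. The threshold is a
configuration value, not a claim of equivalence with any external
domain database's cutoff.

Auxiliary domains (TPR, coiled-coil, CaM, RRM, WD40, U-box, zinc
finger, TM …) are accepted from an annotation file rather than
re-derived; only the compositionally defined Arg/Lys-rich region has an
in-repo detector (windows of 20 with ≥40% R+K, merged, minimum length
30). SD means exactly one catalytic domain and nothing else; everything
else is MD. Composition strings list features N→C with repeat
collapsing (`FKBP×3+TPR+CaM`).

## Targeting signals

Tat (twin-arginine) signals: RR pairs in the N-terminal 80 residues are
scanned left to right; the first followed within 25 residues by a
hydrophobic stretch (≥8 residues averaging ≥1.5 on the packaged
Kyte–Doolittle scale; extension stops at the first non-hydrophobic
residue) yields the signal. A failing RR does not mask a later valid
one — requiring strictly the first RR would make the detector fail on
sequences with an incidental upstream RR, which the rule's authors
plainly did not intend. The Ala-x-Ala cleavage site is sought within 30
residues after the stretch, allowing a 2-residue overlap with its tail
because Ala is itself hydrophobic and often terminates the run;
absence of the motif calls the protein membrane-anchored. `KR`/`RK`
variants are rejected by default (toggle available).

ER: an N-terminal hydrophobic leader (same run rule, first 30
residues) plus a C-terminal retention tetrapeptide (x-[SD]EL or
[KH]DEL). NLS: monopartite (≥4 K/R in a window of 6) or bipartite (two
basic doublets spaced 9–12), merged.

Precedence for the compartment call: Tat+cleavage → chloroplast lumen;
Tat without cleavage → chloroplast membrane-anchored; ER leader +
retention → ER; NLS alone → nucleus; otherwise cytosol. The stroma is
never emitted: nothing in these heuristics can separate it from the
lumen route, and pretending otherwise would be false precision. All
thresholds above are config fields; the defaults were fixed once from
the canonical descriptions of each signal class.

## Key-residue conservation

A candidate (in the pipeline: its representative domain) is globally
aligned to the family reference and the residue in each key position's
column is read off (`-` when gapped). Conservation is the exact-match
count over the positions, as a percentage rounded half away from zero
(so 12/14 → 86). Pair similarity between two profiles is identity by
default — identity reproduces the printed values of the tables'
internally consistent rows — with a matrix-positive mode available.
Column conservation divides by the number of profiles present for that
organism.

The two packaged tables transcribe the printed rice/Arabidopsis residue
tables verbatim in their compact ditto notation. The parser expands
`"`/`X`/`X/Y`/`-` cells into residue profiles; rows keep their raw cell
tokens because the printed tables occasionally spell a reference
residue literally instead of using ditto, so canonical re-rendering
would be lossy — parse→render round-trips byte for byte. One printed
cell contains the nonstandard letter `O` (an evident typo); profile
strings therefore admit any uppercase letter, and nonstandard letters
simply never count as conserved. Recomputation reproduces the printed
Conserved/Similarity values for 47 of the 54 scored rows; the
remainder (and most bottom-row column percentages) contradict their own
printed residues under any consistent counting rule and are flagged as
known inconsistencies in the audit report — flagged, never forced.

## Nomenclature

Mature mass is the ExPASy average residue-mass sum plus one water,
computed on the sequence after the Tat or ER cleavage point when one
was detected, else full length; the kDa suffix rounds half away from
zero. Ortholog assignment requires >50% global identity, the same
compartment call and the same architecture composition; the best
identity wins, ties by similarity then reference name. Named orthologs
donate their suffix; otherwise the kDa value is the suffix; candidates
flagged as trigger factors are named `<prefix>TIG`. Suffix groups of
two or more receive letters a, b, c… by decreasing similarity to the
ortholog (ortholog groups) or decreasing mean identity to the other
group members (molecular-weight groups); naming is a pure function of
its inputs and invariant to input order. Callers must pre-select one
(the longest) isoform per gene; isoform grouping is out of scope.

## Phylogeny

Progressive MSA: UPGMA guide tree from pairwise p-distances, then
profile–profile merges under a Gotoh affine DP whose column–column
score is the mean pairwise substitution score (existing gaps neutral).
Single-row merges provably reduce to the pairwise optimum and are
cross-checked against the pairwise engine in the tests; the full
procedure is a heuristic with no sum-of-pairs optimality claim. Trees
are canonical neighbor joining (via scikit-bio), exact on additive
matrices — verified by regenerating random 4–8-taxon trees from their
own distance matrices — with negative branch-length estimates clamped
to zero and flagged. Newick serialization quotes labels containing
metacharacters. In the pipeline's tree stage, multi-domain members
contribute only their most conserved domain copy: aligning repeat
architectures full length can place two single-domain proteins on
different copies, leaving them no shared columns and hence no defined
p-distance. Exact reproduction of any published tree topology is not
claimed (that would require the original sequence set and aligner
parameters); clade labels have no algorithmic definition, so monophyly
is a per-query check.

## Synthetic data

The generator emulates the observed structure of a plant immunophilin
inventory: 60/40 FKBP/CYP mix; 1–3 domain copies (30% multi-domain,
2:1 double:triple); a signal mix of 20% Tat with cleavage, 10% Tat
anchored, 15% ER, 15% NLS, 40% none; 20% of multi-domain proteins get
an Arg/Lys-rich linker. Substitutions are independent per site and
uniform over the 19 alternatives, at separate key-site and background
rates (defaults 0.1/0.1) — the simplest null that exercises the
scoring. Signal geometry (spacer 2–10, hydrophobic run 8–15 over
L/V/I/F) matches the detector defaults so implanted positives are
detectable by construction. Ancestors default to the unmutated
reference cores; ortholog-recovery runs use 4 independently diverged
ancestors per family (rate 0.3) with candidates mutated at 0.2.

What the generator does *not* emulate: indels, site-rate heterogeneity,
realistic substitution matrices, compositional bias, or genuinely novel
folds. Passing recovery tests therefore shows the pipeline implements
its stated rules correctly under its own assumptions, not that it
matches external predictors on real proteomes.

## Problem sizes and numerical choices

Recovery benchmarks run at n=200 (domains, ortholog naming), n=500
(Tat detection) and 50 seeded runs of 12 taxa (clade monophyly);
byte-determinism checks rerun the full pipeline (with trees) at n=15.
NJ consistency uses 100 random trees of 4–8 taxa. All randomness in
tests, drivers and the acceptance script flows through explicit seeds;
identical seeds give byte-identical FASTA, truth tables and reports.
Traceback ties in the profile DP prefer diagonal, then gap in the
second profile; percentages round half away from zero; DP score
comparisons in tracebacks use a 1e-9 tolerance (scores are exact
half-integer multiples, so this is slack, not a fudge).

## Known limitations

The signal heuristics are rule transcriptions, not statistical models —
no equivalence with TargetP/PSORT/SignalP-class predictors is implied,
and mitochondrial presequences are out of scope. The ortholog gates use
global-alignment identity, whose absolute values differ from BLASTP
conventions on real, length-heterogeneous proteins. The progressive
aligner is not a substitute for a production MSA tool on distant or
indel-rich families.
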