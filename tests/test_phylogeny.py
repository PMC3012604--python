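"""Progressive MSA, p-distance matrices, neighbor joining, Newick."""

import numpy as np
import pytest

from immclass.align import global_align, p_distance
from immclass.phylogeny import (
    DistanceMatrix,
    neighbor_joining,
    p_distance_matrix,
    parse_newick,
    progressive_msa,
    random_additive_tree,
    same_topology,
    sum_of_pairs_score,
    tree_distance_matrix,
    write_newick,
)
from immclass.records import AA20, ProteinRecord


def _mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(seq)):
        if rng.random() < rate:
            out[i] = [a for a in AA20 if a != seq[i]][int(rng.integers(19))]
    return "".join(out)


def test_two_records_reduce_to_pairwise(scheme):
    a = ProteinRecord("a", "ACDEFGHIKL")
    b = ProteinRecord("b", "ACDEGHIKL")
    msa = progressive_msa([a, b], scheme)
    al = global_align(a, b, scheme)
    assert msa.rows == (al.aligned_a, al.aligned_b)
    with pytest.raises(ValueError):
        progressive_msa([a], scheme)


def test_identical_sequences_align_gap_free(scheme):
    recs = [ProteinRecord(f"s{i}", "ACDEFGHIKLMNP") for i in range(3)]
    msa = progressive_msa(recs, scheme)
    assert all(row == "ACDEFGHIKLMNP" for row in msa.rows)


def test_no_all_gap_columns(scheme):
    rng = np.random.default_rng(10)
    base = "".join(rng.choice(list(AA20), size=40))
    recs = [ProteinRecord(f"s{i}", _mutate(base, 0.3, rng)) for i in range(5)]
    msa = progressive_msa(recs, scheme)
    for j in range(msa.n_columns):
        assert any(row[j] != "-" for row in msa.rows)


@pytest.mark.parametrize("seed", range(5))
def test_guide_tree_order_not_worse_than_input_order(scheme, seed):
    """For structured triples (two close, one far, shuffled) the guide tree
    achieves at least the input-order sum-of-pairs score (heuristic)."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AA20), size=50))
    close = _mutate(base, 0.08, rng)
    far = _mutate(base, 0.5, rng)
    recs = [ProteinRecord("far", far), ProteinRecord("a", base), ProteinRecord("b", close)]
    sop_guide = sum_of_pairs_score(progressive_msa(recs, scheme, order="guide"), scheme)
    sop_input = sum_of_pairs_score(progressive_msa(recs, scheme, order="input"), scheme)
    assert sop_guide >= sop_input - 1e-9


def test_profile_aligner_matches_pairwise_optimum(scheme):
    """Single-row profile merges reproduce the affine-gap pairwise optimum
    (cross-check of the profile DP against the pairwise engine)."""
    from immclass.phylogeny import _profile_align

    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    m = scheme.matrix

    def induced_score(x, y):
        total, in_gap = 0.0, None
        for c1, c2 in zip(x, y):
            if c1 == "-" and c2 == "-":
                continue
            if c1 == "-" or c2 == "-":
                side = "a" if c1 == "-" else "b"
                total -= ge if in_gap == side else go
                in_gap = side
            else:
                total += float(m[c1, c2])
                in_gap = None
        return total

    rng = np.random.default_rng(77)
    for _ in range(60):
        a = "".join(rng.choice(list(AA20), size=rng.integers(1, 30)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(1, 30)))
        na, nb = _profile_align([a], [b], scheme)
        assert induced_score(na[0], nb[0]) == pytest.approx(
            global_align(a, b, scheme).score
        ), (a, b)


def test_p_distance_matrix_contract(scheme):
    from immclass.phylogeny import MultipleAlignment

    msa = MultipleAlignment(ids=("a", "b"), rows=("ACDEFGHIKL", "ACDEFGHIKL"))
    assert p_distance_matrix(msa).values[0, 1] == 0.0
    msa = MultipleAlignment(ids=("a", "b"), rows=("AAAAAAAAAA", "AAAAAAAAAT"))
    assert p_distance_matrix(msa).values[0, 1] == pytest.approx(0.1)
    # consistency with the pairwise route when the MSA is that alignment
    a, b = ProteinRecord("a", "ACDEFGHIKL"), ProteinRecord("b", "ACDFGHIKW")
    al = global_align(a, b, scheme)
    msa = MultipleAlignment(ids=("a", "b"), rows=(al.aligned_a, al.aligned_b))
    assert p_distance_matrix(msa).values[0, 1] == pytest.approx(p_distance(al))


def test_three_taxon_closed_form():
    # d(AB)=5, d(AC)=9, d(BC)=10 -> a=2, b=3, c=7
    dm = DistanceMatrix(
        labels=("A", "B", "C"),
        values=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float),
    )
    tree = neighbor_joining(dm)
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths == {"A": pytest.approx(2.0), "B": pytest.approx(3.0), "C": pytest.approx(7.0)}
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))


@pytest.mark.parametrize("n_taxa", [4, 6, 8])
def test_nj_exact_on_additive_matrices(n_taxa):
    rng = np.random.default_rng(n_taxa)
    for _ in range(10):
        true = random_additive_tree(n_taxa, rng)
        dm = tree_distance_matrix(true)
        recovered = neighbor_joining(dm)
        assert same_topology(true, recovered)
        back = tree_distance_matrix(recovered, dm.labels)
        assert np.allclose(back.values, dm.values, atol=1e-8)


def test_newick_round_trip_and_quoting():
    rng = np.random.default_rng(99)
    for _ in range(10):
        tree = random_additive_tree(int(rng.integers(3, 9)), rng)
        text = write_newick(tree)
        assert text.endswith(";")
        again = parse_newick(text)
        assert same_topology(tree, again)
        assert np.allclose(
            tree_distance_matrix(again).values, tree_distance_matrix(tree).values, atol=1e-9
        )
    assert "'a b'" in write_newick(parse_newick("('a b':1,c:1,d:2);"))


def test_label_permutation_invariance():
    rng = np.random.default_rng(42)
    tree = random_additive_tree(6, rng)
    dm = tree_distance_matrix(tree)
    perm = np.random.default_rng(1).permutation(len(dm.labels))
    dm2 = DistanceMatrix(
        labels=tuple(dm.labels[i] for i in perm),
        values=dm.values[np.ix_(perm, perm)],
    )
    t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
    assert same_topology(t1, t2)


def test_three_clade_monophyly_recovery(refs, scheme):
    """Three synthetic clades (within 0.05, between ~0.3 divergence) come
    out monophyletic in at least 95% of seeded runs."""
    core = refs.fkbp_reference.sequence
    ok = 0
    n_runs = 50
    for seed in range(n_runs):
        rng = np.random.default_rng(1000 + seed)
        recs, clades = [], []
        for c in range(3):
            ancestor = _mutate(core, 0.3, rng)
            members = [f"C{c}_{k}" for k in range(4)]
            clades.append(members)
            recs.extend(
                ProteinRecord(m, _mutate(ancestor, 0.05, rng)) for m in members
            )
        msa = progressive_msa(recs, scheme)
        tree = neighbor_joining(p_distance_matrix(msa))
        if all(tree.is_monophyletic(c) for c in clades):
            ok += 1
    assert ok / n_runs >= 0.95
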