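"""Mature-mass computation, orthology gates, and the naming rules."""

import numpy as np
import pytest

from immclass.nomenclature import (
    NamedReference,
    NamingInput,
    OrthologAssignment,
    assign_names,
    assign_ortholog,
    mature_mass_kda,
    parse_name_suffix,
)
from immclass.records import AA20, ProteinRecord


def test_decaglycine_mass_hand_sum():
    kda, mass = mature_mass_kda("G" * 10)
    assert mass == pytest.approx(10 * 57.0519 + 18.0153, abs=1e-6)
    assert kda == 1


def test_cleavage_equals_suffix_mass():
    seq = "ACDEFGHIKLMNPQRS"
    _, cleaved = mature_mass_kda(seq, cleavage_position=5)
    _, suffix = mature_mass_kda(seq[5:])
    assert cleaved == suffix
    with pytest.raises(ValueError):
        mature_mass_kda(seq, cleavage_position=len(seq))


def test_mass_strictly_increases_with_appended_residues():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list(AA20), size=5))
    last = mature_mass_kda(seq)[1]
    for _ in range(20):
        seq += str(rng.choice(list(AA20)))
        mass = mature_mass_kda(seq)[1]
        assert mass > last
        last = mass


def test_human_fkbp12_rounds_to_12_kda(refs):
    assert mature_mass_kda(refs.fkbp_reference)[0] == 12


@pytest.mark.parametrize(
    "name,expected",
    [
        ("AtFKBP20-1", ("FKBP", "20-1")),
        ("AtCYP40", ("CYP", "40")),
        ("OsTIG", ("TIG", "")),
        ("REF_FKBP13", ("FKBP", "13")),
    ],
)
def test_parse_established_names(name, expected):
    assert parse_name_suffix(name) == expected


def _named_ref(name, seq, compartment="cytosol", architecture="FKBP"):
    return NamedReference(ProteinRecord(name, seq), name, compartment, architecture)


def test_ortholog_gates(scheme):
    rng = np.random.default_rng(7)
    base = "".join(rng.choice(list(AA20), size=80))
    near = base[:8] + "W" + base[9:]  # ~99% identical
    cand = ProteinRecord("cand", near)
    ref = _named_ref("AtFKBP13", base)
    hit = assign_ortholog(cand, "cytosol", "FKBP", [ref], scheme=scheme)
    assert hit.ortholog_id == "AtFKBP13" and hit.identity_percent > 95

    # same identity, wrong compartment -> falls through
    miss = assign_ortholog(cand, "nucleus", "FKBP", [ref], scheme=scheme)
    assert miss.ortholog_id is None
    # wrong architecture -> falls through
    miss = assign_ortholog(cand, "cytosol", "FKBP×2", [ref], scheme=scheme)
    assert miss.ortholog_id is None
    # below the 50% identity gate -> falls through
    far = "".join(rng.choice(list(AA20), size=80))
    miss = assign_ortholog(ProteinRecord("far", far), "cytosol", "FKBP", [ref], scheme=scheme)
    assert miss.ortholog_id is None


def test_ortholog_recovery_on_synthetic_family(refs, scheme):
    """Candidates mutated at 20% from diverged named ancestors are assigned
    back to the right ancestor."""
    from immclass.synth import GeneratorConfig, generate_family

    cfg = GeneratorConfig(
        n_proteins=200, key_mutation_rate=0.2, background_mutation_rate=0.2,
        multi_domain_prob=0.0, p_tat=0, p_tat_no_cleavage=0, p_er=0, p_nls=0,
        n_ancestors_per_family=4, ancestor_divergence=0.3, seed=37,
    )
    records, truth, ancestors = generate_family(cfg, refs)
    named = [
        _named_ref(a.name, a.sequence, "cytosol", a.family) for a in ancestors
    ]
    correct = 0
    for rec in records:
        fam = truth.loc[rec.id, "family"]
        pool = [r for r in named if r.architecture == fam]
        hit = assign_ortholog(rec, "cytosol", fam, pool, scheme=scheme)
        correct += hit.ortholog_id == truth.loc[rec.id, "ancestor"]
    assert correct / len(records) >= 0.95


def _naming_input(rid, seq, family="CYP", assignment=None, kda=20):
    return NamingInput(ProteinRecord(rid, seq), family, assignment, kda)


def test_paralog_letters_by_similarity_order():
    asg = lambda rid, sim: OrthologAssignment(rid, "AtCYP40", 60.0, sim, True, True)
    items = [
        _naming_input("g1", "ACDEFGHIKL", assignment=asg("g1", 70.0)),
        _naming_input("g2", "ACDEFGHIKM", assignment=asg("g2", 73.0)),
    ]
    names = assign_names(items, "Os")
    assert str(names["g2"]) == "OsCYP40a" and str(names["g1"]) == "OsCYP40b"

    three = [
        _naming_input("x1", "ACDEFGHIKL", "FKBP",
                      OrthologAssignment("x1", "AtFKBP62", 60.0, 77.0, True, True)),
        _naming_input("x2", "ACDEFGHIKM", "FKBP",
                      OrthologAssignment("x2", "AtFKBP62", 60.0, 75.0, True, True)),
        _naming_input("x3", "ACDEFGHIKW", "FKBP",
                      OrthologAssignment("x3", "AtFKBP62", 60.0, 73.0, True, True)),
    ]
    names = assign_names(three, "Os")
    assert [str(names[f"x{i}"]) for i in (1, 2, 3)] == ["OsFKBP62a", "OsFKBP62b", "OsFKBP62c"]


def test_molecular_weight_naming_and_trigger_factor():
    names = assign_names([_naming_input("solo", "ACDE", "FKBP", None, 46)], "Os")
    assert str(names["solo"]) == "OsFKBP46"
    names = assign_names([_naming_input("tf", "ACDE", "TIG", None, 60)], "Os")
    assert str(names["tf"]) == "OsTIG"


def test_naming_is_order_invariant_and_unique():
    asg = lambda rid, sim: OrthologAssignment(rid, "AtCYP40", 60.0, sim, True, True)
    items = [
        _naming_input("a", "ACDEFGHIKL", assignment=asg("a", 70.0)),
        _naming_input("b", "ACDEFGHIKM", assignment=asg("b", 73.0)),
        _naming_input("c", "MMMMMMMMMM", "FKBP", None, 46),
        _naming_input("d", "MMMMMMMMMW", "FKBP", None, 46),
    ]
    forward = assign_names(items, "Os")
    backward = assign_names(list(reversed(items)), "Os")
    assert {k: str(v) for k, v in forward.items()} == {k: str(v) for k, v in backward.items()}
    rendered = [str(v) for v in forward.values()]
    assert len(set(rendered)) == len(rendered)
    letters = sorted(str(forward[k])[-1] for k in ("c", "d"))
    assert letters == ["a", "b"]
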