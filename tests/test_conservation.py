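"""Key-residue conservation scoring and the ditto-notation tables.

The packaged tables transcribe the printed rice/Arabidopsis residue
tables verbatim; worked-example values asserted here are the printed
ones for rows whose arithmetic is internally consistent.
"""

import numpy as np
import pytest

from immclass.conservation import (
    KeyResidueProfile,
    column_conservation,
    conserved_percent,
    extract_key_residues,
    pair_similarity_percent,
    parse_ditto_table,
    render_ditto_table,
    round_half_away,
)
from immclass.records import ProteinRecord
from immclass.seqio import table_fixture_text


@pytest.fixture(scope="module")
def tables(refs):
    return {
        fam: parse_ditto_table(table_fixture_text(fam), refs, fam)
        for fam in ("FKBP", "CYP")
    }


def _row(tables, family, name):
    return next(r for r in tables[family].rows if r.name_1 == name)


def test_rounding_half_away_from_zero():
    assert round_half_away(85.5) == 86
    assert round_half_away(85.4999) == 85
    assert round_half_away(12.0 / 14 * 100) == 86  # 85.71...


def test_extract_key_residues_identity_and_point_mutation(refs, scheme):
    ref = refs.fkbp_reference
    p = extract_key_residues(ref, ref, refs.fkbp_key_positions, scheme, family="FKBP")
    assert p.residues == refs.key_residue_string("FKBP")
    seq = list(ref.sequence)
    seq[88 - 1] = "A"
    mutant = ProteinRecord("mut", "".join(seq))
    pm = extract_key_residues(mutant, ref, refs.fkbp_key_positions, scheme, family="FKBP")
    diff = [i for i, (x, y) in enumerate(zip(p.residues, pm.residues)) if x != y]
    assert diff == [[pos for pos, _ in refs.fkbp_key_positions].index(88)]
    assert pm.residues[diff[0]] == "A"


def test_extract_key_residues_recovers_generator_truth(refs, scheme):
    """Implanted key residues are recovered from mutated domains."""
    import json
    from immclass.synth import GeneratorConfig, generate_family

    cfg = GeneratorConfig(
        n_proteins=60, key_mutation_rate=0.15, background_mutation_rate=0.15,
        multi_domain_prob=0.0, p_tat=0, p_tat_no_cleavage=0, p_er=0, p_nls=0, seed=11,
    )
    records, truth, _ = generate_family(cfg, refs)
    exact = 0
    for rec in records:
        fam = truth.loc[rec.id, "family"]
        p = extract_key_residues(
            rec, refs.reference(fam), refs.key_positions(fam), scheme, family=fam
        )
        exact += p.residues == json.loads(truth.loc[rec.id, "key_residues"])[0]
    assert exact / len(records) >= 0.95


@pytest.mark.parametrize(
    "family,name,expected",
    [
        ("FKBP", "OsFKBP13", 86),
        ("FKBP", "OsFKBP17-2", 0),
        ("FKBP", "OsFKBP16-4", 50),
        ("CYP", "OsCYP17", 43),
        ("CYP", "OsCYP19-2", 100),
    ],
)
def test_conserved_percent_reproduces_printed_rows(tables, refs, family, name, expected):
    row = _row(tables, family, name)
    result = conserved_percent(row.profile_1, refs)
    assert result.percent == expected == row.printed_conserved_1


def test_reference_profile_is_fully_conserved(refs):
    p = KeyResidueProfile("ref", "FKBP", refs.key_residue_string("FKBP"), refs.fkbp_key_positions)
    r = conserved_percent(p, refs)
    assert (r.conserved_count, r.percent) == (14, 100)


def test_pair_similarity_identity_mode_reproduces_printed_value(tables, refs):
    row = _row(tables, "FKBP", "OsFKBP16-4")
    assert pair_similarity_percent(row.profile_1, row.profile_2) == 93


def test_pair_similarity_matrix_positive_dominates_identity(refs, scheme):
    rng = np.random.default_rng(5)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    positions = refs.fkbp_key_positions
    for _ in range(200):
        a = KeyResidueProfile("a", "FKBP", "".join(rng.choice(letters, 14)), positions)
        b = KeyResidueProfile("b", "FKBP", "".join(rng.choice(letters, 14)), positions)
        ident = pair_similarity_percent(a, b, "identity", scheme)
        plus = pair_similarity_percent(a, b, "matrix_positive", scheme)
        assert 0 <= ident <= plus <= 100
    same = KeyResidueProfile("s", "FKBP", refs.key_residue_string("FKBP"), positions)
    assert pair_similarity_percent(same, same, "identity") == 100
    assert pair_similarity_percent(same, same, "matrix_positive") == 100


def test_column_conservation_at_position_88_is_zero(tables, refs):
    """No rice FKBP retains His88 of human FKBP12."""
    profiles = tables["FKBP"].profiles_1()
    assert len(profiles) == 28
    idx = [p for p, _ in refs.fkbp_key_positions].index(88)
    assert column_conservation(profiles, idx, refs) == 0


def test_column_conservation_small_cases(refs):
    positions = refs.fkbp_key_positions
    ref_profile = KeyResidueProfile("r", "FKBP", refs.key_residue_string("FKBP"), positions)
    other = KeyResidueProfile("o", "FKBP", "A" * 14, positions)
    for i in range(14):
        assert column_conservation([ref_profile], i, refs) == 100
    idx0 = 0
    assert column_conservation([ref_profile, other], idx0, refs) == 50


def test_ditto_expansion_of_mixed_row(tables, refs):
    row = _row(tables, "FKBP", "OsFKBP12")
    assert row.profile_1.residues == "CFWAFSVIWAYFIF"
    assert row.profile_2.residues == "CFWEFAVIWAYFIF"


def test_all_ditto_row_expands_to_reference(refs):
    text = "\t".join(["OsX", "AtX"] + ['"'] * 14 + ["100/100", "100"])
    table = parse_ditto_table(text, refs, "FKBP")
    assert table.rows[0].profile_1.residues == refs.key_residue_string("FKBP")
    assert table.rows[0].profile_2.residues == refs.key_residue_string("FKBP")


def test_ditto_round_trip_is_byte_stable(tables, refs):
    for family in ("FKBP", "CYP"):
        text = table_fixture_text(family)
        assert render_ditto_table(tables[family], refs) == text


def test_render_canonical_cells(refs):
    positions = refs.fkbp_key_positions
    ref_string = refs.key_residue_string("FKBP")
    p1 = KeyResidueProfile("Os1", "FKBP", ref_string, positions)
    p2 = KeyResidueProfile("At1", "FKBP", "W" + ref_string[1:], positions)
    from immclass.conservation import DittoRow, DittoTable

    table = DittoTable(
        family="FKBP",
        rows=(DittoRow("Os1", "At1", p1, p2, None, None, None),),
        printed_column_conserved=(),
    )
    rendered = render_ditto_table(table, refs)
    cells = rendered.splitlines()[2].split("\t")[2:16]
    assert cells[0] == '"/W' and set(cells[1:]) == {'"'}


def test_parse_rejects_bad_cells_and_column_counts(refs):
    with pytest.raises(ValueError, match="fields"):
        parse_ditto_table("OsX\tAtX\t\"\t\"\n", refs, "FKBP")
    bad = "\t".join(["OsX", "AtX"] + ['"'] * 13 + ["ZZ"] + ["100/100", ""])
    with pytest.raises(ValueError, match="token"):
        parse_ditto_table(bad, refs, "FKBP")
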