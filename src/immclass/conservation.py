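"""Key-residue conservation scoring against the human references.

The central statistic of the classification: for each candidate domain,
the residues found at the fixed human FKBP12 (14) or cyclophilin A (7)
binding/activity positions, and the percentage of those positions where
the human residue is retained.  Also implements the compact
"ditto" table notation used to tabulate these profiles for rice and
Arabidopsis side by side: ``"`` means "same residue as the human
reference", ``X/Y`` gives the first organism's residue then the second
organism's, and ``-`` marks an absent position.

Percentages are rounded to the nearest integer, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import DEFAULT_SCHEME, PairwiseAlignment, ScoringScheme, global_align
from .records import ProteinRecord, ReferenceSet

# Table cells pass through verbatim, so profile characters are any
# uppercase letter plus '-'; nonstandard letters (typos in printed
# tables) are legal here and simply never count as conserved.
_PROFILE_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class KeyResidueProfile:
    """A protein's residues at the fixed reference key positions."""

    protein_id: str
    family: str
    residues: str
    positions: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.positions):
            raise ValueError(
                f"{self.protein_id}: {len(self.residues)} residues for "
                f"{len(self.positions)} key positions"
            )
        bad = set(self.residues) - _PROFILE_ALPHABET
        if bad:
            raise ValueError(f"{self.protein_id}: illegal profile characters {sorted(bad)}")


@dataclass(frozen=True)
class ConservationResult:
    conserved_count: int
    total: int
    percent: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("conservation total must be positive")


def extract_key_residues(
    record: ProteinRecord,
    reference: ProteinRecord,
    positions: Sequence[tuple[int, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    family: str = "",
) -> KeyResidueProfile:
    """Globally align *record* to *reference* and read off the record
    residue in the column of each reference key position ('-' if gapped)."""
    al = global_align(reference, record, scheme)
    wanted = {pos: i for i, (pos, _) in enumerate(positions)}
    out = ["-"] * len(positions)
    ref_pos = 0
    for ref_char, rec_char in al.columns():
        if ref_char != "-":
            ref_pos += 1
            if ref_pos in wanted:
                out[wanted[ref_pos]] = rec_char if rec_char != "-" else "-"
    return KeyResidueProfile(
        protein_id=record.id,
        family=family,
        residues="".join(out),
        positions=tuple(positions),
    )


def conserved_percent(profile: KeyResidueProfile, refs: ReferenceSet) -> ConservationResult:
    """Count positions retaining the human reference residue exactly."""
    positions = refs.key_positions(profile.family)
    if len(profile.residues) != len(positions):
        raise ValueError("profile length does not match reference position list")
    conserved = sum(
        1 for ch, (_, ref_res) in zip(profile.residues, positions) if ch == ref_res
    )
    total = len(positions)
    return ConservationResult(conserved, total, round_half_away(100.0 * conserved / total))


def pair_similarity_percent(
    a: KeyResidueProfile,
    b: KeyResidueProfile,
    mode: str = "identity",
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> int:
    """Percent of key positions where two profiles agree.

    ``identity`` counts equal residues; ``matrix_positive`` additionally
    counts positive-scoring substitutions.  A position absent ('-') in
    either profile never counts.
    """
    if a.positions != b.positions:
        raise ValueError("profiles tabulate different position lists")
    m = scheme.matrix
    n = 0
    for x, y in zip(a.residues, b.residues):
        if x == "-" or y == "-":
            continue
        if x == y:
            n += 1
        elif mode == "matrix_positive":
            try:
                if float(m[x, y]) > 0:
                    n += 1
            except IndexError:
                pass  # nonstandard letter: never similar
        elif mode != "identity":
            raise ValueError(f"unknown mode {mode!r}")
    return round_half_away(100.0 * n / len(a.residues))


def column_conservation(
    profiles: Sequence[KeyResidueProfile],
    position_index: int,
    refs: ReferenceSet,
) -> int:
    """Percent of profiles retaining the reference residue at one position."""
    if not profiles:
        raise ValueError("column_conservation of an empty profile list")
    family = profiles[0].family
    ref_res = refs.key_positions(family)[position_index][1]
    hit = sum(1 for p in profiles if p.residues[position_index] == ref_res)
    return round_half_away(100.0 * hit / len(profiles))


# --------------------------------------------------------------------------
# Ditto-notation tables


@dataclass(frozen=True)
class DittoRow:
    """One parsed table row: a first-organism (rice) profile and/or a
    second-organism (Arabidopsis) profile, plus the values the table
    printed for them."""

    name_1: str
    name_2: str
    profile_1: KeyResidueProfile | None
    profile_2: KeyResidueProfile | None
    printed_conserved_1: int | None
    printed_conserved_2: int | None
    printed_similarity: int | None
    # Verbatim cell tokens: printed tables occasionally spell a reference
    # residue out instead of using ditto, so canonical re-derivation is lossy.
    raw_cells: tuple[str, ...] | None = None


@dataclass(frozen=True)
class DittoTable:
    family: str
    rows: tuple[DittoRow, ...]
    printed_column_conserved: tuple[tuple[int | None, int | None], ...]

    def profiles_1(self) -> list[KeyResidueProfile]:
        return [r.profile_1 for r in self.rows if r.profile_1 is not None]

    def profiles_2(self) -> list[KeyResidueProfile]:
        return [r.profile_2 for r in self.rows if r.profile_2 is not None]


def _expand_token(token: str, ref_res: str) -> str:
    if token == '"':
        return ref_res
    if len(token) == 1 and token in _PROFILE_ALPHABET:
        return token
    raise ValueError(f"illegal residue cell token {token!r}")


def _parse_printed_pair(text: str) -> tuple[int | None, int | None]:
    left, _, right = text.partition("/")
    v1 = None if left in ("-", "") else int(left)
    v2 = None if right in ("-", "") else int(right)
    return v1, v2


def parse_ditto_table(table_text: str, refs: ReferenceSet, family: str) -> DittoTable:
    """Parse a tab-separated ditto-notation table into residue profiles.

    Cell grammar per key position: ``"`` reference residue for both
    organisms; ``X`` residue X for both; ``X/Y`` first-organism X,
    second-organism Y (either side may be ``"`` or ``-``); ``-`` absent.
    Rows with an empty first name carry a second-organism profile only.
    """
    positions = refs.key_positions(family)
    n = len(positions)
    rows: list[DittoRow] = []
    column_printed: tuple[tuple[int | None, int | None], ...] = ()
    for lineno, line in enumerate(table_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "%column":
            if len(fields) != n + 1:
                raise ValueError(f"line {lineno}: column-summary row needs {n} cells")
            column_printed = tuple(_parse_printed_pair(f) for f in fields[1:])
            continue
        if len(fields) != n + 4:
            raise ValueError(
                f"line {lineno}: expected {n + 4} tab-separated fields, got {len(fields)}"
            )
        name_1, name_2 = fields[0], fields[1]
        cells = fields[2 : 2 + n]
        res_1, res_2 = [], []
        for cell, (_, ref_res) in zip(cells, positions):
            first, slash, second = cell.partition("/")
            r1 = _expand_token(first, ref_res)
            r2 = _expand_token(second, ref_res) if slash else r1
            res_1.append(r1)
            res_2.append(r2)
        profile_1 = (
            KeyResidueProfile(name_1, family, "".join(res_1), positions) if name_1 else None
        )
        profile_2 = (
            KeyResidueProfile(name_2, family, "".join(res_2), positions) if name_2 else None
        )
        c1, c2 = _parse_printed_pair(fields[2 + n])
        sim_text = fields[3 + n]
        rows.append(
            DittoRow(
                name_1=name_1,
                name_2=name_2,
                profile_1=profile_1,
                profile_2=profile_2,
                printed_conserved_1=c1,
                printed_conserved_2=c2,
                printed_similarity=None if sim_text == "" else int(sim_text),
                raw_cells=tuple(cells),
            )
        )
    return DittoTable(family=family, rows=tuple(rows), printed_column_conserved=column_printed)


def _cell_token(res: str | None, ref_res: str) -> str:
    if res is None:
        return "-"
    return '"' if res == ref_res else res


def _format_pair(v1: int | None, v2: int | None) -> str:
    left = "-" if v1 is None else str(v1)
    right = "-" if v2 is None else str(v2)
    return f"{left}/{right}"


def render_ditto_table(table: DittoTable, refs: ReferenceSet, recompute: bool = False) -> str:
    """Render a parsed table back to the compact ditto notation.

    With ``recompute=False`` the printed conserved/similarity values are
    re-emitted verbatim, so parse -> render round-trips byte for byte.
    With ``recompute=True`` those columns (including the bottom
    per-position summary) are recomputed from the residue profiles.
    """
    positions = refs.key_positions(table.family)
    lines = [
        f"# family={table.family}",
        "# positions=" + ",".join(str(p) for p, _ in positions),
    ]
    for row in table.rows:
        if not recompute and row.raw_cells is not None:
            cells = list(row.raw_cells)
            lines.append(
                "\t".join(
                    [row.name_1, row.name_2]
                    + cells
                    + [
                        _format_pair(row.printed_conserved_1, row.printed_conserved_2),
                        "" if row.printed_similarity is None else str(row.printed_similarity),
                    ]
                )
            )
            continue
        cells = []
        for i, (_, ref_res) in enumerate(positions):
            r1 = row.profile_1.residues[i] if row.profile_1 else None
            r2 = row.profile_2.residues[i] if row.profile_2 else None
            if r1 is not None and r2 is not None:
                t1, t2 = _cell_token(r1, ref_res), _cell_token(r2, ref_res)
                cells.append(t1 if t1 == t2 else f"{t1}/{t2}")
            else:
                cells.append(_cell_token(r1 if r1 is not None else r2, ref_res))
        if recompute:
            c1 = conserved_percent(row.profile_1, refs).percent if row.profile_1 else None
            c2 = conserved_percent(row.profile_2, refs).percent if row.profile_2 else None
            sim = (
                pair_similarity_percent(row.profile_1, row.profile_2)
                if row.profile_1 and row.profile_2
                else None
            )
        else:
            c1, c2 = row.printed_conserved_1, row.printed_conserved_2
            sim = row.printed_similarity
        lines.append(
            "\t".join(
                [row.name_1, row.name_2]
                + cells
                + [_format_pair(c1, c2), "" if sim is None else str(sim)]
            )
        )
    if recompute:
        p1, p2 = table.profiles_1(), table.profiles_2()
        summary = tuple(
            (
                column_conservation(p1, i, refs) if p1 else None,
                column_conservation(p2, i, refs) if p2 else None,
            )
            for i in range(len(positions))
        )
    else:
        summary = table.printed_column_conserved
    if summary:
        lines.append("\t".join(["%column"] + [_format_pair(a, b) for a, b in summary]))
    return "\n".join(lines) + "\n"
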