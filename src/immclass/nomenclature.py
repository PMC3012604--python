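"""Ortholog assignment and immunophilin naming rules.

Names follow the plant-immunophilin convention: an organism prefix
("Os", "At" ...), the family token (FKBP / CYP / TIG for the trigger
factor), and a numeric suffix.  When a candidate has a clear ortholog
in a reference proteome — more than 50% identity, the same predicted
compartment and the same domain architecture — it inherits the
ortholog's suffix; otherwise the suffix is the calculated molecular
weight (kDa) of the predicted mature protein.  When several candidates
share one suffix they become paralogs lettered a, b, c ... in
decreasing order of similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import DEFAULT_SCHEME, ScoringScheme, global_align, percent_identity, percent_similarity
from .conservation import round_half_away
from .records import ProteinRecord

# ExPASy average residue masses (Da); a peptide mass is the residue sum
# plus one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
RESIDUE_MASS["X"] = sum(RESIDUE_MASS.values()) / 20  # unknown: average residue
WATER = 18.0153


def mature_mass_kda(
    record: ProteinRecord | str, cleavage_position: int | None = None
) -> tuple[int, float]:
    """(kDa rounded half away from zero, exact average mass in Da) of the
    mature sequence, i.e. everything after the 1-based cleavage position."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if cleavage_position is not None:
        if cleavage_position >= len(seq):
            raise ValueError("cleavage position at or beyond sequence end")
        seq = seq[cleavage_position:]
    if not seq:
        raise ValueError("empty mature sequence")
    mass = sum(RESIDUE_MASS[c] for c in seq) + WATER
    return round_half_away(mass / 1000.0), mass


@dataclass(frozen=True)
class OrthologAssignment:
    candidate_id: str
    ortholog_id: str | None
    identity_percent: float
    similarity_percent: float
    location_match: bool
    architecture_match: bool


@dataclass(frozen=True)
class ImmunophilinName:
    prefix: str
    family_token: str  # FKBP | CYP | TIG
    suffix: str        # ortholog suffix ("20-1") or kDa value ("46"); "" for TIG
    paralog_letter: str = ""

    def __str__(self) -> str:
        return f"{self.prefix}{self.family_token}{self.suffix}{self.paralog_letter}"


_NAME_RE = re.compile(r"^.*?(FKBP|CYP|TIG)([0-9][0-9-]*)?([a-z]?)$")


def parse_name_suffix(name: str) -> tuple[str, str]:
    """Family token and suffix from an established name like ``AtFKBP20-1``."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse immunophilin name {name!r}")
    return m.group(1), m.group(2) or ""


@dataclass(frozen=True)
class NamedReference:
    """A reference-proteome protein with an established name and the
    classification context needed for the orthology gates."""

    record: ProteinRecord
    name: str
    compartment: str
    architecture: str  # composition string


def assign_ortholog(
    candidate: ProteinRecord,
    candidate_compartment: str,
    candidate_architecture: str,
    references: Sequence[NamedReference],
    id_threshold: float = 50.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> OrthologAssignment:
    """Best reference passing all three gates: identity above threshold,
    same compartment, same architecture.  Ties by higher similarity, then
    lexicographic reference name."""
    best: tuple[float, float, str] | None = None
    best_ref: NamedReference | None = None
    for ref in sorted(references, key=lambda r: r.name):
        al = global_align(candidate, ref.record, scheme)
        ident = percent_identity(al)
        simil = percent_similarity(al, scheme)
        if ident <= id_threshold:
            continue
        if ref.compartment != candidate_compartment:
            continue
        if ref.architecture != candidate_architecture:
            continue
        key = (ident, simil, ref.name)
        if best is None or ident > best[0] or (ident == best[0] and simil > best[1]):
            best, best_ref = key, ref
    if best_ref is None:
        return OrthologAssignment(candidate.id, None, 0.0, 0.0, False, False)
    return OrthologAssignment(
        candidate_id=candidate.id,
        ortholog_id=best_ref.name,
        identity_percent=best[0],
        similarity_percent=best[1],
        location_match=True,
        architecture_match=True,
    )


@dataclass(frozen=True)
class NamingInput:
    """Everything the naming rules need for one candidate."""

    record: ProteinRecord
    family: str  # FKBP | CYP | TIG
    assignment: OrthologAssignment | None
    mature_kda: int


def assign_names(
    candidates: Sequence[NamingInput],
    organism_prefix: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, ImmunophilinName]:
    """Deterministic naming of a candidate collection.

    Ortholog suffix when assigned, else the mature-mass kDa value;
    trigger-factor candidates are named ``<prefix>TIG``.  Suffix groups
    of two or more get letters a, b, c ... — by decreasing similarity to
    the ortholog for ortholog groups, by decreasing mean identity to the
    other group members for molecular-weight groups.  Input order never
    affects the result.
    """
    groups: dict[tuple[str, str], list[NamingInput]] = {}
    for cand in candidates:
        if cand.family == "TIG":
            key = ("TIG", "")
        elif cand.assignment is not None and cand.assignment.ortholog_id is not None:
            _, suffix = parse_name_suffix(cand.assignment.ortholog_id)
            key = (cand.family, suffix)
        else:
            key = (cand.family, str(cand.mature_kda))
        groups.setdefault(key, []).append(cand)

    names: dict[str, ImmunophilinName] = {}
    for (family, suffix), members in groups.items():
        if len(members) == 1:
            order = members
        elif members[0].assignment is not None and members[0].assignment.ortholog_id:
            order = sorted(
                members,
                key=lambda c: (-c.assignment.similarity_percent,
                               -c.assignment.identity_percent, c.record.id),
            )
        else:
            mean_ident = {}
            for c in members:
                others = [o for o in members if o is not c]
                mean_ident[c.record.id] = sum(
                    percent_identity(global_align(c.record, o.record, scheme)) for o in others
                ) / len(others)
            order = sorted(members, key=lambda c: (-mean_ident[c.record.id], c.record.id))
        for i, cand in enumerate(order):
            letter = chr(ord("a") + i) if len(order) > 1 else ""
            names[cand.record.id] = ImmunophilinName(organism_prefix, family, suffix, letter)
    rendered = [str(n) for n in names.values()]
    assert len(set(rendered)) == len(rendered), "name collision after lettering"
    return names
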