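"""Core record types shared by every pipeline stage.

A :class:`ProteinRecord` is the unit that flows through the whole
classification: an identifier, a free-text description, an uppercase
amino-acid sequence over the 20 standard residues plus ``X`` for
unknowns, and an organism tag (``"Os"``, ``"At"``, ``"Hs"`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Sequence alphabet: the 20 standard residues plus X (unknown/masked).
AA21 = AA20 + "X"
_VALID = frozenset(AA21)


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and organism tag."""

    id: str
    sequence: str
    description: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)} "
                f"(alphabet is the 20 standard residues plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSet:
    """The two human reference proteins and their key binding positions.

    Positions are 1-based on the reference protein's own numbering.
    ``fkbp_key_positions`` / ``cyp_key_positions`` are ordered
    ``(position, residue)`` tuples; the residue is the one the human
    reference carries at that position, against which conservation is
    scored.
    """

    fkbp_reference: ProteinRecord
    cyp_reference: ProteinRecord
    fkbp_key_positions: tuple[tuple[int, str], ...]
    cyp_key_positions: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        for ref, positions, label in (
            (self.fkbp_reference, self.fkbp_key_positions, "FKBP"),
            (self.cyp_reference, self.cyp_key_positions, "CYP"),
        ):
            last = 0
            for pos, res in positions:
                if pos <= last:
                    raise ValueError(f"{label} key positions not strictly increasing at {pos}")
                if pos > len(ref):
                    raise ValueError(f"{label} key position {pos} beyond reference length {len(ref)}")
                if ref.sequence[pos - 1] != res:
                    raise ValueError(
                        f"{label} reference residue mismatch at position {pos}: "
                        f"fixture says {res}, sequence has {ref.sequence[pos - 1]}"
                    )
                last = pos

    def reference(self, family: str) -> ProteinRecord:
        return {"FKBP": self.fkbp_reference, "CYP": self.cyp_reference}[family]

    def key_positions(self, family: str) -> tuple[tuple[int, str], ...]:
        return {"FKBP": self.fkbp_key_positions, "CYP": self.cyp_key_positions}[family]

    def key_residue_string(self, family: str) -> str:
        return "".join(res for _, res in self.key_positions(family))
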