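"""FASTA reading/writing and packaged reference fixtures.

The FASTA reader is deliberately strict: it reports the offending record
id and line number for malformed headers, empty bodies and illegal
characters, which is why it does not delegate to a permissive library
parser.  ``load_references`` returns the packaged human FKBP12 / CypA
proteins together with the key binding-site positions and validates them
against each other on every load.
"""

from __future__ import annotations

import os
from importlib import resources
from typing import Iterable, Sequence

from .records import ProteinRecord, ReferenceSet, SequenceError

_DATA = resources.files("immclass") / "data"


def read_fasta(path: str | os.PathLike, organism: str = "") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, line wraps joined and a single terminal
    ``*`` (stop) stripped.  Malformed input raises :class:`SequenceError`
    naming the record and the line where the problem starts.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        name = header.split(None, 1)
        rid = name[0] if name else ""
        desc = name[1] if len(name) > 1 else ""
        if not rid:
            raise SequenceError(f"line {header_line}: FASTA header with no identifier")
        if not seq:
            raise SequenceError(f"record {rid!r} (line {header_line}): empty sequence body")
        try:
            records.append(ProteinRecord(id=rid, sequence=seq, description=desc, organism=organism))
        except SequenceError as exc:
            raise SequenceError(f"line {header_line}: {exc}") from None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise SequenceError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line)
    flush()
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"{path}: duplicate record id(s) {dup}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    if not records:
        raise ValueError("write_fasta: empty record list")
    if width < 1:
        raise ValueError("write_fasta: width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _read_positions(name: str) -> tuple[tuple[int, str], ...]:
    out = []
    for line in (_DATA / name).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, res = line.split("\t")
        out.append((int(pos), res))
    return tuple(out)


def _read_packaged_fasta(name: str, organism: str) -> ProteinRecord:
    text = (_DATA / name).read_text()
    header, *body = [l.strip() for l in text.splitlines() if l.strip()]
    rid, _, desc = header[1:].partition(" ")
    return ProteinRecord(id=rid, sequence="".join(body).upper(), description=desc, organism=organism)


def load_references() -> ReferenceSet:
    """Load the packaged human FKBP12 / cyclophilin A reference fixtures.

    Deterministic and side-effect free; raises if a fixture is missing or
    a key-position residue disagrees with the reference sequence.
    """
    return ReferenceSet(
        fkbp_reference=_read_packaged_fasta("hFKBP12.fasta", "Hs"),
        cyp_reference=_read_packaged_fasta("hCYPA.fasta", "Hs"),
        fkbp_key_positions=_read_positions("fkbp_key_positions.tsv"),
        cyp_key_positions=_read_positions("cyp_key_positions.tsv"),
    )


def load_hydropathy() -> dict[str, float]:
    """Kyte-Doolittle hydropathy scale (packaged fixture)."""
    scale: dict[str, float] = {}
    for line in (_DATA / "kyte_doolittle.tsv").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    return scale


def table_fixture_text(family: str) -> str:
    """Verbatim text of the packaged key-residue table for a family."""
    return (_DATA / {"FKBP": "table_fkbp.tsv", "CYP": "table_cyp.tsv"}[family]).read_text()
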