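"""Heuristic detection of protein targeting signals.

Implements the signal repertoire read off immunophilin alignments:

* twin-arginine (Tat) chloroplast-lumen signals — an RR pair near the
  N-terminus followed by a hydrophobic stretch, optionally ending in an
  Ala-Xaa-Ala peptidase cleavage site (absence of the cleavage site
  implies a thylakoid-membrane-anchored mature protein);
* N-terminal hydrophobic ER signal sequences and C-terminal ER
  retention tetrapeptides (KDEL-like and the x-[SD]EL variants);
* mono- and bipartite nuclear localization signals (basic clusters).

A precedence rule combines the evidence into a single compartment call.
All thresholds are configurable; the defaults are chosen so that
canonical textbook signals are detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .records import ProteinRecord
from .seqio import load_hydropathy

CYTOSOL = "cytosol"
CHLOROPLAST_LUMEN = "chloroplast_lumen"
CHLOROPLAST_MEMBRANE = "chloroplast_membrane_anchored"
ER = "ER"
NUCLEUS = "nucleus"
UNASSIGNED = "unassigned"

_KD = load_hydropathy()


@dataclass(frozen=True)
class TatSignal:
    """Twin-arginine translocation signal evidence (1-based coordinates)."""

    rr_position: int                 # first Arg of the RR pair
    h_region: tuple[int, int]        # hydrophobic stretch span
    cleavage_site: int | None        # final Ala of the A-x-A motif
    anchored: bool                   # no cleavage site: membrane-anchored


@dataclass(frozen=True)
class SignalEvidence:
    signal_type: str
    start: int
    end: int
    detail: str = ""


@dataclass(frozen=True)
class TargetingCall:
    compartment: str
    evidence: tuple[SignalEvidence, ...]


def _seq(x: ProteinRecord | str) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else x


def _hydrophobic_run(
    seq: str, start0: int, h_min_len: int, h_min_mean: float, scale: dict[str, float]
) -> tuple[int, int] | None:
    """Greedy hydrophobic stretch starting at 0-based *start0*.

    Requires the first ``h_min_len`` residues to average at least
    ``h_min_mean``; then extends while the running mean stays above it.
    Returns a 1-based inclusive span or None.
    """
    if start0 + h_min_len > len(seq):
        return None
    total = sum(scale.get(c, 0.0) for c in seq[start0 : start0 + h_min_len])
    if total / h_min_len < h_min_mean:
        return None
    end0 = start0 + h_min_len - 1
    while end0 + 1 < len(seq):
        val = scale.get(seq[end0 + 1], 0.0)
        # extend only over residues that are themselves hydrophobic, so a
        # downstream polar cleavage region is not swallowed by the run
        if val <= 0 or (total + val) / (end0 + 2 - start0) < h_min_mean:
            break
        total += val
        end0 += 1
    return (start0 + 1, end0 + 1)


def detect_tat_signal(
    record: ProteinRecord | str,
    n_window: int = 80,
    hydropathy: dict[str, float] | None = None,
    h_min_len: int = 8,
    h_min_mean: float = 1.5,
    cleave_window: int = 30,
    rr_max_gap: int = 25,
    allow_kr_variants: bool = False,
) -> TatSignal | None:
    """Detect a twin-arginine signal in the N-terminal *n_window* residues.

    RR pairs are scanned left to right; the first pair followed (within
    ``rr_max_gap`` residues) by a hydrophobic stretch of at least
    ``h_min_len`` residues averaging ``h_min_mean`` on the hydropathy
    scale yields the signal.  An Ala-Xaa-Ala motif within
    ``cleave_window`` residues after the stretch gives the cleavage
    site; otherwise the protein is called membrane-anchored.
    """
    seq = _seq(record)
    scale = hydropathy if hydropathy is not None else _KD
    window = seq[: max(n_window, 2)]
    pairs = ("RR", "KR", "RK") if allow_kr_variants else ("RR",)
    for i in range(len(window) - 1):
        if window[i : i + 2] not in pairs:
            continue
        h_region = None
        for s0 in range(i + 2, min(i + 2 + rr_max_gap, len(seq))):
            h_region = _hydrophobic_run(seq, s0, h_min_len, h_min_mean, scale)
            if h_region:
                break
        if h_region is None:
            continue
        h_end0 = h_region[1] - 1
        cleavage = None
        zone_end = min(h_end0 + 1 + cleave_window, len(seq))
        # the Ala-x-Ala motif may begin on the trailing Ala of the
        # hydrophobic stretch itself, so allow a 2-residue overlap
        for j in range(max(h_end0 - 1, 0), zone_end - 2):
            if seq[j] == "A" and seq[j + 2] == "A":
                cleavage = j + 3  # 1-based final Ala
                break
        return TatSignal(
            rr_position=i + 1,
            h_region=h_region,
            cleavage_site=cleavage,
            anchored=cleavage is None,
        )
    return None


def detect_er_signal(
    record: ProteinRecord | str,
    n_window: int = 30,
    hydropathy: dict[str, float] | None = None,
    h_min_len: int = 8,
    h_min_mean: float = 1.5,
) -> tuple[int, int] | None:
    """N-terminal hydrophobic signal sequence (1-based span) or None."""
    seq = _seq(record)
    scale = hydropathy if hydropathy is not None else _KD
    for s0 in range(min(n_window, len(seq))):
        run = _hydrophobic_run(seq, s0, h_min_len, h_min_mean, scale)
        if run:
            return run
    return None


def detect_er_retention(record: ProteinRecord | str) -> str | None:
    """C-terminal ER retention tetrapeptide (x-[SD]EL or [KH]DEL) or None."""
    seq = _seq(record)
    if len(seq) < 4:
        return None
    tail = seq[-4:]
    if tail[1] in "SD" and tail[2:] == "EL":
        return tail
    if tail[0] in "KH" and tail[1:] == "DEL":
        return tail
    return None


def detect_nls(
    record: ProteinRecord | str,
    mono_window: int = 6,
    mono_min_basic: int = 4,
    bi_spacer: range = range(9, 13),
) -> list[tuple[int, int]]:
    """Nuclear localization signals: merged 1-based spans.

    Monopartite: any window of ``mono_window`` residues with at least
    ``mono_min_basic`` Lys/Arg.  Bipartite: two basic doublets whose
    spacer length falls in ``bi_spacer``.
    """
    seq = _seq(record)
    basic = [c in "KR" for c in seq]
    spans: list[tuple[int, int]] = []
    counts = [0] * (len(seq) + 1)
    for i, b in enumerate(basic):
        counts[i + 1] = counts[i] + b
    for s in range(len(seq) - mono_window + 1):
        if counts[s + mono_window] - counts[s] >= mono_min_basic:
            spans.append((s + 1, s + mono_window))
    doublets = [i for i in range(len(seq) - 1) if basic[i] and basic[i + 1]]
    for i in doublets:
        for j in doublets:
            spacer = j - (i + 2)
            if spacer in bi_spacer:
                spans.append((i + 1, j + 2))
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def predict_localization(
    record: ProteinRecord | str,
    tat: TatSignal | None,
    er_signal_present: bool,
    er_retention: str | None,
    nls: Sequence[tuple[int, int]],
) -> TargetingCall:
    """Combine signal evidence into a compartment call.

    Precedence: Tat with cleavage -> chloroplast lumen; Tat without ->
    chloroplast membrane-anchored; ER signal + retention -> ER; NLS
    (no Tat/ER) -> nucleus; otherwise cytosol.
    """
    seq = _seq(record)
    evidence: list[SignalEvidence] = []
    if tat is not None:
        evidence.append(SignalEvidence("tat_rr", tat.rr_position, tat.rr_position + 1, "RR"))
        evidence.append(SignalEvidence("tat_h_region", *tat.h_region, "hydrophobic stretch"))
        if tat.cleavage_site is not None:
            evidence.append(
                SignalEvidence("tat_cleavage", tat.cleavage_site - 2, tat.cleavage_site, "A-x-A")
            )
    if er_retention is not None:
        evidence.append(SignalEvidence("er_retention", len(seq) - 3, len(seq), er_retention))
    for s, e in nls:
        evidence.append(SignalEvidence("nls", s, e, "basic cluster"))

    if tat is not None:
        compartment = CHLOROPLAST_MEMBRANE if tat.anchored else CHLOROPLAST_LUMEN
    elif er_signal_present and er_retention is not None:
        compartment = ER
    elif nls:
        compartment = NUCLEUS
    else:
        compartment = CYTOSOL
    return TargetingCall(compartment=compartment, evidence=tuple(evidence))
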