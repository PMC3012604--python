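"""PPIase (FKBP / cyclophilin) domain detection and architecture calls.

Domain copies are found by iterative local alignment of each family's
reference domain (the full human FKBP12, itself a lone FKBP domain, and
human cyclophilin A) against the protein: take the best hit across both
families, mask its span with ``X`` (which scores below zero against
everything, keeping coordinates intact), and repeat until the
normalized score drops below threshold or ``max_copies`` is reached.
The normalized score is the raw local score divided by the reference's
self-score, so a verbatim reference copy scores exactly 1.0.

Architectures are classified single-domain (SD: exactly one catalytic
domain and nothing else) versus multiple-domain (MD).  Auxiliary
domains (TPR, CCD, CaM, RRM, WD40, U-box, zinc fingers, TM ...) are
accepted as externally supplied annotations; only the compositionally
defined Arg/Lys-rich region has an in-repo detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import DEFAULT_SCHEME, ScoringScheme, local_align
from .records import ProteinRecord, ReferenceSet

FAMILIES = ("FKBP", "CYP")


@dataclass(frozen=True)
class DomainHit:
    family: str
    start: int  # 1-based inclusive
    end: int
    raw_score: float
    normalized_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain hit with start > end")


@dataclass(frozen=True)
class AuxFeature:
    name: str
    start: int
    end: int


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    hits: tuple[DomainHit, ...]
    aux_features: tuple[AuxFeature, ...]
    sd_md: str

    @property
    def composition(self) -> str:
        """N-to-C composition string, e.g. ``FKBP×3+TPR+CaM``."""
        items = [(h.start, h.family) for h in self.hits] + [
            (f.start, f.name) for f in self.aux_features
        ]
        items.sort()
        parts: list[list] = []
        for _, label in items:
            if parts and parts[-1][0] == label:
                parts[-1][1] += 1
            else:
                parts.append([label, 1])
        return "+".join(lbl if n == 1 else f"{lbl}×{n}" for lbl, n in parts)


def scan_ppiase_domains(
    record: ProteinRecord | str,
    references: ReferenceSet,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_normalized: float = 0.3,
    max_copies: int = 4,
) -> list[DomainHit]:
    """Greedy iterative local scan for PPIase domain copies.

    Returns non-overlapping hits sorted by start; an empty list is a
    valid result.  Families compete: at each round the best normalized
    hit across FKBP and CYP references wins and its span is masked.
    """
    if not 0 < min_normalized <= 1:
        raise ValueError("min_normalized must be in (0, 1]")
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    refs = {fam: references.reference(fam).sequence for fam in FAMILIES}
    self_scores = {fam: scheme.self_score(refs[fam]) for fam in FAMILIES}
    masked = seq
    hits: list[DomainHit] = []
    for _ in range(max_copies):
        best: DomainHit | None = None
        for fam in FAMILIES:
            al = local_align(refs[fam], masked, scheme)
            if al.b_span is None:
                continue
            norm = al.score / self_scores[fam]
            cand = DomainHit(fam, al.b_span[0], al.b_span[1], al.score, norm)
            if (
                best is None
                or cand.normalized_score > best.normalized_score
                or (cand.normalized_score == best.normalized_score and cand.start < best.start)
            ):
                best = cand
        if best is None or best.normalized_score < min_normalized:
            break
        hits.append(best)
        masked = masked[: best.start - 1] + "X" * (best.end - best.start + 1) + masked[best.end :]
    hits.sort(key=lambda h: h.start)
    return hits


def select_representative_domain(hits: Sequence[DomainHit]) -> DomainHit:
    """The most conserved copy: maximal normalized score, ties by start."""
    if not hits:
        raise ValueError("select_representative_domain: no hits")
    return max(hits, key=lambda h: (h.normalized_score, -h.start))


def detect_rk_rich(
    record: ProteinRecord | str,
    window: int = 20,
    min_fraction: float = 0.4,
    min_length: int = 30,
) -> list[tuple[int, int]]:
    """Arg/Lys-rich regions: maximal runs in which every length-*window*
    subwindow has an R+K fraction of at least *min_fraction*, merged and
    trimmed to *min_length*.  1-based inclusive spans."""
    if window < 5:
        raise ValueError("window must be >= 5")
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if len(seq) < window:
        return []
    counts = [0] * (len(seq) + 1)
    for i, c in enumerate(seq):
        counts[i + 1] = counts[i] + (c in "RK")
    good = [
        counts[s + window] - counts[s] >= min_fraction * window
        for s in range(len(seq) - window + 1)
    ]
    spans: list[tuple[int, int]] = []
    run_start = None
    for s, ok in enumerate(good + [False]):
        if ok and run_start is None:
            run_start = s
        elif not ok and run_start is not None:
            spans.append((run_start + 1, s - 1 + window))
            run_start = None
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s + 1 >= min_length]


def classify_architecture(
    protein_id: str,
    hits: Sequence[DomainHit],
    aux_features: Sequence[AuxFeature] = (),
) -> DomainArchitecture:
    """SD iff exactly one PPIase hit and no auxiliary features; else MD."""
    sd = len(hits) == 1 and not aux_features
    return DomainArchitecture(
        protein_id=protein_id,
        hits=tuple(sorted(hits, key=lambda h: h.start)),
        aux_features=tuple(sorted(aux_features, key=lambda f: f.start)),
        sd_md="SD" if sd else "MD",
    )


def load_aux_features(path) -> dict[str, list[AuxFeature]]:
    """Read a tab-separated ``protein_id  feature  start  end`` file."""
    out: dict[str, list[AuxFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            pid, name, start, end = fields
            out.setdefault(pid, []).append(AuxFeature(name, int(start), int(end)))
    return out
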