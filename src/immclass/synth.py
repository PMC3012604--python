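"""Synthetic immunophilin-like families with machine-readable ground truth.

The generator emulates the structure of a plant immunophilin inventory:
a PPIase core (a mutated copy of human FKBP12 or cyclophilin A) with
independent per-site substitution rates at key binding positions
(``key_mutation_rate``) and elsewhere (``background_mutation_rate``);
optionally 2-3 domain copies separated by linkers, some of them
Arg/Lys-rich; and an implanted targeting signal drawn from a mix of
Tat (with or without an Ala-x-Ala cleavage site), ER (hydrophobic
leader plus C-terminal retention tetrapeptide), nuclear (basic
cluster), or none.  Substitutions are uniform over the 19 alternative
residues — the simplest null that still exercises the scoring; there
are no indels or site-rate heterogeneity, so detector boundary errors
come only from alignment end-clipping.

Signal geometry (spacer 2-10, hydrophobic run 8-15) matches the signal
detectors' defaults so every implanted positive is detectable by
construction, making recovery metrics interpretable as pipeline —
rather than generator — error.

All randomness flows from a single seed; the same seed reproduces the
FASTA and truth table byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import AA20, ProteinRecord, ReferenceSet
from .seqio import load_references
from .signals import predict_localization, TatSignal

_POLAR = "STNQGDE"        # spacers / guards: no basics, no Ala, no hydrophobics
_HYDROPHOBIC = "LVIF"     # Tat/ER hydrophobic runs (no Ala: keeps A-x-A unambiguous)
_LINKER = "GSTNQDE"       # neutral inter-domain linkers
_RK_FILL = "ADGES"


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 200
    fkbp_fraction: float = 0.6
    key_mutation_rate: float = 0.1
    background_mutation_rate: float = 0.1
    p_tat: float = 0.2
    p_tat_no_cleavage: float = 0.1
    p_er: float = 0.15
    p_nls: float = 0.15
    multi_domain_prob: float = 0.3
    copy_weights: tuple[float, float] = (0.7, 0.3)  # 2 vs 3 copies
    rk_linker_prob: float = 0.2
    n_ancestors_per_family: int = 1
    ancestor_divergence: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        probs = (self.p_tat, self.p_tat_no_cleavage, self.p_er, self.p_nls)
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1:
            raise ValueError("signal probabilities must be in [0,1] and sum to <= 1")
        for r in (self.key_mutation_rate, self.background_mutation_rate,
                  self.fkbp_fraction, self.multi_domain_prob, self.rk_linker_prob,
                  self.ancestor_divergence):
            if not 0 <= r <= 1:
                raise ValueError("rates and probabilities must lie in [0,1]")
        if self.n_proteins < 1 or self.n_ancestors_per_family < 1:
            raise ValueError("counts must be positive")

    @property
    def p_none(self) -> float:
        return 1 - self.p_tat - self.p_tat_no_cleavage - self.p_er - self.p_nls


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            key_sites: frozenset[int] = frozenset(), key_rate: float | None = None) -> str:
    out = list(seq)
    for i in range(len(seq)):
        r = key_rate if (key_rate is not None and i in key_sites) else rate
        if r > 0 and rng.random() < r:
            alternatives = [a for a in AA20 if a != seq[i]]
            out[i] = alternatives[int(rng.integers(19))]
    return "".join(out)


def _rand_str(alphabet: str, length: int, rng: np.random.Generator) -> str:
    return "".join(alphabet[int(rng.integers(len(alphabet)))] for _ in range(length))


@dataclass(frozen=True)
class SyntheticAncestor:
    name: str
    family: str
    sequence: str


def make_ancestors(config: GeneratorConfig, refs: ReferenceSet,
                   rng: np.random.Generator) -> list[SyntheticAncestor]:
    """Named ancestor cores: the unmutated references when divergence is 0,
    otherwise independently diverged copies (for ortholog-recovery runs)."""
    out = []
    for family in ("FKBP", "CYP"):
        core = refs.reference(family).sequence
        for k in range(config.n_ancestors_per_family):
            seq = _mutate(core, config.ancestor_divergence, rng)
            out.append(SyntheticAncestor(name=f"REF_{family}{k + 1}", family=family, sequence=seq))
    return out


def generate_family(
    config: GeneratorConfig, refs: ReferenceSet | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame, list[SyntheticAncestor]]:
    """Generate records plus a per-record ground-truth table.

    Truth columns: family, ancestor, n_domains, domain_spans (JSON,
    1-based inclusive), key residues of each domain copy (JSON),
    signal_type, Tat/NLS coordinates, rk_span, compartment, and the
    mutation rates used.
    """
    refs = refs or load_references()
    rng = np.random.default_rng(config.seed)
    ancestors = make_ancestors(config, refs, rng)
    by_family = {
        fam: [a for a in ancestors if a.family == fam] for fam in ("FKBP", "CYP")
    }
    key_sites = {
        fam: frozenset(p - 1 for p, _ in refs.key_positions(fam)) for fam in ("FKBP", "CYP")
    }
    signal_types = np.array(["tat", "tat_anchor", "er", "nls", "none"])
    signal_probs = np.array(
        [config.p_tat, config.p_tat_no_cleavage, config.p_er, config.p_nls, config.p_none]
    )

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for idx in range(config.n_proteins):
        family = "FKBP" if rng.random() < config.fkbp_fraction else "CYP"
        ancestor = by_family[family][int(rng.integers(len(by_family[family])))]
        sig = str(signal_types[int(rng.choice(len(signal_types), p=signal_probs))])
        n_copies = 1
        if rng.random() < config.multi_domain_prob:
            n_copies = 2 + int(rng.random() < config.copy_weights[1] /
                               (config.copy_weights[0] + config.copy_weights[1]))
        # N-terminal signal
        prefix = ""
        rr_pos = h_span = cleavage = nls_span = None
        retention = None
        if sig in ("tat", "tat_anchor"):
            spacer = _rand_str(_POLAR, int(rng.integers(2, 11)), rng)
            hrun = _rand_str(_HYDROPHOBIC, int(rng.integers(8, 16)), rng)
            gap = _rand_str(_POLAR, int(rng.integers(1, 6)), rng)
            prefix = "M" + spacer + "RR" + gap + hrun
            rr_pos = len("M" + spacer) + 1
            h_span = (rr_pos + 2 + len(gap), rr_pos + 1 + len(gap) + len(hrun))
            if sig == "tat":
                x = _POLAR[int(rng.integers(len(_POLAR)))]
                prefix += "A" + x + "A"
                cleavage = len(prefix)
            else:
                prefix += _rand_str(_POLAR, 4, rng)
        elif sig == "er":
            prefix = "M" + _rand_str(_HYDROPHOBIC, int(rng.integers(10, 15)), rng)
            retention = ("KDEL", "HDEL", "DSEL", "NSEL")[int(rng.integers(4))]

        # domain copies with linkers
        body = prefix
        spans: list[tuple[int, int]] = []
        key_res: list[str] = []
        rk_span = None
        for c in range(n_copies):
            if c > 0:
                if rk_span is None and rng.random() < config.rk_linker_prob:
                    n_link = int(rng.integers(30, 51))
                    link = "".join(
                        ("KR"[int(rng.integers(2))] if rng.random() < 0.7
                         else _RK_FILL[int(rng.integers(len(_RK_FILL)))])
                        for _ in range(n_link)
                    )
                    rk_span = (len(body) + 1, len(body) + n_link)
                else:
                    link = _rand_str(_LINKER, int(rng.integers(10, 26)), rng)
                body += link
            domain = _mutate(
                ancestor.sequence,
                config.background_mutation_rate,
                rng,
                key_sites=key_sites[family],
                key_rate=config.key_mutation_rate,
            )
            spans.append((len(body) + 1, len(body) + len(domain)))
            key_res.append(
                "".join(domain[p - 1] for p, _ in refs.key_positions(family))
            )
            body += domain
        if sig == "nls":
            body += _rand_str(_LINKER, int(rng.integers(3, 11)), rng)
            cluster = "P" + _rand_str("KR", int(rng.integers(4, 7)), rng) + "V"
            nls_span = (len(body) + 2, len(body) + len(cluster) - 1)
            body += cluster
        body += _rand_str(_LINKER, int(rng.integers(5, 21)), rng)
        if retention:
            body += retention

        rid = f"SYN{idx + 1:04d}"
        records.append(ProteinRecord(id=rid, sequence=body, organism="Syn"))
        tat = None
        if rr_pos is not None:
            tat = TatSignal(rr_pos, h_span, cleavage, cleavage is None)
        compartment = predict_localization(
            body, tat, sig == "er", retention, [nls_span] if nls_span else []
        ).compartment
        truth_rows.append(
            {
                "id": rid,
                "family": family,
                "ancestor": ancestor.name,
                "n_domains": n_copies,
                "domain_spans": json.dumps(spans),
                "key_residues": json.dumps(key_res),
                "signal_type": sig,
                "rr_position": rr_pos,
                "h_start": h_span[0] if h_span else None,
                "h_end": h_span[1] if h_span else None,
                "cleavage_site": cleavage,
                "nls_start": nls_span[0] if nls_span else None,
                "nls_end": nls_span[1] if nls_span else None,
                "er_retention": retention,
                "rk_start": rk_span[0] if rk_span else None,
                "rk_end": rk_span[1] if rk_span else None,
                "compartment": compartment,
                "key_mutation_rate": config.key_mutation_rate,
                "background_mutation_rate": config.background_mutation_rate,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("id")
    return records, truth, ancestors


def score_recovery(truth: pd.DataFrame, results: dict[str, dict]) -> dict[str, float]:
    """Compare pipeline output against generator ground truth.

    *results* maps record id to a dict with keys ``n_domains``,
    ``domain_spans`` (list of (start, end)), ``tat_detected`` (bool),
    ``compartment`` and optionally ``ortholog`` (assigned ancestor name
    or None).  Returns accuracy/sensitivity metrics in [0, 1] and the
    domain boundary MAE in residues (over records with the correct
    domain count).
    """
    if set(truth.index) != set(results):
        raise ValueError("record ids of truth and results differ")
    n = len(truth)
    count_ok = 0
    boundary_errors: list[float] = []
    tat_true = tat_detected_true = 0
    tat_false = tat_detected_false = 0
    compartment_ok = 0
    orth_total = orth_ok = 0
    for rid, row in truth.iterrows():
        res = results[rid]
        true_spans = json.loads(row["domain_spans"])
        if res["n_domains"] == row["n_domains"]:
            count_ok += 1
            for (ts, te), (ps, pe) in zip(true_spans, res["domain_spans"]):
                boundary_errors.append(abs(ts - ps))
                boundary_errors.append(abs(te - pe))
        is_tat = row["signal_type"] in ("tat", "tat_anchor")
        if is_tat:
            tat_true += 1
            tat_detected_true += bool(res["tat_detected"])
        else:
            tat_false += 1
            tat_detected_false += bool(res["tat_detected"])
        compartment_ok += res["compartment"] == row["compartment"]
        if "ortholog" in res:
            orth_total += 1
            orth_ok += res["ortholog"] == row["ancestor"]
    metrics = {
        "domain_count_accuracy": count_ok / n,
        "boundary_mae": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        "tat_sensitivity": tat_detected_true / tat_true if tat_true else float("nan"),
        "tat_fpr": tat_detected_false / tat_false if tat_false else float("nan"),
        "compartment_accuracy": compartment_ok / n,
    }
    if orth_total:
        metrics["ortholog_accuracy"] = orth_ok / orth_total
    return metrics
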