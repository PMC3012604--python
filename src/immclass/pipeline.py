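"""End-to-end immunophilin classification.

``classify`` runs the full chain on a set of protein records: PPIase
domain scan -> targeting signals -> compartment call -> key-residue
extraction on the most conserved domain copy -> conservation scoring ->
ortholog assignment -> naming -> per-family phylogeny, and renders the
inventory, conservation tables, Newick trees and a run log.  The same
inputs and configuration always produce byte-identical reports.

``recompute_paper_tables`` replays the conservation arithmetic over the
packaged rice/Arabidopsis residue tables and reports, row by row, where
the recomputed values agree with the printed ones; the handful of rows
whose printed numbers contradict their own printed residues are flagged,
not forced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import ScoringScheme
from .config import PipelineConfig
from .conservation import (
    ConservationResult,
    DittoRow,
    DittoTable,
    KeyResidueProfile,
    column_conservation,
    conserved_percent,
    pair_similarity_percent,
    parse_ditto_table,
    render_ditto_table,
)
from .domains import (
    AuxFeature,
    DomainArchitecture,
    classify_architecture,
    detect_rk_rich,
    scan_ppiase_domains,
    select_representative_domain,
)
from .nomenclature import (
    ImmunophilinName,
    NamedReference,
    NamingInput,
    OrthologAssignment,
    assign_names,
    assign_ortholog,
    mature_mass_kda,
)
from .phylogeny import neighbor_joining, p_distance_matrix, progressive_msa, write_newick
from .records import ProteinRecord, ReferenceSet
from .seqio import load_references, table_fixture_text
from .signals import (
    TargetingCall,
    TatSignal,
    detect_er_retention,
    detect_er_signal,
    detect_nls,
    detect_tat_signal,
    predict_localization,
)


@dataclass(frozen=True)
class ClassifiedRecord:
    """One inventory row: a record with everything the pipeline derived."""

    record: ProteinRecord
    family: str  # FKBP | CYP | TIG | unassigned
    architecture: DomainArchitecture
    targeting: TargetingCall
    tat: TatSignal | None
    profile: KeyResidueProfile | None
    conservation: ConservationResult | None
    assignment: OrthologAssignment | None
    name: ImmunophilinName | None
    mature_mass_da: float
    mature_kda: int


@dataclass(frozen=True)
class ClassifyResult:
    classified: tuple[ClassifiedRecord, ...]
    reports: Mapping[str, str]
    failures: tuple[tuple[str, str], ...]  # (record id, error message)


def _classify_one(
    record: ProteinRecord,
    refs: ReferenceSet,
    config: PipelineConfig,
    aux: Sequence[AuxFeature],
) -> dict:
    scheme = config.scheme
    hits = scan_ppiase_domains(
        record, refs, scheme, min_normalized=config.min_normalized, max_copies=config.max_copies
    )
    rk_spans = detect_rk_rich(
        record, config.rk_window, config.rk_min_fraction, config.rk_min_length
    )
    aux = list(aux) + [AuxFeature("RK-rich", s, e) for s, e in rk_spans]
    is_tig = any(f.name.upper() == "TIG" for f in aux)
    family = "unassigned"
    if hits:
        best = select_representative_domain(hits)
        family = "TIG" if (is_tig and best.family == "FKBP") else best.family
    arch = classify_architecture(record.id, hits, [f for f in aux if f.name.upper() != "TIG"])

    tat = detect_tat_signal(
        record,
        n_window=config.tat_n_window,
        h_min_len=config.h_min_len,
        h_min_mean=config.h_min_mean,
        cleave_window=config.cleave_window,
        allow_kr_variants=config.allow_kr_variants,
    )
    er_signal = detect_er_signal(
        record, n_window=config.er_n_window,
        h_min_len=config.h_min_len, h_min_mean=config.h_min_mean,
    )
    er_ret = detect_er_retention(record)
    nls = detect_nls(record, config.mono_window, config.mono_min_basic, config.bi_spacer)
    targeting = predict_localization(record, tat, er_signal is not None, er_ret, nls)

    profile = conservation = None
    if hits:
        rep = select_representative_domain(hits)
        rep_family = rep.family
        sub = ProteinRecord(
            id=record.id,
            sequence=record.sequence[rep.start - 1 : rep.end],
            description=record.description,
            organism=record.organism,
        )
        from .conservation import extract_key_residues

        profile = extract_key_residues(
            sub, refs.reference(rep_family), refs.key_positions(rep_family),
            scheme, family=rep_family,
        )
        conservation = conserved_percent(profile, refs)

    cleavage = tat.cleavage_site if (tat and tat.cleavage_site) else (
        er_signal[1] if (er_signal and er_ret) else None
    )
    if cleavage is not None and cleavage >= len(record):
        cleavage = None
    kda, mass = mature_mass_kda(record, cleavage)
    return {
        "record": record,
        "family": family,
        "architecture": arch,
        "targeting": targeting,
        "tat": tat,
        "profile": profile,
        "conservation": conservation,
        "mature_kda": kda,
        "mature_mass_da": mass,
    }


def classify(
    records: Sequence[ProteinRecord],
    named_references: Sequence[NamedReference] = (),
    aux_features: Mapping[str, Sequence[AuxFeature]] | None = None,
    config: PipelineConfig | None = None,
    refs: ReferenceSet | None = None,
    build_trees: bool = True,
) -> ClassifyResult:
    """Classify a record collection end to end.

    Per-record failures are collected and reported, never silently
    dropped; an empty input is an error.
    """
    if not records:
        raise ValueError("classify: no input records")
    config = config or PipelineConfig()
    refs = refs or load_references()
    aux_features = aux_features or {}
    scheme = config.scheme

    partial: list[dict] = []
    failures: list[tuple[str, str]] = []
    for record in records:
        try:
            partial.append(
                _classify_one(record, refs, config, aux_features.get(record.id, ()))
            )
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            failures.append((record.id, str(exc)))

    # orthology + naming over the whole collection
    for item in partial:
        if named_references and item["family"] in ("FKBP", "CYP"):
            item["assignment"] = assign_ortholog(
                item["record"],
                item["targeting"].compartment,
                item["architecture"].composition,
                named_references,
                id_threshold=config.id_threshold,
                scheme=scheme,
            )
        else:
            item["assignment"] = None
    naming_inputs = [
        NamingInput(
            record=item["record"],
            family=item["family"] if item["family"] != "unassigned" else "FKBP",
            assignment=item["assignment"],
            mature_kda=item["mature_kda"],
        )
        for item in partial
    ]
    names = assign_names(naming_inputs, config.organism_prefix, scheme)

    classified = tuple(
        ClassifiedRecord(
            record=item["record"],
            family=item["family"],
            architecture=item["architecture"],
            targeting=item["targeting"],
            tat=item["tat"],
            profile=item["profile"],
            conservation=item["conservation"],
            assignment=item["assignment"],
            name=names.get(item["record"].id),
            mature_mass_da=item["mature_mass_da"],
            mature_kda=item["mature_kda"],
        )
        for item in partial
    )

    reports = dict(_render_reports(classified, refs, config, build_trees))
    reports["log"] = _render_log(classified, failures, config)
    return ClassifyResult(classified=classified, reports=reports, failures=tuple(failures))


def _render_reports(
    classified: Sequence[ClassifiedRecord],
    refs: ReferenceSet,
    config: PipelineConfig,
    build_trees: bool,
) -> dict[str, str]:
    rows = []
    for c in classified:
        rows.append(
            {
                "id": c.record.id,
                "name": str(c.name) if c.name else "",
                "family": c.family,
                "class": c.architecture.sd_md,
                "composition": c.architecture.composition,
                "localization": c.targeting.compartment,
                "mature_kda": c.mature_kda,
                "conserved_percent": c.conservation.percent if c.conservation else "",
                "key_residues": c.profile.residues if c.profile else "",
                "ortholog": c.assignment.ortholog_id if c.assignment and c.assignment.ortholog_id else "",
                "identity_percent": round(c.assignment.identity_percent, 1) if c.assignment and c.assignment.ortholog_id else "",
            }
        )
    inventory = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    reports = {"inventory": inventory}

    for family in ("FKBP", "CYP"):
        members = [c for c in classified if c.family == family and c.profile is not None]
        if members:
            table = DittoTable(
                family=family,
                rows=tuple(
                    DittoRow(
                        name_1=str(c.name) if c.name else c.record.id,
                        name_2="",
                        profile_1=KeyResidueProfile(
                            c.profile.protein_id, family, c.profile.residues, c.profile.positions
                        ),
                        profile_2=None,
                        printed_conserved_1=None,
                        printed_conserved_2=None,
                        printed_similarity=None,
                    )
                    for c in members
                ),
                printed_column_conserved=(),
            )
            reports[f"conservation_{family}"] = render_ditto_table(table, refs, recompute=True)
        if build_trees and len(members) >= 3:
            # multi-domain members contribute their most conserved domain
            # copy; aligning repeat architectures full length can put two
            # single-domain proteins on different copies (no shared columns)
            leaves = []
            for c in members:
                rep = select_representative_domain(c.architecture.hits)
                seq = (
                    c.record.sequence[rep.start - 1 : rep.end]
                    if len(c.architecture.hits) > 1
                    else c.record.sequence
                )
                leaves.append(ProteinRecord(c.record.id, seq, organism=c.record.organism))
            msa = progressive_msa(leaves, config.scheme)
            tree = neighbor_joining(p_distance_matrix(msa))
            reports[f"tree_{family}"] = write_newick(tree) + "\n"
    return reports


def _render_log(classified, failures, config: PipelineConfig) -> str:
    out = io.StringIO()
    out.write("immclass run log\n")
    for key, value in sorted(vars(config).items()):
        out.write(f"config {key} = {value}\n")
    out.write(f"records classified: {len(classified)}\n")
    for c in classified:
        out.write(
            f"{c.record.id}\tfamily={c.family}\tclass={c.architecture.sd_md}"
            f"\tlocalization={c.targeting.compartment}\tname={c.name}\n"
        )
    for rid, msg in failures:
        out.write(f"FAILED {rid}: {msg}\n")
    return out.getvalue()


# --------------------------------------------------------------------------
# Printed-table recomputation


#: Rows/columns of the packaged tables whose printed value contradicts the
#: printed residues themselves (audited once; flagged, never forced).
KNOWN_INCONSISTENT_ROWS = {
    "FKBP": ("OsFKBP15-2", "OsFKBP20-1b", "OsFKBP53", "OsFKBP58", "OsFKBP73"),
    "CYP": ("OsCYP19-4", "OsCYP21-4", "OsCYP95"),
}
KNOWN_INCONSISTENT_COLUMNS = {
    "FKBP": (43, 47, 56, 57, 82, 83, 92, 100),
    "CYP": (54, 55, 60, 111, 113, 121, 126),
}


def recompute_paper_tables(
    family: str, refs: ReferenceSet | None = None
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Recompute the Conserved / Similarity columns of a packaged table.

    Returns (rendered table with recomputed statistics, per-row report,
    per-column report).  The row report has one row per first-organism
    profile with printed vs recomputed conserved percent and similarity;
    ``flag`` marks disagreements, ``known_inconsistency`` marks the rows
    in the audited list.
    """
    refs = refs or load_references()
    table = parse_ditto_table(table_fixture_text(family), refs, family)
    rendered = render_ditto_table(table, refs, recompute=True)

    rows = []
    for row in table.rows:
        if row.profile_1 is None:
            continue
        rec = conserved_percent(row.profile_1, refs).percent
        sim = (
            pair_similarity_percent(row.profile_1, row.profile_2)
            if row.profile_2 is not None
            else None
        )
        mismatch = (
            row.printed_conserved_1 is not None and rec != row.printed_conserved_1
        ) or (
            row.printed_similarity is not None and sim is not None
            and sim != row.printed_similarity
        )
        rows.append(
            {
                "name": row.name_1,
                "printed_conserved": row.printed_conserved_1,
                "recomputed_conserved": rec,
                "printed_similarity": row.printed_similarity,
                "recomputed_similarity": sim,
                "flag": bool(mismatch),
                "known_inconsistency": row.name_1 in KNOWN_INCONSISTENT_ROWS[family],
            }
        )
    row_report = pd.DataFrame(rows).set_index("name")

    profiles = table.profiles_1()
    cols = []
    for i, (pos, _) in enumerate(refs.key_positions(family)):
        rec = column_conservation(profiles, i, refs)
        printed = (
            table.printed_column_conserved[i][0] if table.printed_column_conserved else None
        )
        cols.append(
            {
                "position": pos,
                "printed": printed,
                "recomputed": rec,
                "flag": printed is not None and rec != printed,
                "known_inconsistency": pos in KNOWN_INCONSISTENT_COLUMNS[family],
            }
        )
    col_report = pd.DataFrame(cols).set_index("position")
    return rendered, row_report, col_report
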