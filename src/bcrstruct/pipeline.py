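"""End-to-end orchestration: raw repertoires -> annotated study results.

Chains the stages in their natural order: numbering + viability filters,
canonical class assignment, template library clustering, ESS cutoff
calibration, per-sequence template prediction, repertoire quality filters,
usage profiles, the embedding/sweep, and the stem categorization per
(B-cell type, isotype) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import canonical, fread, loopgeom, profiles, seqqc, stems
from .seqqc import GermlineReference, NumberedSequence, QcReport, RawSequenceRecord
from .synthdata import StudyData
from .templates import TemplateLibrary


@dataclass
class StudyResult:
    clusters: loopgeom.TemplateClusterSet
    cutoffs: fread.LengthBinCutoffs
    repertoires: list[profiles.Repertoire]
    qc_reports: dict[str, QcReport]
    usage_profiles: list[profiles.UsageProfile]       # after quality filters
    removed: list[tuple[str, str]]
    sweep: profiles.SweepResult | None
    ledgers: dict[tuple[str, str], stems.UsageCategoryLedger]
    entropy: dict[str, profiles.EntropyResult] = field(default_factory=dict)
    category_coverage: dict[str, dict[str, float]] = field(default_factory=dict)


def annotate_repertoire(
    meta: dict,
    records: list[RawSequenceRecord],
    germlines: GermlineReference,
    library: TemplateLibrary,
    clusters: loopgeom.TemplateClusterSet,
    db: canonical.CanonicalClassDb | None,
    model: fread.EssModel,
    cutoffs: fread.LengthBinCutoffs,
    cfg: profiles.AnalysisConfig,
) -> tuple[profiles.Repertoire, QcReport]:
    """Run one repertoire through numbering, canonical and template stages."""
    report = QcReport()
    qc_cfg = seqqc.SeqQcConfig(
        min_cdrh3=cfg.cdrh3_len_min, max_cdrh3=cfg.cdrh3_len_max
    )
    numbered = seqqc.number_repertoire(records, germlines, qc_cfg, report)
    in_range = seqqc.select_modellable(
        numbered, cfg.cdrh3_len_min, cfg.cdrh3_len_max, report
    )
    preds = fread.predict_repertoire(in_range, library, model, cutoffs)
    if db is not None:
        h1 = canonical.assign_canonical_batch(
            [s.cdrh1_seq for s in in_range], "H1", db
        )
        h2 = canonical.assign_canonical_batch(
            [s.cdrh2_seq for s in in_range], "H2", db
        )
    else:
        h1 = h2 = [None] * len(in_range)
    annots = []
    for s, p, a1, a2 in zip(in_range, preds, h1, h2):
        cid = clusters.cluster_of(p.template_id) if p.template_id else None
        p.cluster_id = cid
        annots.append(
            profiles.SequenceAnnotation(
                sequence_id=s.id,
                cdrh3_len=len(s.cdrh3_seq),
                v_mutation_count=s.v_mutation_count,
                v_aligned_len=sum(
                    1 for pos in s.positions if int(pos.split(".")[0]) <= 104
                ),
                template_id=p.template_id,
                cluster_id=cid,
                template_species=(
                    library[p.template_id].species if p.template_id else None
                ),
                h1_class=a1.class_id if a1 else None,
                h2_class=a2.class_id if a2 else None,
            )
        )
    rep = profiles.Repertoire(
        repertoire_id=str(meta["repertoire_id"]),
        subject=str(meta.get("subject", "")),
        species=str(meta.get("species", "")),
        b_cell_type=str(meta.get("b_cell_type", "")),
        isotype=str(meta.get("isotype", "")),
        records=annots,
    )
    return rep, report


def run_study(
    study: StudyData,
    cfg: profiles.AnalysisConfig | None = None,
    reference_b_cell_type: str | None = None,
    canonical_db: canonical.CanonicalClassDb | None = None,
) -> StudyResult:
    """Full pipeline over an in-memory study.

    `reference_b_cell_type` names the antigen-unexperienced group used as
    the joining reference in the DBSCAN sweep (defaults to the first
    group's B-cell type).  A canonical class database trained on the
    study's germline CDR-H1/H2 loops is built unless one is supplied.
    """
    cfg = cfg or profiles.AnalysisConfig()
    library = study.library
    germlines = study.germlines
    clusters = loopgeom.cluster_templates(library, cfg.rmsd_cluster_threshold)
    cutoffs = fread.calibrate_ess_cutoffs(
        [library[t] for t in library.template_ids], library
    )
    if canonical_db is None:
        canonical_db = train_germline_canonical_db(germlines)
    model = fread.EssModel.default()
    reps: list[profiles.Repertoire] = []
    qc: dict[str, QcReport] = {}
    for meta, records in study.repertoires:
        rep, report = annotate_repertoire(
            meta, records, germlines, library, clusters,
            canonical_db, model, cutoffs, cfg,
        )
        reps.append(rep)
        qc[rep.repertoire_id] = report
    all_profiles = [profiles.usage_profile(r) for r in reps]
    retained, removed = profiles.filter_repertoires(all_profiles, cfg)
    retained_ids = {p.repertoire_id for p in retained}
    sweep = None
    if len(retained) >= 2:
        matrix = profiles.usage_matrix(retained)
        ref_type = reference_b_cell_type or reps[0].b_cell_type
        reference_ids = [
            p.repertoire_id for p in retained
            if _b_cell_type_of(p, reps) == ref_type
        ]
        sweep = profiles.embed_and_sweep(matrix, cfg, reference_ids)
    ledgers: dict[tuple[str, str], stems.UsageCategoryLedger] = {}
    template_lengths = {t: library[t].length for t in library.template_ids}
    groups: dict[tuple[str, str], list[profiles.Repertoire]] = {}
    for r in reps:
        if r.repertoire_id in retained_ids:
            groups.setdefault(r.group, []).append(r)
    prof_by_id = {p.repertoire_id: p for p in retained}
    cat_cov: dict[str, dict[str, float]] = {}
    for group, greps in sorted(groups.items()):
        if len(greps) < 2:
            continue
        spec = stems.randomization_spec_from_group(
            greps, randomized_size=cfg.randomized_size, rng_seed=cfg.rng_seed
        )
        randomized = stems.build_randomized_dataset(spec, clusters, template_lengths)
        observed = [prof_by_id[r.repertoire_id] for r in greps]
        ledger = stems.classify_cluster_usage(observed, randomized, cfg.alpha)
        ledgers[group] = ledger
        for p in observed:
            cat_cov[p.repertoire_id] = stems.category_coverage(p, ledger)
    entropy = {p.repertoire_id: profiles.entropy_stats(p) for p in retained}
    return StudyResult(
        clusters=clusters,
        cutoffs=cutoffs,
        repertoires=reps,
        qc_reports=qc,
        usage_profiles=retained,
        removed=removed,
        sweep=sweep,
        ledgers=ledgers,
        entropy=entropy,
        category_coverage=cat_cov,
    )


def _b_cell_type_of(p: profiles.UsageProfile, reps: list[profiles.Repertoire]) -> str:
    for r in reps:
        if r.repertoire_id == p.repertoire_id:
            return r.b_cell_type
    return ""


def train_germline_canonical_db(
    germlines: GermlineReference,
) -> canonical.CanonicalClassDb:
    """Canonical class database from the germline CDR-H1/H2 loops.

    Each germline loop founds its own class (named for loop kind, length
    and an ordinal letter), the desk-scale stand-in for a curated canonical
    class database.
    """
    labelled = []
    seen: dict[tuple[str, str], str] = {}
    counters: dict[tuple[str, int], int] = {}
    for name in germlines.names:
        for loop, seq in (
            ("H1", germlines.cdr1_seq(name)),
            ("H2", germlines.cdr2_seq(name)),
        ):
            key = (loop, seq)
            if key not in seen:
                n = counters.get((loop, len(seq)), 0)
                counters[(loop, len(seq))] = n + 1
                seen[key] = f"{loop}-{len(seq)}-{chr(ord('A') + n)}"
            labelled.append((loop, seq, seen[key]))
    return canonical.build_canonical_db(labelled)


def annotations_table(result: StudyResult) -> pd.DataFrame:
    """Flat per-sequence annotation table across all repertoires."""
    rows = []
    for rep in result.repertoires:
        for r in rep.records:
            rows.append(
                (rep.repertoire_id, r.sequence_id, r.cdrh3_len,
                 r.v_mutation_count, r.template_id or "", r.cluster_id or "",
                 r.h1_class or "", r.h2_class or "")
            )
    return pd.DataFrame(
        rows,
        columns=["repertoire_id", "sequence_id", "cdrh3_len",
                 "v_mutation_count", "template_id", "cluster_id",
                 "h1_class", "h2_class"],
    )
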