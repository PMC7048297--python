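"""ESS scoring, template prediction and cutoff calibration."""

import math

import numpy as np
import pytest

from bcrstruct.fread import (
    EssModel,
    LengthBinCutoffs,
    calibrate_ess_cutoffs,
    ess_score,
    framework_sequence,
    predict_cdrh3,
    predict_repertoire,
    prediction_precision,
    predictions_frame,
)
from bcrstruct.imgt import AA20
from bcrstruct.loopgeom import BackboneLoop
from bcrstruct.seqqc import number_repertoire
from bcrstruct.synthdata import GroupDesign, generate_repertoire
from bcrstruct.templates import TemplateLibrary, TemplateRecord

from conftest import random_loop


def _identity_model() -> EssModel:
    return EssModel(table=np.eye(20))


def _template(tid, seq, loop=None, fw="QVQLV", species="human"):
    rng = np.random.default_rng(abs(hash(tid)) % 2**31)
    return TemplateRecord(
        template_id=tid,
        cdrh3_seq=seq,
        loop=loop if loop is not None else random_loop(rng, len(seq)),
        species=species,
        framework_seq=fw,
    )


# ---------------------------------------------------------------------------
# ess_score


def test_ess_identity_table_counts_matches():
    m = _identity_model()
    t = _template("x_A", "ACDEFGHK")
    assert ess_score("ACDEFGHK", t, m) == pytest.approx(8.0)
    assert ess_score("ACDEFGHW", t, m) == pytest.approx(7.0)


def test_ess_matches_manual_summation_oracle():
    rng = np.random.default_rng(0)
    model = EssModel.default()
    for _ in range(20):
        q = "".join(AA20[i] for i in rng.integers(0, 20, 10))
        s = "".join(AA20[i] for i in rng.integers(0, 20, 10))
        manual = sum(
            float(model.table[AA20.index(a), AA20.index(b)])
            for a, b in zip(q, s)
        )
        assert ess_score(q, _template("y_A", s), model) == pytest.approx(manual)


def test_ess_symmetric_under_symmetric_table():
    model = EssModel.default()
    a, b = "ACDEFYWK", "KWYFEDCA"
    assert ess_score(a, _template("z_A", b), model) == pytest.approx(
        ess_score(b, _template("z_A", a), model)
    )


def test_ess_length_mismatch_fatal():
    with pytest.raises(ValueError):
        ess_score("ACDEF", _template("w_A", "ACDEFG"), _identity_model())


def test_default_model_diagonal_dominant():
    t = EssModel.default().table
    assert np.all(t.diagonal()[:, None] >= t)


def test_model_file_roundtrip(tmp_path):
    m = EssModel.default()
    p = tmp_path / "ess.tsv"
    m.to_file(p)
    assert np.array_equal(EssModel.from_file(p).table, m.table)


# ---------------------------------------------------------------------------
# prediction


def _numbered_from(germlines, library, families, n=80, shm=0.0, seed=3):
    group = GroupDesign("naive", "IGHM", 1, n, 5.0, True, (), 1.0, shm)
    recs, manifest = generate_repertoire(
        group, library, families, germlines, seed=seed, repertoire_id="r0"
    )
    return number_repertoire(recs, germlines), manifest


def test_exact_match_predicted(germlines, small_library):
    library, families = small_library
    numbered, manifest = _numbered_from(germlines, library, families, n=40)
    truth = dict(zip(manifest.sequence_id, manifest.template_id))
    cutoffs = LengthBinCutoffs()  # permissive
    preds = predict_repertoire(numbered, library, EssModel.default(), cutoffs)
    for s, p in zip(numbered, preds):
        assert p.template_id is not None
        assert len(library[p.template_id].cdrh3_seq) == len(s.cdrh3_seq)


def test_clone_family_accuracy_unmutated(germlines, small_library):
    """Unmutated clones map back to their source template's shape family."""
    library, families = small_library
    fam_of = {t: f for f, ts in families.items() for t in ts}
    numbered, manifest = _numbered_from(germlines, library, families, n=120)
    truth = dict(zip(manifest.sequence_id, manifest.family_id))
    preds = predict_repertoire(
        numbered, library, EssModel.default(), LengthBinCutoffs()
    )
    assert all(fam_of[p.template_id] == truth[p.sequence_id] for p in preds)


def test_cutoff_above_max_gives_none(germlines, small_library):
    library, families = small_library
    numbered, _ = _numbered_from(germlines, library, families, n=10)
    cutoffs = LengthBinCutoffs(cutoffs=(math.inf, math.inf, math.inf))
    preds = predict_repertoire(numbered, library, EssModel.default(), cutoffs)
    assert all(p.template_id is None for p in preds)


def test_equal_scores_take_lexicographically_smaller_template(germlines):
    rng = np.random.default_rng(4)
    loop = random_loop(rng, 8)
    lib = TemplateLibrary(templates={
        "b000_A": _template("b000_A", "ACDEFGHK", loop),
        "a000_A": _template("a000_A", "ACDEFGHK", loop),
    })
    from bcrstruct.seqqc import RawSequenceRecord, number_and_filter
    name = germlines.names[0]
    raw = RawSequenceRecord(
        "q", germlines.ungapped(name) + "ACDEFGHK" + germlines.j_tail
    )
    seq = number_and_filter(raw, germlines)
    p = predict_cdrh3(seq, lib, EssModel.default(), LengthBinCutoffs())
    assert p.template_id == "a000_A"


def test_coverage_monotone_in_cutoff(germlines, small_library):
    library, families = small_library
    numbered, _ = _numbered_from(germlines, library, families, n=200, shm=0.05)
    model = EssModel.default()
    cov = []
    for c in (-math.inf, 20.0, 40.0, 60.0, math.inf):
        cutoffs = LengthBinCutoffs(cutoffs=(c, c, c))
        preds = predict_repertoire(numbered, library, model, cutoffs)
        cov.append(sum(1 for p in preds if p.template_id))
    assert cov == sorted(cov, reverse=True)


def test_prediction_determinism(germlines, small_library):
    library, families = small_library
    numbered, _ = _numbered_from(germlines, library, families, n=60, shm=0.03)
    model = EssModel.default()
    cutoffs = LengthBinCutoffs()
    f1 = predictions_frame(predict_repertoire(numbered, library, model, cutoffs))
    f2 = predictions_frame(predict_repertoire(numbered, library, model, cutoffs))
    assert f1.to_csv() == f2.to_csv()


# ---------------------------------------------------------------------------
# calibration


def _pair_library(n_pairs=6, length=8, seed=0, spread=30.0):
    """Families of two congruent templates; families far apart (RMSD 0 hits)."""
    rng = np.random.default_rng(seed)
    templates = {}
    for k in range(n_pairs):
        loop = BackboneLoop(random_loop(rng, length).coords + [spread * k, 0, 0])
        seq = "".join(AA20[i] for i in rng.integers(0, 20, length))
        for j in range(2):
            tid = f"p{k}{j}_A"
            templates[tid] = _template(tid, seq, loop, fw=f"FW{k}")
    return TemplateLibrary(templates=templates)


def test_calibration_zero_rmsd_bin_takes_min_score():
    lib = _pair_library()
    validation = [lib[t] for t in lib.template_ids]
    cutoffs = calibrate_ess_cutoffs(validation, lib, EssModel.default())
    # oracle: exhaustive scan over the observed top-hit score grid
    model = EssModel.default()
    scores = []
    for rec in validation:
        cands = [lib[t] for t in lib.template_ids
                 if t != rec.template_id and lib[t].length == rec.length]
        best = max(
            cands,
            key=lambda t: ( _fw_id(rec, t), ess_score(rec.cdrh3_seq, t, model)),
        )
        scores.append(ess_score(rec.cdrh3_seq, best, model))
    # every top hit is the congruent partner: RMSD 0, so the smallest grid
    # cutoff already meets the target and retains full coverage
    assert cutoffs.cutoff_for(8) == pytest.approx(min(scores))


def _fw_id(a, b):
    n = max(len(a.framework_seq), len(b.framework_seq))
    return sum(x == y for x, y in zip(a.framework_seq, b.framework_seq)) / n


def test_calibration_falls_back_to_coverage_rule():
    """All-singleton far-apart library: no cutoff reaches the RMSD target."""
    rng = np.random.default_rng(1)
    templates = {}
    for k in range(10):
        loop = BackboneLoop(random_loop(rng, 8).coords + [60.0 * k, 0, 0])
        seq = "".join(AA20[i] for i in rng.integers(0, 20, 8))
        tid = f"q{k}_A"
        templates[tid] = _template(tid, seq, loop)
    lib = TemplateLibrary(templates=templates)
    validation = [lib[t] for t in lib.template_ids]
    model = EssModel.default()
    cutoffs = calibrate_ess_cutoffs(validation, lib, model)
    # oracle: largest grid cutoff with coverage > 15%
    hits = []
    for rec in validation:
        cands = [lib[t] for t in lib.template_ids if t != rec.template_id]
        best = max(
            cands,
            key=lambda t: (_fw_id(rec, t), ess_score(rec.cdrh3_seq, t, model)),
        )
        hits.append(ess_score(rec.cdrh3_seq, best, model))
    grid = sorted(set(hits))
    want = max(c for c in grid if sum(h >= c for h in hits) / len(hits) > 0.15)
    assert cutoffs.cutoff_for(8) == pytest.approx(want)


def test_calibration_empty_bin_sentinel():
    lib = _pair_library(length=8)
    validation = [lib[t] for t in lib.template_ids]  # lengths 5-12 bin only
    cutoffs = calibrate_ess_cutoffs(validation, lib)
    assert cutoffs.cutoff_for(13) == math.inf
    assert cutoffs.cutoff_for(15) == math.inf


def test_cutoffs_file_roundtrip(tmp_path):
    c = LengthBinCutoffs(cutoffs=(12.5, 30.0, math.inf))
    p = tmp_path / "cutoffs.tsv"
    c.to_file(p)
    assert LengthBinCutoffs.from_file(p) == c


# ---------------------------------------------------------------------------
# precision


def test_precision_examples():
    lib = _pair_library(n_pairs=2)
    t0 = lib["p00_A"]
    from bcrstruct.fread import TemplatePrediction

    exact = [(TemplatePrediction("s", "p00_A", 1.0), t0.loop)] * 4
    assert prediction_precision(exact, lib) == pytest.approx(100.0)
    far = BackboneLoop(t0.loop.coords + np.random.default_rng(0).normal(0, 9, t0.loop.coords.shape))
    mixed = exact[:3] + [(TemplatePrediction("s", "p00_A", 1.0), far)]
    assert prediction_precision(mixed, lib) == pytest.approx(75.0)
    none_retained = [(TemplatePrediction("s", None, 0.0), t0.loop)]
    assert prediction_precision(none_retained, lib) is None
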