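"""Usage profiles, quality filters, diversity statistics and the sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcrstruct.profiles import (
    AnalysisConfig,
    Repertoire,
    SequenceAnnotation,
    UsageProfile,
    embed_and_sweep,
    entropy_stats,
    filter_repertoires,
    never_used_templates,
    sequence_descriptors,
    species_usage,
    subsampled_richness,
    usage_matrix,
    usage_profile,
)


def _profile(counts, n_total=None, rep_id="r", templates=None):
    n_mod = sum(counts.values())
    return UsageProfile(
        repertoire_id=rep_id,
        cluster_counts=dict(counts),
        template_counts=dict(templates or {}),
        n_modelled=n_mod,
        n_total_in_range=n_total if n_total is not None else n_mod,
    )


def _annot(i, cluster, template=None, length=10, mut=0, v_len=100, species=None):
    return SequenceAnnotation(
        sequence_id=f"s{i}", cdrh3_len=length, v_mutation_count=mut,
        v_aligned_len=v_len, template_id=template, cluster_id=cluster,
        template_species=species,
    )


def _repertoire(records, rep_id="r0", b_cell_type="naive"):
    return Repertoire(
        repertoire_id=rep_id, subject="s", species="human",
        b_cell_type=b_cell_type, isotype="IGHM", records=records,
    )


# ---------------------------------------------------------------------------
# usage profiles


def test_usage_profile_counts_and_coverage():
    recs = [_annot(i, "A", "tA") for i in range(4)]
    recs += [_annot(4 + i, "B", "tB") for i in range(3)]
    recs += [_annot(7 + i, None) for i in range(3)]
    p = usage_profile(_repertoire(recs))
    assert p.coverage == pytest.approx(0.7)
    assert p.frequencies["A"] == pytest.approx(4 / 7)
    assert sum(p.frequencies.values()) == pytest.approx(1.0)


def test_usage_profile_single_cluster():
    p = usage_profile(_repertoire([_annot(i, "A", "t") for i in range(5)]))
    assert p.frequencies == {"A": 1.0}


def test_usage_profile_empty():
    p = usage_profile(_repertoire([_annot(0, None)]))
    assert p.frequencies == {} and p.coverage == 0.0


# ---------------------------------------------------------------------------
# repertoire quality filters


def test_filter_redundancy_boundary():
    cfg = AnalysisConfig(min_modelled=10)
    at_limit = _profile({"A": 50, "B": 30, "C": 20})          # top2 = 0.80
    over = _profile({"A": 51, "B": 30, "C": 19}, rep_id="x")  # top2 = 0.81
    retained, removed = filter_repertoires([at_limit, over], cfg)
    assert [p.repertoire_id for p in retained] == ["r"]
    assert removed == [("x", "top2_redundancy")]


def test_filter_min_modelled_boundary():
    cfg = AnalysisConfig()
    small = _profile({c: 1 for c in map(str, range(9_999))}, rep_id="small")
    big = _profile({c: 1 for c in map(str, range(10_000))}, rep_id="big")
    retained, removed = filter_repertoires([small, big], cfg)
    assert [p.repertoire_id for p in retained] == ["big"]
    assert removed == [("small", "min_modelled")]


# ---------------------------------------------------------------------------
# entropy


def test_entropy_uniform_and_degenerate():
    uniform = _profile({c: 10 for c in "ABCD"})
    e = entropy_stats(uniform)
    assert e.H == pytest.approx(math.log(4))
    assert e.normalized == pytest.approx(1.0)
    single = entropy_stats(_profile({"A": 7}))
    assert single.H == 0.0 and single.normalized == 0.0
    half = entropy_stats(_profile({"A": 5, "B": 5}))
    assert half.H == pytest.approx(math.log(2))


def test_entropy_empty_profile_flagged():
    e = entropy_stats(_profile({}))
    assert e.flagged and e.normalized == 1.0 and e.richness == 0


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=1000), min_size=2, max_size=30))
def test_entropy_invariants(counts):
    p = _profile({f"c{i}": n for i, n in enumerate(counts)})
    e = entropy_stats(p)
    assert 0.0 <= e.H <= e.H_max + 1e-12
    assert 0.0 <= e.normalized <= 1.0 + 1e-12
    # relabeling clusters leaves H unchanged
    q = _profile({f"z{i}": n for i, n in enumerate(counts)})
    assert entropy_stats(q).H == pytest.approx(e.H)
    if len(set(counts)) == 1:
        assert e.normalized == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# subsampled richness


def test_richness_saturates_on_abundant_clusters():
    p = _profile({"A": 10_000, "B": 10_000, "C": 10_000})
    cfg = AnalysisConfig(subsample_size=10_000, n_subsamples=20)
    assert subsampled_richness(p, cfg) == pytest.approx(3.0)


def test_richness_full_sample_no_variance():
    p = _profile({"A": 600, "B": 300, "C": 100})
    cfg = AnalysisConfig(subsample_size=1000, n_subsamples=10)
    assert subsampled_richness(p, cfg) == pytest.approx(3.0)


def test_richness_too_small_directs_to_filter():
    with pytest.raises(ValueError):
        subsampled_richness(_profile({"A": 10}), AnalysisConfig())


def test_richness_matches_closed_form_oracle():
    """Planted richness-20 heavy-tail repertoire vs exact expectation.

    E[richness] = sum_i 1 - C(N - n_i, m) / C(N, m) for a subsample of m
    from counts n_i (hypergeometric inclusion-exclusion, computed
    independently of the resampling implementation).
    """
    rng = np.random.default_rng(5)
    counts = {f"c{i:02d}": int(np.ceil(30_000 * (i + 1) ** -2.2)) for i in range(20)}
    p = _profile(counts)
    N = sum(counts.values())
    m = 10_000
    from scipy.stats import hypergeom

    exact = sum(1 - hypergeom.pmf(0, N, n, m) for n in counts.values())
    cfg = AnalysisConfig(subsample_size=m, n_subsamples=100, rng_seed=17)
    assert subsampled_richness(p, cfg) == pytest.approx(exact, abs=0.5)


def test_richness_monotone_in_subsample_size():
    rng = np.random.default_rng(6)
    counts = {f"c{i}": int(v) for i, v in
              enumerate(rng.integers(1, 2000, size=15))}
    p = _profile(counts)
    means = [
        subsampled_richness(
            p, AnalysisConfig(subsample_size=m, n_subsamples=60, rng_seed=2)
        )
        for m in (50, 200, 1000)
        if m <= p.n_modelled
    ]
    assert means == sorted(means)
    assert all(m <= p.richness for m in means)


# ---------------------------------------------------------------------------
# species usage and descriptors


def test_species_usage_uniform_and_degenerate(small_library):
    library, families = small_library
    comp = library.species_composition()
    tids = library.template_ids
    counts = {t: 5 for t in tids}  # every template equally
    p = _profile({"A": 5 * len(tids)}, templates=counts)
    su = species_usage(p, library)
    assert su.expected == comp
    for sp, frac in comp.items():
        assert su.observed[sp] == pytest.approx(frac, abs=1e-9)
    mouse_only = [t for t in tids if library[t].species == "mouse"][:3]
    p2 = _profile({"A": 3}, templates={t: 1 for t in mouse_only})
    assert species_usage(p2, library).observed == {"mouse": 1.0}


def test_never_used_templates_matches_set_difference(small_library):
    library, _ = small_library
    used = library.template_ids[:50]
    profiles_ = [_profile({"A": 50}, templates={t: 1 for t in used})]
    want = sorted(set(library.template_ids) - set(used))
    assert never_used_templates(profiles_, library) == want


def test_sequence_descriptors():
    recs = [_annot(0, "A", length=12), _annot(1, "A", length=12)]
    assert sequence_descriptors(_repertoire(recs))[0] == pytest.approx(12.0)
    recs = [_annot(0, "A", length=10), _annot(1, "A", length=14)]
    assert sequence_descriptors(_repertoire(recs))[0] == pytest.approx(12.0)
    recs = [_annot(i, "A", mut=5, v_len=100) for i in range(4)]
    assert sequence_descriptors(_repertoire(recs))[1] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# embedding and sweep


def _matrix_from_rows(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_two_tight_groups_cluster_internally_first():
    rng = np.random.default_rng(7)
    a = np.array([0.5, 0.3, 0.2, 0.0])
    b = np.array([0.0, 0.1, 0.2, 0.7])
    rows = {}
    for i in range(3):
        rows[f"a{i}"] = a + rng.normal(0, 0.002, 4)
        rows[f"b{i}"] = b + rng.normal(0, 0.002, 4)
    cfg = AnalysisConfig(eps_grid=tuple(np.round(np.linspace(0.01, 1.0, 40), 4)))
    res = embed_and_sweep(
        _matrix_from_rows(rows), cfg, reference_ids=["a0", "a1", "a2"]
    )
    a_eps = max(res.join_eps[f"a{i}"] for i in range(3))
    b_eps = min(res.join_eps[f"b{i}"] for i in range(3))
    assert a_eps < b_eps
    # before any cross-group merge each group is internally clustered
    first = res.trace[res.trace.eps == cfg.eps_grid[0]]
    labels = dict(zip(first.repertoire_id, first.label))
    assert len({labels[f"a{i}"] for i in range(3)}) == 1
    assert len({labels[f"b{i}"] for i in range(3)}) == 1
    assert labels["a0"] != labels["b0"]


def test_identical_profiles_merge_at_smallest_eps():
    rows = {f"r{i}": [0.25, 0.25, 0.25, 0.25] for i in range(4)}
    cfg = AnalysisConfig()
    res = embed_and_sweep(_matrix_from_rows(rows), cfg)
    assert all(e == cfg.eps_grid[0] for e in res.join_eps.values())


def test_planted_ordering_recovered():
    """Group closer to the reference joins at smaller epsilon."""
    rng = np.random.default_rng(8)
    base = np.array([0.4, 0.3, 0.2, 0.1])
    shift_b = np.array([0.05, -0.05, 0.0, 0.0])
    shift_c = np.array([0.25, -0.15, -0.05, -0.05])
    rows = {}
    for i in range(3):
        rows[f"a{i}"] = base + rng.normal(0, 0.002, 4)
        rows[f"b{i}"] = base + shift_b + rng.normal(0, 0.002, 4)
        rows[f"c{i}"] = base + shift_c + rng.normal(0, 0.002, 4)
    # pairwise-distance oracle on the planted centroids
    assert np.linalg.norm(shift_b) < np.linalg.norm(shift_c)
    cfg = AnalysisConfig(eps_grid=tuple(np.round(np.linspace(0.005, 0.6, 120), 4)))
    res = embed_and_sweep(
        _matrix_from_rows(rows), cfg, reference_ids=["a0", "a1", "a2"]
    )
    join_b = max(res.join_eps[f"b{i}"] for i in range(3))
    join_c = min(res.join_eps[f"c{i}"] for i in range(3))
    assert join_b < join_c


def test_fewer_repertoires_than_min_pts_all_noise():
    rows = {"r0": [1.0, 0.0], "r1": [0.0, 1.0]}
    cfg = AnalysisConfig(dbscan_min_pts=3)
    res = embed_and_sweep(_matrix_from_rows(rows), cfg)
    assert (res.trace.label == -1).all()


def test_usage_matrix_and_pca_reproducible():
    p1 = _profile({"A": 3, "B": 1}, rep_id="r1")
    p2 = _profile({"B": 2, "C": 2}, rep_id="r2")
    m = usage_matrix([p1, p2])
    assert list(m.columns) == ["A", "B", "C"]
    assert m.loc["r1", "A"] == pytest.approx(0.75)
    assert m.loc["r2", "A"] == 0.0
    cfg = AnalysisConfig()
    r1 = embed_and_sweep(m, cfg)
    r2 = embed_and_sweep(m, cfg)
    assert np.allclose(r1.pca.to_numpy(), r2.pca.to_numpy())
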