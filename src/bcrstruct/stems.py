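"""Categorizing CDR-H3 cluster usage: Structural Stems vs random usage.

For each B-cell-type group, repertoire-matched randomized datasets are
built by resampling templates from each repertoire's own observed template
set, following its CDR-H3 length distribution thinned by the per-length
modellable proportion.  A one-sided Mann-Whitney rank test then compares
each cluster's relative usage in the real repertoires against the
randomized ones:

* STRUCTURAL_STEM    — significantly over-represented across repertoires,
* UNDER_REPRESENTED  — significantly under-represented,
* RANDOM_USAGE       — indistinguishable from random template sampling.

Structural Stems are the "public" loop shapes a B-cell type relies on
across individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .loopgeom import TemplateClusterSet
from .profiles import Repertoire, UsageProfile

STRUCTURAL_STEM = "STRUCTURAL_STEM"
RANDOM_USAGE = "RANDOM_USAGE"
UNDER_REPRESENTED = "UNDER_REPRESENTED"
CATEGORIES = (STRUCTURAL_STEM, RANDOM_USAGE, UNDER_REPRESENTED)


@dataclass
class RandomizationSpec:
    """Everything needed to build a group's randomized datasets.

    One entry per repertoire: its CDR-H3 length distribution (over
    in-range sequences), the group's per-length modellable proportion, and
    the templates observed in that repertoire (sampling never invents
    template usage a repertoire did not show).
    """

    group: tuple[str, str]
    length_dists: dict[str, dict[int, float]]       # rep_id -> length -> prob
    modellable_by_length: dict[int, float]          # length -> proportion
    allowed_templates: dict[str, list[str]]         # rep_id -> template_ids
    randomized_size: int
    rng_seed: int


def randomization_spec_from_group(
    reps: list[Repertoire],
    randomized_size: int = 1_000_000,
    rng_seed: int = 0,
) -> RandomizationSpec:
    """Derive the randomization inputs from a group's annotated repertoires."""
    if not reps:
        raise ValueError("group has no repertoires")
    group = reps[0].group
    length_dists: dict[str, dict[int, float]] = {}
    allowed: dict[str, list[str]] = {}
    len_total: dict[int, int] = {}
    len_modelled: dict[int, int] = {}
    for rep in reps:
        counts: dict[int, int] = {}
        tids: set[str] = set()
        for r in rep.records:
            counts[r.cdrh3_len] = counts.get(r.cdrh3_len, 0) + 1
            len_total[r.cdrh3_len] = len_total.get(r.cdrh3_len, 0) + 1
            if r.template_id is not None:
                tids.add(r.template_id)
                len_modelled[r.cdrh3_len] = len_modelled.get(r.cdrh3_len, 0) + 1
        n = sum(counts.values())
        length_dists[rep.repertoire_id] = {L: c / n for L, c in sorted(counts.items())}
        allowed[rep.repertoire_id] = sorted(tids)
    modellable = {
        L: len_modelled.get(L, 0) / t for L, t in sorted(len_total.items())
    }
    return RandomizationSpec(
        group=group,
        length_dists=length_dists,
        modellable_by_length=modellable,
        allowed_templates=allowed,
        randomized_size=randomized_size,
        rng_seed=rng_seed,
    )


def build_randomized_dataset(
    spec: RandomizationSpec,
    clusters: TemplateClusterSet,
    template_lengths: dict[str, int],
) -> list[UsageProfile]:
    """One randomized usage profile per repertoire of the group.

    For each repertoire, `randomized_size` template picks are drawn with
    replacement: lengths follow the repertoire's length distribution
    thinned by the per-length modellable proportion; within a length,
    templates are uniform over the repertoire's own observed set.  Picks
    aggregate to cluster frequencies (materialized as counts, never as
    explicit records).
    """
    rng = np.random.default_rng(spec.rng_seed)
    out: list[UsageProfile] = []
    for rep_id in sorted(spec.length_dists):
        by_len: dict[int, list[str]] = {}
        for tid in spec.allowed_templates[rep_id]:
            by_len.setdefault(template_lengths[tid], []).append(tid)
        tids: list[str] = []
        probs: list[float] = []
        for L, p_len in spec.length_dists[rep_id].items():
            w = p_len * spec.modellable_by_length.get(L, 0.0)
            pool = by_len.get(L, [])
            if w <= 0 or not pool:
                continue  # represented length with no usable template
            for t in pool:
                tids.append(t)
                probs.append(w / len(pool))
        if not tids:
            out.append(
                UsageProfile(
                    repertoire_id=f"randomized:{rep_id}",
                    cluster_counts={}, template_counts={},
                    n_modelled=0, n_total_in_range=0,
                )
            )
            continue
        p = np.array(probs)
        p /= p.sum()
        picks = rng.multinomial(spec.randomized_size, p)
        template_counts = {
            t: int(n) for t, n in zip(tids, picks) if n > 0
        }
        cluster_counts: dict[str, int] = {}
        for t, n in template_counts.items():
            cid = clusters.cluster_of(t)
            cluster_counts[cid] = cluster_counts.get(cid, 0) + n
        out.append(
            UsageProfile(
                repertoire_id=f"randomized:{rep_id}",
                cluster_counts=cluster_counts,
                template_counts=template_counts,
                n_modelled=spec.randomized_size,
                n_total_in_range=spec.randomized_size,
            )
        )
    return out


@dataclass(frozen=True)
class CategoryCall:
    category: str
    p_over: float
    p_under: float
    flagged: bool = False


@dataclass
class UsageCategoryLedger:
    """Per-cluster usage category for one (B-cell type, isotype) group."""

    group: tuple[str, str]
    calls: dict[str, CategoryCall]

    def stems(self) -> set[str]:
        return {c for c, call in self.calls.items()
                if call.category == STRUCTURAL_STEM}

    def category_of(self, cluster_id: str) -> str:
        call = self.calls.get(cluster_id)
        return call.category if call else RANDOM_USAGE

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.group[0], self.group[1], c, call.category,
             call.p_over, call.p_under)
            for c, call in sorted(self.calls.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["b_cell_type", "isotype", "cluster_id", "category",
                     "p_over", "p_under"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _one_sided_p(x: list[float], y: list[float], alternative: str) -> float:
    """Mann-Whitney p: exact null for small untied groups, else normal
    approximation with continuity correction (midranks handle ties)."""
    combined = list(x) + list(y)
    has_ties = len(set(combined)) != len(combined)
    if not has_ties and max(len(x), len(y)) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def classify_cluster_usage(
    observed: list[UsageProfile],
    randomized: list[UsageProfile],
    alpha: float = 0.05,
    fdr_correct: bool = False,
) -> UsageCategoryLedger:
    """Categorize every represented cluster of a group.

    Tests each cluster's per-repertoire relative usage against the matched
    randomized profiles, one-sided in both directions.  The two one-sided
    calls are mutually exclusive at any alpha < 0.5 (verified on every
    run).  `fdr_correct` applies Benjamini-Hochberg across clusters
    (off by default).
    """
    if len(observed) != len(randomized) or len(observed) < 2:
        raise ValueError("need matched observed/randomized groups of size >= 2")
    group = (observed[0].b_cell_type, observed[0].isotype)
    cluster_ids: set[str] = set()
    for p in observed + randomized:
        cluster_ids |= set(p.cluster_counts)
    obs_freqs = {c: [p.frequencies.get(c, 0.0) for p in observed]
                 for c in cluster_ids}
    rnd_freqs = {c: [p.frequencies.get(c, 0.0) for p in randomized]
                 for c in cluster_ids}
    p_over: dict[str, float] = {}
    p_under: dict[str, float] = {}
    flagged: set[str] = set()
    for c in sorted(cluster_ids):
        x, y = obs_freqs[c], rnd_freqs[c]
        if not any(x) and not any(y):
            p_over[c] = p_under[c] = 1.0
            flagged.add(c)
            continue
        p_over[c] = _one_sided_p(x, y, "greater")
        p_under[c] = _one_sided_p(x, y, "less")
    if fdr_correct:
        order = sorted(p_over)
        adj_over = stats.false_discovery_control([p_over[c] for c in order])
        adj_under = stats.false_discovery_control([p_under[c] for c in order])
        p_over = dict(zip(order, map(float, adj_over)))
        p_under = dict(zip(order, map(float, adj_under)))
    calls: dict[str, CategoryCall] = {}
    for c in sorted(cluster_ids):
        po, pu = p_over[c], p_under[c]
        if po <= alpha and pu <= alpha:
            raise AssertionError(
                f"cluster {c}: both one-sided tests significant — inconsistent"
            )
        if po <= alpha:
            cat = STRUCTURAL_STEM
        elif pu <= alpha:
            cat = UNDER_REPRESENTED
        else:
            cat = RANDOM_USAGE
        calls[c] = CategoryCall(cat, po, pu, flagged=c in flagged)
    return UsageCategoryLedger(group=group, calls=calls)


def category_coverage(
    profile: UsageProfile, ledger: UsageCategoryLedger
) -> dict[str, float]:
    """Fraction of a repertoire's predicted sequences per usage category."""
    totals = {cat: 0 for cat in CATEGORIES}
    for c, n in profile.cluster_counts.items():
        totals[ledger.category_of(c)] += n
    n_mod = sum(totals.values())
    if n_mod == 0:
        return {cat: 0.0 for cat in CATEGORIES}
    return {cat: totals[cat] / n_mod for cat in CATEGORIES}


def stem_overlap(
    ledger_a: UsageCategoryLedger, ledger_b: UsageCategoryLedger
) -> int:
    """Number of Structural Stem clusters shared between two groups."""
    return len(ledger_a.stems() & ledger_b.stems())
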