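"""Repertoire-level structural statistics.

Turns per-sequence annotations into per-repertoire usage profiles over
CDR-H3 structural clusters, applies the repertoire quality filters
(amplification-redundancy and minimum-sampling rules), and computes the
diversity statistics used to compare B-cell types: structural coverage,
subsampled cluster richness, Shannon entropy normalized to its theoretical
maximum, template species usage, and the PCA embedding plus DBSCAN
epsilon-sweep that orders repertoires by similarity of cluster usage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .templates import TemplateLibrary


def _default_eps_grid() -> tuple[float, ...]:
    return tuple(round(0.01 * k, 4) for k in range(1, 61))


@dataclass
class AnalysisConfig:
    """Fixed constants of the repertoire analysis protocol."""

    cdrh3_len_min: int = 5
    cdrh3_len_max: int = 16
    top2_redundancy_max: float = 0.80   # removal when strictly exceeded
    min_modelled: int = 10_000
    subsample_size: int = 10_000
    n_subsamples: int = 100
    randomized_size: int = 1_000_000
    alpha: float = 0.05
    rmsd_cluster_threshold: float = 0.6
    eps_grid: tuple[float, ...] = field(default_factory=_default_eps_grid)
    dbscan_min_pts: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if list(self.eps_grid) != sorted(set(self.eps_grid)):
            raise ValueError("eps_grid must be strictly increasing")


@dataclass(frozen=True)
class SequenceAnnotation:
    """Minimal per-sequence record consumed by repertoire statistics."""

    sequence_id: str
    cdrh3_len: int
    v_mutation_count: int
    v_aligned_len: int
    template_id: str | None
    cluster_id: str | None
    template_species: str | None = None
    h1_class: str | None = None
    h2_class: str | None = None


@dataclass
class Repertoire:
    """One BCR repertoire: study metadata plus annotated sequences."""

    repertoire_id: str
    subject: str
    species: str
    b_cell_type: str
    isotype: str
    records: list[SequenceAnnotation]

    @property
    def group(self) -> tuple[str, str]:
        return (self.b_cell_type, self.isotype)


@dataclass
class UsageProfile:
    """Relative cluster-usage vector of one repertoire, with coverage."""

    repertoire_id: str
    cluster_counts: dict[str, int]
    template_counts: dict[str, int]
    n_modelled: int
    n_total_in_range: int
    b_cell_type: str = ""
    isotype: str = ""

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_modelled == 0:
            return {}
        return {c: n / self.n_modelled for c, n in sorted(self.cluster_counts.items())}

    @property
    def coverage(self) -> float:
        if self.n_total_in_range == 0:
            return 0.0
        return self.n_modelled / self.n_total_in_range

    @property
    def richness(self) -> int:
        return sum(1 for n in self.cluster_counts.values() if n > 0)

    def top2_share(self) -> float:
        if self.n_modelled == 0:
            return 0.0
        top = sorted(self.cluster_counts.values(), reverse=True)[:2]
        return sum(top) / self.n_modelled


def usage_profile(rep: Repertoire) -> UsageProfile:
    """Cluster frequencies over predicted sequences + structural coverage."""
    cluster_counts: dict[str, int] = {}
    template_counts: dict[str, int] = {}
    n_mod = 0
    for r in rep.records:
        if r.cluster_id is not None:
            cluster_counts[r.cluster_id] = cluster_counts.get(r.cluster_id, 0) + 1
            n_mod += 1
            if r.template_id is not None:
                template_counts[r.template_id] = (
                    template_counts.get(r.template_id, 0) + 1
                )
    return UsageProfile(
        repertoire_id=rep.repertoire_id,
        cluster_counts=cluster_counts,
        template_counts=template_counts,
        n_modelled=n_mod,
        n_total_in_range=len(rep.records),
        b_cell_type=rep.b_cell_type,
        isotype=rep.isotype,
    )


def filter_repertoires(
    profiles: list[UsageProfile], cfg: AnalysisConfig
) -> tuple[list[UsageProfile], list[tuple[str, str]]]:
    """Apply the repertoire quality rules; returns (retained, removal log).

    A repertoire is removed when its two most redundant clusters hold more
    than `top2_redundancy_max` of its sequences (PCR amplification
    artefact), or when fewer than `min_modelled` sequences carry a
    structural prediction (insufficient sampling of template usage).
    """
    retained, removed = [], []
    for p in profiles:
        if p.top2_share() > cfg.top2_redundancy_max:
            removed.append((p.repertoire_id, "top2_redundancy"))
        elif p.n_modelled < cfg.min_modelled:
            removed.append((p.repertoire_id, "min_modelled"))
        else:
            retained.append(p)
    return retained, removed


@dataclass(frozen=True)
class EntropyResult:
    H: float
    H_max: float
    normalized: float
    richness: int
    flagged: bool = False


def entropy_stats(profile: UsageProfile) -> EntropyResult:
    """Shannon entropy over represented clusters, normalized to its maximum.

    H = -sum f ln f; the theoretical maximum uses the repertoire's own
    represented clusters in equal proportions (H_max = ln richness).  A
    single-cluster repertoire has zero diversity (normalized 0); an empty
    profile is flagged and reported as normalized 1 by convention.
    """
    freqs = [f for f in profile.frequencies.values() if f > 0]
    k = len(freqs)
    if k == 0:
        return EntropyResult(0.0, 0.0, 1.0, 0, flagged=True)
    H = float(-sum(f * math.log(f) for f in freqs))
    H_max = math.log(k)
    if H_max == 0.0:
        return EntropyResult(H, 0.0, 0.0, k)
    return EntropyResult(H, H_max, min(H / H_max, 1.0), k)


def subsampled_richness(
    profile: UsageProfile, cfg: AnalysisConfig
) -> float:
    """Mean cluster count over repeated subsamples without replacement.

    Draws `cfg.subsample_size` sequences `cfg.n_subsamples` times from the
    repertoire's cluster counts (multivariate hypergeometric, seeded from
    cfg.rng_seed) and averages the number of distinct clusters hit.
    """
    if profile.n_modelled < cfg.subsample_size:
        raise ValueError(
            "repertoire smaller than subsample_size; apply filter_repertoires first"
        )
    counts = np.array(
        [profile.cluster_counts[c] for c in sorted(profile.cluster_counts)]
    )
    rng = np.random.default_rng(cfg.rng_seed)
    draws = rng.multivariate_hypergeometric(
        counts, cfg.subsample_size, size=cfg.n_subsamples
    )
    return float((draws > 0).sum(axis=1).mean())


@dataclass(frozen=True)
class SpeciesUsage:
    observed: dict[str, float]      # species -> fraction of predicted seqs
    expected: dict[str, float]      # library composition (uniform sampling)


def species_usage(profile: UsageProfile, library: TemplateLibrary) -> SpeciesUsage:
    """Observed species-of-origin proportions of used templates vs uniform."""
    sp_counts: dict[str, int] = {}
    for tid, n in profile.template_counts.items():
        sp = library[tid].species
        sp_counts[sp] = sp_counts.get(sp, 0) + n
    total = sum(sp_counts.values())
    observed = (
        {sp: c / total for sp, c in sorted(sp_counts.items())} if total else {}
    )
    return SpeciesUsage(observed=observed, expected=library.species_composition())


def never_used_templates(
    profiles: list[UsageProfile], library: TemplateLibrary
) -> list[str]:
    """Library templates absent from every profile's predictions."""
    used: set[str] = set()
    for p in profiles:
        used |= set(p.template_counts)
    return sorted(set(library.template_ids) - used)


def sequence_descriptors(rep: Repertoire) -> tuple[float, float]:
    """(mean CDR-H3 length, mean percent V-gene mutation) of a repertoire."""
    if not rep.records:
        return (float("nan"), float("nan"))
    mean_len = float(np.mean([r.cdrh3_len for r in rep.records]))
    pct_mut = float(
        np.mean(
            [100 * r.v_mutation_count / r.v_aligned_len for r in rep.records]
        )
    )
    return (mean_len, pct_mut)


def usage_matrix(
    profiles: list[UsageProfile], cluster_ids: list[str] | None = None
) -> pd.DataFrame:
    """Repertoires x clusters frequency matrix (missing clusters are 0).

    `cluster_ids` restricts the columns, e.g. to clusters of one CDR-H3
    length for the per-length embedding.
    """
    if cluster_ids is None:
        all_c: set[str] = set()
        for p in profiles:
            all_c |= set(p.cluster_counts)
        cluster_ids = sorted(all_c)
    data = np.zeros((len(profiles), len(cluster_ids)))
    for i, p in enumerate(profiles):
        f = p.frequencies
        for j, c in enumerate(cluster_ids):
            data[i, j] = f.get(c, 0.0)
    return pd.DataFrame(
        data, index=[p.repertoire_id for p in profiles], columns=cluster_ids
    )


@dataclass
class SweepResult:
    pca: pd.DataFrame                 # index repertoire_id, columns PC1, PC2
    trace: pd.DataFrame               # eps, repertoire_id, label, joined_reference
    join_eps: dict[str, float]        # repertoire_id -> smallest joining eps


def embed_and_sweep(
    matrix: pd.DataFrame,
    cfg: AnalysisConfig,
    reference_ids: list[str] | None = None,
    standardize: bool = False,
) -> SweepResult:
    """PCA embedding plus a DBSCAN epsilon sweep over usage profiles.

    PCA (two components, mean-centred, unscaled unless `standardize`) is
    for visualization; the sweep clusters the raw frequency vectors with
    Euclidean DBSCAN at each epsilon of cfg.eps_grid.  For every
    repertoire the trace records the smallest epsilon at which it shares a
    cluster with the reference repertoires (the cluster holding the most
    of them; ties to the lowest label).  Repertoires that cluster at lower
    epsilon have more similar usage distributions.
    """
    X = matrix.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(2, min(X.shape))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(len(X))])
    pca_df = pd.DataFrame(coords, index=matrix.index, columns=["PC1", "PC2"])

    rep_ids = list(matrix.index)
    reference_ids = reference_ids or rep_ids
    ref_idx = [i for i, r in enumerate(rep_ids) if r in set(reference_ids)]
    rows = []
    join_eps: dict[str, float] = {r: math.nan for r in rep_ids}
    for eps in cfg.eps_grid:
        if len(rep_ids) < cfg.dbscan_min_pts:
            labels = np.full(len(rep_ids), -1)
        else:
            labels = DBSCAN(eps=eps, min_samples=cfg.dbscan_min_pts).fit(X).labels_
        ref_labels = [labels[i] for i in ref_idx if labels[i] >= 0]
        if ref_labels:
            vals, counts = np.unique(ref_labels, return_counts=True)
            ref_cluster = int(vals[np.argmax(counts)])  # ties -> lowest label
        else:
            ref_cluster = None
        for i, r in enumerate(rep_ids):
            joined = ref_cluster is not None and labels[i] == ref_cluster
            if joined and math.isnan(join_eps[r]):
                join_eps[r] = eps
            rows.append((eps, r, int(labels[i]), joined))
    trace = pd.DataFrame(
        rows, columns=["eps", "repertoire_id", "label", "joined_reference"]
    )
    return SweepResult(pca=pca_df, trace=trace, join_eps=join_eps)


# ---------------------------------------------------------------------------
# standard group-comparison wrappers


def coverage_kruskal(groups: dict[str, list[UsageProfile]]) -> tuple[float, float]:
    """Kruskal-Wallis H test on structural coverage across groups."""
    samples = [[p.coverage for p in ps] for ps in groups.values()]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def entropy_mannwhitney(
    group_a: list[UsageProfile], group_b: list[UsageProfile]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on normalized entropy between two groups."""
    ea = [entropy_stats(p).normalized for p in group_a]
    eb = [entropy_stats(p).normalized for p in group_b]
    u, p = stats.mannwhitneyu(ea, eb, alternative="two-sided")
    return float(u), float(p)
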