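"""Knowledge-based CDR-H3 template prediction.

Each query loop is searched against same-length library templates, ranked
by framework sequence identity, then by a substitution-based compatibility
score (ESS) over the aligned loop positions, with deterministic
lexicographic tie-breaks.  A prediction is retained only if its ESS clears
a per-length-bin cutoff; cutoffs are calibrated on structures of known
backbone so that retained predictions average better than a target RMSD,
falling back to a minimum-coverage rule when that target is unreachable.

The default substitution table is BLOSUM62 (symmetric, diagonal-dominant);
any 20x20 symmetric table can be supplied from file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .imgt import AA20
from .loopgeom import BackboneLoop, backbone_rmsd
from .seqqc import NumberedSequence
from .templates import TemplateLibrary, TemplateRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

DEFAULT_BINS = ((5, 12), (13, 14), (15, 16))


@dataclass(frozen=True)
class EssModel:
    """Symmetric 20x20 substitution score table over the standard residues."""

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (20, 20):
            raise ValueError("substitution table must be 20x20")
        if not np.allclose(t, t.T):
            raise ValueError("substitution table must be symmetric")
        if np.any(t.diagonal()[:, None] < t):
            raise ValueError("self-substitution must score at least any swap")
        object.__setattr__(self, "table", t)

    @classmethod
    def default(cls) -> "EssModel":
        blosum = substitution_matrices.load("BLOSUM62")
        t = np.empty((20, 20))
        for i, a in enumerate(AA20):
            for j, b in enumerate(AA20):
                t[i, j] = blosum[a, b]
        return cls(table=t)

    @classmethod
    def from_file(cls, path: str | Path) -> "EssModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        t = df.loc[list(AA20), list(AA20)].to_numpy(dtype=float)
        return cls(table=t)

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(self.table, index=list(AA20), columns=list(AA20)).to_csv(
            path, sep="\t"
        )


@dataclass(frozen=True)
class LengthBinCutoffs:
    """ESS cutoff per CDR-H3 length bin; +inf means no predictions retained."""

    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS
    cutoffs: tuple[float, ...] = (-math.inf, -math.inf, -math.inf)

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.cutoffs):
            raise ValueError("one cutoff per bin required")

    def cutoff_for(self, length: int) -> float:
        for (lo, hi), c in zip(self.bins, self.cutoffs):
            if lo <= length <= hi:
                return c
        raise ValueError(f"length {length} not covered by any bin")

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            dict(
                lo=[b[0] for b in self.bins],
                hi=[b[1] for b in self.bins],
                ess_cutoff=list(self.cutoffs),
            )
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "LengthBinCutoffs":
        df = pd.read_csv(path, sep="\t")
        return cls(
            bins=tuple((int(r.lo), int(r.hi)) for r in df.itertuples(index=False)),
            cutoffs=tuple(float(r.ess_cutoff) for r in df.itertuples(index=False)),
        )


@dataclass
class TemplatePrediction:
    sequence_id: str
    template_id: str | None
    ess: float
    cluster_id: str | None = None


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[aa] for aa in seq], dtype=int)


def ess_score(query: str, template: TemplateRecord | str, model: EssModel) -> float:
    """Positionwise substitution score between equal-length loop sequences."""
    tseq = template if isinstance(template, str) else template.cdrh3_seq
    if len(query) != len(tseq):
        raise ValueError("query and template lengths differ")
    q = _encode(query)
    t = _encode(tseq)
    return float(model.table[q, t].sum())


def _identity(a: str, b: str) -> float:
    n = max(len(a), len(b))
    return sum(x == y for x, y in zip(a, b)) / n if n else 0.0


def framework_sequence(seq: NumberedSequence) -> str:
    """Concatenated framework-1/2/3 residues of a numbered sequence."""
    from . import imgt
    return "".join(
        res for pos, res in seq.positions.items()
        if imgt.region_of(pos) in ("fw1", "fw2", "fw3")
    )


def predict_cdrh3(
    seq: NumberedSequence,
    library: TemplateLibrary,
    model: EssModel,
    cutoffs: LengthBinCutoffs,
) -> TemplatePrediction:
    """Best same-length template for one sequence, or NONE below cutoff."""
    preds = predict_repertoire([seq], library, model, cutoffs)
    return preds[0]


def predict_repertoire(
    seqs: list[NumberedSequence],
    library: TemplateLibrary,
    model: EssModel,
    cutoffs: LengthBinCutoffs,
) -> list[TemplatePrediction]:
    """Vectorized template search for a batch of numbered sequences.

    Ranking per query: framework identity (desc), ESS (desc), template_id
    (asc).  Identical inputs yield byte-identical outputs.
    """
    out: list[TemplatePrediction] = [None] * len(seqs)  # type: ignore
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s.cdrh3_seq), []).append(i)
    for L, idxs in sorted(by_len.items()):
        templates = library.of_length(L)
        cutoff = cutoffs.cutoff_for(L)
        if not templates:
            for i in idxs:
                out[i] = TemplatePrediction(seqs[i].id, None, -math.inf)
            continue
        tmat = np.stack([_encode(t.cdrh3_seq) for t in templates])   # (T, L)
        qmat = np.stack([_encode(seqs[i].cdrh3_seq) for i in idxs])  # (Q, L)
        ess = model.table[qmat[:, None, :], tmat[None, :, :]].sum(axis=2)
        fw_q = [framework_sequence(seqs[i]) for i in idxs]
        ident = np.empty((len(idxs), len(templates)))
        fw_t = [t.framework_seq for t in templates]
        # framework identity is coarse; cache per distinct query framework
        cache: dict[str, np.ndarray] = {}
        for r, fq in enumerate(fw_q):
            row = cache.get(fq)
            if row is None:
                row = np.array([_identity(fq, ft) for ft in fw_t])
                cache[fq] = row
            ident[r] = row
        im = ident.max(axis=1, keepdims=True)
        m1 = ident == im
        ess_masked = np.where(m1, ess, -np.inf)
        em = ess_masked.max(axis=1, keepdims=True)
        m2 = m1 & (ess_masked == em)
        best = m2.argmax(axis=1)  # templates sorted by id: first max wins ties
        for r, i in enumerate(idxs):
            e = float(ess[r, best[r]])
            if e >= cutoff:
                out[i] = TemplatePrediction(
                    seqs[i].id, templates[best[r]].template_id, e
                )
            else:
                out[i] = TemplatePrediction(seqs[i].id, None, e)
    return out


@dataclass(frozen=True)
class _CalibrationHit:
    length: int
    ess: float
    rmsd: float


def _top_hit(
    rec: TemplateRecord, library: TemplateLibrary, model: EssModel
) -> _CalibrationHit | None:
    """Leave-one-out top hit for a validation structure."""
    cands = [t for t in library.of_length(rec.length) if t.template_id != rec.template_id]
    if not cands:
        return None
    best = None
    for t in cands:
        key = (_identity(rec.framework_seq, t.framework_seq),
               ess_score(rec.cdrh3_seq, t, model))
        if best is None or key > best[0]:
            best = (key, t)
    (_, ess), t = best
    return _CalibrationHit(rec.length, ess, backbone_rmsd(rec.loop, t.loop))


def calibrate_ess_cutoffs(
    validation: list[TemplateRecord],
    library: TemplateLibrary,
    model: EssModel | None = None,
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS,
    rmsd_target: float = 3.0,
    min_coverage: float = 0.15,
) -> LengthBinCutoffs:
    """Choose per-bin ESS cutoffs from structures of known backbone.

    For each bin, scan the grid of observed top-hit scores from low to
    high and pick the smallest cutoff whose retained predictions average
    an RMSD below `rmsd_target`; if no cutoff manages that, pick the
    largest cutoff whose coverage still exceeds `min_coverage`.  Empty bins
    get a +inf sentinel (no predictions at those lengths).
    """
    model = model or EssModel.default()
    hits: list[_CalibrationHit] = []
    for rec in validation:
        h = _top_hit(rec, library, model)
        if h is not None:
            hits.append(h)
    cutoffs = []
    for lo, hi in bins:
        bin_hits = [h for h in hits if lo <= h.length <= hi]
        n_queries = sum(1 for r in validation if lo <= r.length <= hi)
        if not bin_hits:
            cutoffs.append(math.inf)
            continue
        grid = sorted({h.ess for h in bin_hits})
        chosen = None
        for c in grid:  # ascending: smallest cutoff meeting the RMSD target
            retained = [h for h in bin_hits if h.ess >= c]
            if retained and np.mean([h.rmsd for h in retained]) < rmsd_target:
                chosen = c
                break
        if chosen is None:
            for c in reversed(grid):  # largest cutoff keeping coverage
                retained = [h for h in bin_hits if h.ess >= c]
                if len(retained) / n_queries > min_coverage:
                    chosen = c
                    break
        cutoffs.append(math.inf if chosen is None else chosen)
    return LengthBinCutoffs(bins=bins, cutoffs=tuple(cutoffs))


def prediction_precision(
    predictions: list[tuple[TemplatePrediction, BackboneLoop]],
    library: TemplateLibrary,
    rmsd_target: float = 3.0,
) -> float | None:
    """Percent of retained predictions within `rmsd_target` of the truth.

    Returns None when no prediction was retained (precision undefined).
    """
    retained = [(p, true) for p, true in predictions if p.template_id]
    if not retained:
        return None
    n_ok = sum(
        1
        for p, true in retained
        if backbone_rmsd(library[p.template_id].loop, true) < rmsd_target
    )
    return 100.0 * n_ok / len(retained)


def predictions_frame(preds: list[TemplatePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            sequence_id=[p.sequence_id for p in preds],
            template_id=[p.template_id or "" for p in preds],
            ess=[p.ess for p in preds],
            cluster_id=[p.cluster_id or "" for p in preds],
        )
    )
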