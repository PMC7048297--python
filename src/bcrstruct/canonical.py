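"""Canonical class assignment for CDR-H1/H2 loops.

Non-CDR-H3 loops adopt a small set of recurrent backbone shapes (canonical
classes) that are predictable from sequence alone.  This module assigns
classes by position-specific scoring matrices (PSSMs): one log-odds matrix
per (loop, length, class) with a per-class score threshold below which a
loop is UNASSIGNED.  It also computes germline canonical divergence — the
fraction of sequences whose H1 or H2 class differs from that of their
germline V gene — a structural readout of affinity maturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imgt import AA20

UNASSIGNED = "UNASSIGNED"

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


@dataclass(frozen=True)
class PssmClass:
    class_id: str
    loop: str               # "H1" or "H2"
    length: int
    pssm: np.ndarray        # (length, 20) log-odds
    threshold: float

    def score(self, seq: str) -> float:
        idx = [_AA_INDEX.get(aa, -1) for aa in seq]
        if -1 in idx:
            return -np.inf
        return float(self.pssm[np.arange(self.length), idx].sum())


@dataclass
class CanonicalClassDb:
    """PSSM classes keyed by (loop, length); class ids unique overall."""

    classes: list[PssmClass]
    _index: dict[tuple[str, int], list[PssmClass]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        ids = [c.class_id for c in self.classes]
        if len(ids) != len(set(ids)):
            raise ValueError("class_ids must be unique")
        index: dict[tuple[str, int], list[PssmClass]] = {}
        for c in sorted(self.classes, key=lambda c: c.class_id):
            index.setdefault((c.loop, c.length), []).append(c)
        self._index = index

    def candidates(self, loop: str, length: int) -> list[PssmClass]:
        return self._index.get((loop, length), [])


@dataclass(frozen=True)
class CanonicalAssignment:
    loop: str
    class_id: str           # or UNASSIGNED
    score: float


@dataclass
class GermlineCanonicalTable:
    """V-gene name -> (H1 class, H2 class); UNASSIGNED entries allowed."""

    entries: dict[str, tuple[str, str]]


def build_canonical_db(
    labelled_loops: list[tuple[str, str, str]],
    pseudocount: float = 0.5,
) -> CanonicalClassDb:
    """Train per-class PSSMs from (loop, sequence, class_id) examples.

    Log-odds against a uniform 1/20 background with an additive
    pseudocount; the class threshold is the minimum self-score over its
    training members.  A residue never seen at a position scores a -inf
    sentinel when pseudocount is zero.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for loop, seq, class_id in labelled_loops:
        groups.setdefault((loop, class_id), []).append(seq)
    classes = []
    for (loop, class_id), seqs in sorted(groups.items()):
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"class {class_id}: training sequences have mixed lengths {lengths}"
            )
        (L,) = lengths
        counts = np.zeros((L, 20))
        for s in seqs:
            for i, aa in enumerate(s):
                counts[i, _AA_INDEX[aa]] += 1
        freqs = (counts + pseudocount) / (len(seqs) + 20 * pseudocount)
        with np.errstate(divide="ignore"):
            pssm = np.log(freqs) - np.log(1 / 20)
        cls = PssmClass(class_id=class_id, loop=loop, length=L,
                        pssm=pssm, threshold=0.0)
        threshold = min(cls.score(s) for s in seqs)
        classes.append(
            PssmClass(class_id=class_id, loop=loop, length=L,
                      pssm=pssm, threshold=threshold)
        )
    return CanonicalClassDb(classes=classes)


def assign_canonical(
    loop_seq: str, loop: str, db: CanonicalClassDb
) -> CanonicalAssignment:
    """Best length-matched class at or above its threshold, else UNASSIGNED.

    Ties break lexicographically on class_id (candidates are pre-sorted).
    """
    cands = db.candidates(loop, len(loop_seq))
    best: CanonicalAssignment | None = None
    for c in cands:
        s = c.score(loop_seq)
        if best is None or s > best.score:
            best = CanonicalAssignment(loop=loop, class_id=c.class_id, score=s)
            best_threshold = c.threshold
    if best is None or best.score < best_threshold:
        return CanonicalAssignment(loop=loop, class_id=UNASSIGNED,
                                   score=best.score if best else float("-inf"))
    return best


def assign_canonical_batch(
    seqs: list[str], loop: str, db: CanonicalClassDb
) -> list[CanonicalAssignment]:
    """Vectorized assignment of many loops of one kind (H1 or H2)."""
    out: list[CanonicalAssignment] = [None] * len(seqs)  # type: ignore
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        cands = db.candidates(loop, L)
        if not cands:
            for i in idxs:
                out[i] = CanonicalAssignment(loop, UNASSIGNED, float("-inf"))
            continue
        enc = np.full((len(idxs), L), -1, dtype=int)
        ok = np.ones(len(idxs), dtype=bool)
        for r, i in enumerate(idxs):
            for j, aa in enumerate(seqs[i]):
                k = _AA_INDEX.get(aa, -1)
                enc[r, j] = k
                if k < 0:
                    ok[r] = False
        pos = np.arange(L)
        scores = np.full((len(idxs), len(cands)), -np.inf)
        for ci, c in enumerate(cands):
            sc = c.pssm[pos[None, :], np.where(enc < 0, 0, enc)].sum(axis=1)
            scores[:, ci] = np.where(ok, sc, -np.inf)
        best_ci = scores.argmax(axis=1)  # first max: lexicographic tie-break
        for r, i in enumerate(idxs):
            c = cands[best_ci[r]]
            s = float(scores[r, best_ci[r]])
            if not np.isfinite(s) or s < c.threshold:
                out[i] = CanonicalAssignment(loop, UNASSIGNED, s)
            else:
                out[i] = CanonicalAssignment(loop, c.class_id, s)
    return out


def germline_canonical_table(
    db: CanonicalClassDb, germlines
) -> GermlineCanonicalTable:
    """Assign each germline V gene's own CDR-H1/H2 loops through the db."""
    entries = {}
    for name in germlines.names:
        h1 = assign_canonical(germlines.cdr1_seq(name), "H1", db)
        h2 = assign_canonical(germlines.cdr2_seq(name), "H2", db)
        entries[name] = (h1.class_id, h2.class_id)
    return GermlineCanonicalTable(entries=entries)


@dataclass(frozen=True)
class DivergenceSummary:
    pct_either: float
    pct_h1: float
    pct_h2: float
    n_used: int
    n_excluded: int


def germline_divergence(
    annotations: list[tuple[str, CanonicalAssignment, CanonicalAssignment]],
    table: GermlineCanonicalTable,
) -> DivergenceSummary:
    """Percentage of sequences whose canonical classes differ from germline.

    `annotations` holds (v_gene, H1 assignment, H2 assignment) per sequence.
    A sequence diverges if either loop's class differs from the germline
    entry; an UNASSIGNED sequence class counts as divergent when the
    germline class is assigned.  Sequences whose V gene is absent from the
    table are excluded and tallied.
    """
    n_used = n_excluded = n_either = n_h1 = n_h2 = 0
    for v_gene, h1, h2 in annotations:
        if v_gene not in table.entries:
            n_excluded += 1
            continue
        g1, g2 = table.entries[v_gene]
        d1 = h1.class_id != g1
        d2 = h2.class_id != g2
        n_used += 1
        n_h1 += d1
        n_h2 += d2
        n_either += d1 or d2
    if n_used == 0:
        return DivergenceSummary(0.0, 0.0, 0.0, 0, n_excluded)
    return DivergenceSummary(
        pct_either=100 * n_either / n_used,
        pct_h1=100 * n_h1 / n_used,
        pct_h2=100 * n_h2 / n_used,
        n_used=n_used,
        n_excluded=n_excluded,
    )


def canonical_pair_usage(
    assignments: list[tuple[CanonicalAssignment, CanonicalAssignment]],
) -> dict[tuple[str, str], float]:
    """Relative frequency of (H1 class, H2 class) pairs in one repertoire.

    UNASSIGNED is kept as an explicit category so unassignable loops remain
    visible in downstream embeddings.
    """
    counts: dict[tuple[str, str], int] = {}
    for h1, h2 in assignments:
        key = (h1.class_id, h2.class_id)
        counts[key] = counts.get(key, 0) + 1
    n = sum(counts.values())
    return {k: v / n for k, v in sorted(counts.items())} if n else {}


# ---------------------------------------------------------------------------
# serialization (bit-exact round-trip)


def write_canonical_db(db: CanonicalClassDb, pssm_path, thresholds_path) -> None:
    rows = []
    for c in sorted(db.classes, key=lambda c: (c.loop, c.length, c.class_id)):
        for p in range(c.length):
            rows.append(
                [c.loop, c.length, c.class_id, p]
                + [repr(float(x)) for x in c.pssm[p]]
            )
    cols = ["loop", "length", "class_id", "position"] + list(AA20)
    pd.DataFrame(rows, columns=cols).to_csv(pssm_path, sep="\t", index=False)
    trows = [
        [c.loop, c.length, c.class_id, repr(float(c.threshold))]
        for c in sorted(db.classes, key=lambda c: (c.loop, c.length, c.class_id))
    ]
    pd.DataFrame(
        trows, columns=["loop", "length", "class_id", "threshold"]
    ).to_csv(thresholds_path, sep="\t", index=False)


def read_canonical_db(pssm_path, thresholds_path) -> CanonicalClassDb:
    pssm_df = pd.read_csv(pssm_path, sep="\t", float_precision="round_trip")
    th_df = pd.read_csv(thresholds_path, sep="\t", float_precision="round_trip")
    thresholds = {
        r.class_id: float(r.threshold) for r in th_df.itertuples(index=False)
    }
    classes = []
    for (loop, length, class_id), grp in pssm_df.groupby(
        ["loop", "length", "class_id"]
    ):
        grp = grp.sort_values("position")
        pssm = grp[list(AA20)].to_numpy(dtype=float)
        classes.append(
            PssmClass(
                class_id=class_id, loop=loop, length=int(length),
                pssm=pssm, threshold=thresholds[class_id],
            )
        )
    return CanonicalClassDb(classes=classes)
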