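"""Backbone geometry for CDR-H3 loops.

Rigid-body superposition (Kabsch, proper rotations only), backbone RMSD,
dynamic-time-warping RMSD for loops of unequal length, and structural
clustering of a template library at a fixed RMSD threshold.

All coordinates are in angstroms.  A loop is represented as an
``(n_residues, 3, 3)`` array of per-residue N, CA, C atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

if TYPE_CHECKING:  # pragma: no cover
    from .templates import TemplateLibrary

ANCHOR_RESIDUES = 3  # terminal residues used for anchor superposition


@dataclass(frozen=True)
class BackboneLoop:
    """Ordered backbone of one loop: per-residue (N, CA, C) coordinates."""

    coords: np.ndarray  # (n_residues, 3, 3)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[1:] != (3, 3):
            raise ValueError("backbone coordinates must have shape (n, 3, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("backbone coordinates must be finite")
        object.__setattr__(self, "coords", c)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> np.ndarray:
        """All backbone atoms as a flat (3n, 3) array in chain order."""
        return self.coords.reshape(-1, 3)

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, (n, 3)."""
        return self.coords[:, 1, :]


def _superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares superpose `moving` onto `fixed` (both (k, 3)).

    Returns the (rotation, translation) applied as a callable-free pair:
    the rotated+translated copy of `moving`, and the RMSD over the fitted
    atoms.  Proper rotation only (no reflection).
    """
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - fc, moving - mc)
    moved = rot.apply(moving - mc) + fc
    return moved, float(rssd / np.sqrt(len(moving)))


def _transform_from(
    moving_ref: np.ndarray, fixed_ref: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Apply the superposition fitted on reference atoms to `points`."""
    mc = moving_ref.mean(axis=0)
    fc = fixed_ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(fixed_ref - fc, moving_ref - mc)
    return rot.apply(points - mc) + fc


def backbone_rmsd(a: BackboneLoop, b: BackboneLoop) -> float:
    """All-backbone-atom RMSD after optimal rigid superposition.

    Symmetric, non-negative, zero for congruent loops.  Raises on length
    mismatch (use :func:`dtw_rmsd` for unequal lengths).
    """
    if len(a) != len(b):
        raise ValueError(
            f"residue counts differ ({len(a)} vs {len(b)}); use dtw_rmsd"
        )
    _, rmsd = _superpose(b.atoms, a.atoms)
    return rmsd


def _dtw_path(d2: np.ndarray) -> tuple[float, int]:
    """Min-cost monotone warping path over a squared-distance matrix.

    Symmetric step set (diagonal, down, right).  Returns (total squared
    distance along the optimal path, path length in matched pairs).
    """
    n, m = d2.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = d2[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i and j:
                best = acc[i - 1, j - 1]
            if i:
                best = min(best, acc[i - 1, j])
            if j:
                best = min(best, acc[i, j - 1])
            acc[i, j] = d2[i, j] + best
    # traceback for path length; prefer the diagonal on ties
    i, j = n - 1, m - 1
    length = 1
    while i or j:
        moves = []
        if i and j:
            moves.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i:
            moves.append((acc[i - 1, j], i - 1, j))
        if j:
            moves.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
        length += 1
    return float(acc[n - 1, m - 1]), length


def dtw_rmsd(a: BackboneLoop, b: BackboneLoop) -> float:
    """CA RMSD along the optimal dynamic-time-warping alignment.

    Equal-length loops are first superposed optimally over all CA atoms, so
    a diagonal warping path reproduces the CA-restricted rigid RMSD and
    warping can only match or beat it.  Unequal-length loops are superposed
    on their anchor residues (the three terminal residues of each end,
    backbone atoms), the natural frame when no residue correspondence
    exists.  The warp runs over per-residue CA distances with symmetric
    steps; the return value is the RMSD over matched pairs on the optimal
    path.
    """
    if len(a) < 4 or len(b) < 4:
        raise ValueError("loops must have at least 4 residues")
    if len(a) == len(b):
        b_ca = _transform_from(b.ca, a.ca, b.ca)
    else:
        k = min(ANCHOR_RESIDUES, len(a) // 2, len(b) // 2)
        anchors_b = np.concatenate([b.coords[:k], b.coords[-k:]]).reshape(-1, 3)
        anchors_a = np.concatenate([a.coords[:k], a.coords[-k:]]).reshape(-1, 3)
        b_ca = _transform_from(anchors_b, anchors_a, b.ca)
    diff = a.ca[:, None, :] - b_ca[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    cost, length = _dtw_path(d2)
    return float(np.sqrt(cost / length))


@dataclass
class TemplateClusterSet:
    """Partition of a template library into structural clusters.

    Clusters are disjoint and exhaustive; each has a representative member
    (the founding template under leader clustering).
    """

    members: dict[str, list[str]]           # cluster_id -> template_ids
    representatives: dict[str, str]         # cluster_id -> template_id
    threshold: float
    _by_template: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_template:
            self._by_template = {
                t: cid for cid, ts in self.members.items() for t in ts
            }

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def cluster_of(self, template_id: str) -> str:
        return self._by_template[template_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, t, t == self.representatives[cid], self.threshold)
            for cid in sorted(self.members)
            for t in self.members[cid]
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "template_id", "is_representative", "threshold"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TemplateClusterSet":
        df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "template_id": str})
        members: dict[str, list[str]] = {}
        reps: dict[str, str] = {}
        for row in df.itertuples(index=False):
            members.setdefault(row.cluster_id, []).append(row.template_id)
            if bool(row.is_representative):
                reps[row.cluster_id] = row.template_id
        return cls(members=members, representatives=reps,
                   threshold=float(df["threshold"].iloc[0]))


def cluster_templates(
    library: "TemplateLibrary", threshold: float = 0.6
) -> TemplateClusterSet:
    """Leader-cluster a template library by backbone RMSD.

    Templates are visited in lexicographic template_id order; each joins the
    first existing cluster whose representative lies within `threshold`
    (all-atom backbone RMSD for equal lengths, DTW CA RMSD otherwise), else
    founds a new cluster.  Deterministic and order-stable.
    """
    reps: list[tuple[str, BackboneLoop]] = []   # (cluster_id, rep loop)
    members: dict[str, list[str]] = {}
    representatives: dict[str, str] = {}
    for tid in sorted(library.template_ids):
        loop = library[tid].loop
        assigned = None
        for cid, rep_loop in reps:
            if len(loop) == len(rep_loop):
                d = backbone_rmsd(loop, rep_loop)
            else:
                d = dtw_rmsd(loop, rep_loop)
            if d <= threshold:
                assigned = cid
                break
        if assigned is None:
            assigned = f"C{len(reps):04d}"
            reps.append((assigned, loop))
            representatives[assigned] = tid
            members[assigned] = []
        members[assigned].append(tid)
    return TemplateClusterSet(
        members=members, representatives=representatives, threshold=threshold
    )
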