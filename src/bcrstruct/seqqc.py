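"""Repertoire ingest, IMGT numbering and structural-viability filtering.

Sequences enter as raw amino-acid strings (AIRR rearrangement TSV or
FASTA), are numbered onto the IMGT scaffold against a germline V-gene
reference, and pass through the structural filters used before any
template search: alignment quality, framework indels, conserved residues,
chimera detection and presence of all three CDR loops.

Numbering is a deterministic profile alignment against per-V-gene
IMGT-aligned references.  The hot path is ungapped (vectorized across a
whole repertoire); sequences that fail it fall back to an affine-gap
pairwise alignment so indel-bearing reads are classified, not silently
dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from . import imgt
from .imgt import ALPHABET, CDR1_RANGE, CDR2_RANGE, V_END

REJECTION_REASONS = (
    "no_alignment",
    "indel_in_framework",
    "missing_conserved_residue",
    "chimeric",
    "missing_cdr",
    "x_in_cdr",
    "too_many_x",
)


@dataclass(frozen=True)
class RawSequenceRecord:
    """One input amino-acid sequence with its repertoire of origin."""

    id: str
    sequence: str
    repertoire_id: str = ""


@dataclass
class GermlineReference:
    """IMGT-aligned germline V genes plus the J-region framework-4 tail."""

    v_genes: dict[str, dict[str, str]]        # name -> position -> residue
    j_tail: str                                # framework-4 residues from 118
    conserved_positions: tuple[tuple[str, str], ...] = imgt.CONSERVED_POSITIONS

    def __post_init__(self) -> None:
        if not self.conserved_positions:
            raise ValueError("conserved_positions must be non-empty")
        for name, posmap in self.v_genes.items():
            if str(V_END) not in posmap:
                raise ValueError(f"{name}: V gene must cover IMGT position {V_END}")

    @property
    def names(self) -> list[str]:
        return sorted(self.v_genes)

    def ungapped(self, name: str) -> str:
        posmap = self.v_genes[name]
        return "".join(posmap[p] for p in imgt.v_positions() if p in posmap)

    def positions_of(self, name: str) -> list[str]:
        posmap = self.v_genes[name]
        return [p for p in imgt.v_positions() if p in posmap]

    def region_seq(self, name: str, lo: int, hi: int) -> str:
        posmap = self.v_genes[name]
        return "".join(
            posmap[str(i)] for i in range(lo, hi + 1) if str(i) in posmap
        )

    def cdr1_seq(self, name: str) -> str:
        return self.region_seq(name, *CDR1_RANGE)

    def cdr2_seq(self, name: str) -> str:
        return self.region_seq(name, *CDR2_RANGE)


@dataclass(frozen=True)
class NumberedSequence:
    """An IMGT-numbered heavy-chain variable domain."""

    id: str
    positions: dict[str, str]
    v_gene: str
    v_identity: float
    cdrh1_seq: str
    cdrh2_seq: str
    cdrh3_seq: str
    v_mutation_count: int
    repertoire_id: str = ""


@dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


@dataclass
class QcReport:
    """Per-stage record counts; rejections + acceptances account for inputs."""

    n_input: int = 0
    n_numbered: int = 0
    n_pass_filters: int = 0
    n_in_length_range: int = 0
    rejections: Counter = field(default_factory=Counter)
    length_removals: Counter = field(default_factory=Counter)

    def check(self) -> None:
        if sum(self.rejections.values()) != self.n_input - self.n_pass_filters:
            raise AssertionError("rejection tallies do not account for inputs")


@dataclass
class SeqQcConfig:
    chimera_split: int = 52        # IMGT position ending the first V half
    chimera_margin: float = 0.10   # identity-fraction margin per half
    max_framework_x: int = 2
    fast_path_min_identity: float = 0.70
    j_min_identity: float = 0.50
    min_cdrh3: int = 5
    max_cdrh3: int = 16


# ---------------------------------------------------------------------------
# ingest


def read_repertoire(
    path: str | Path,
    format: str = "airr",
    metadata: dict | None = None,
    report: QcReport | None = None,
    sequence_column: str = "sequence_alignment_aa",
    id_column: str = "sequence_id",
) -> list[RawSequenceRecord]:
    """Read one repertoire from an AIRR rearrangement TSV or a FASTA file.

    Rows with a missing sequence or a residue outside the 20 standard amino
    acids (plus X) are skipped and tallied in `report`.
    """
    metadata = metadata or {}
    rep_id = str(metadata.get("repertoire_id", Path(path).stem))
    records: list[RawSequenceRecord] = []
    n_bad = 0
    if format == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str)
        col = sequence_column if sequence_column in df.columns else None
        if col is None:
            for cand in ("sequence_alignment_aa", "sequence_aa", "sequence"):
                if cand in df.columns:
                    col = cand
                    break
        if col is None:
            raise ValueError(f"{path}: no amino-acid sequence column found")
        ids = (
            df[id_column]
            if id_column in df.columns
            else pd.Series([f"seq{i}" for i in range(len(df))])
        )
        entries = zip(ids.astype(str), df[col])
    elif format == "fasta":
        entries = ((r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta"))
    else:
        raise ValueError(f"unknown format {format!r}")
    for sid, seq in entries:
        if not isinstance(seq, str) or not seq or not set(seq) <= ALPHABET:
            n_bad += 1
            continue
        records.append(RawSequenceRecord(id=sid, sequence=seq, repertoire_id=rep_id))
    if report is not None:
        # accepted records are counted when they enter numbering
        report.n_input += n_bad
        report.rejections["unreadable_sequence"] += n_bad
    return records


# ---------------------------------------------------------------------------
# numbering


def _encode(seqs: list[str], width: int) -> np.ndarray:
    """Byte-encode sequences into an (n, width) matrix, zero-padded."""
    out = np.zeros((len(seqs), width), dtype=np.uint8)
    for i, s in enumerate(seqs):
        b = np.frombuffer(s[:width].encode(), dtype=np.uint8)
        out[i, : len(b)] = b
    return out


def _build_numbered(
    raw: RawSequenceRecord,
    ref: GermlineReference,
    v_gene: str,
    v_seq_aln: list[tuple[str, str]],
    cdr3: str,
    j_seq: str,
    cfg: SeqQcConfig,
) -> NumberedSequence | Rejection:
    """Assemble a NumberedSequence from an aligned V region + junction + J.

    `v_seq_aln` is the ordered (position, residue) list for the V region.
    Applies the conserved-residue, chimera-independent X filters here.
    """
    positions = dict(v_seq_aln)
    for pos, res in zip(imgt.cdr3_positions(len(cdr3)), cdr3):
        positions[pos] = res
    for pos, res in zip(imgt.fw4_positions(len(j_seq)), j_seq):
        positions[pos] = res
    for pos, allowed in ref.conserved_positions:
        if positions.get(pos) not in set(allowed):
            return Rejection(raw.id, "missing_conserved_residue")
    cdr1 = "".join(
        res for pos, res in positions.items()
        if imgt.region_of(pos) == "cdr1"
    )
    cdr2 = "".join(
        res for pos, res in positions.items()
        if imgt.region_of(pos) == "cdr2"
    )
    if not cdr1 or not cdr2 or not cdr3:
        return Rejection(raw.id, "missing_cdr")
    if "X" in cdr1 or "X" in cdr2 or "X" in cdr3:
        return Rejection(raw.id, "x_in_cdr")
    n_fw_x = sum(
        1 for pos, res in positions.items()
        if res == "X" and imgt.region_of(pos).startswith("fw")
    )
    if n_fw_x > cfg.max_framework_x:
        return Rejection(raw.id, "too_many_x")
    g = ref.v_genes[v_gene]
    aligned = [(p, r) for p, r in v_seq_aln if p in g]
    n_match = sum(1 for p, r in aligned if g[p] == r)
    return NumberedSequence(
        id=raw.id,
        positions=positions,
        v_gene=v_gene,
        v_identity=n_match / len(aligned) if aligned else 0.0,
        cdrh1_seq=cdr1,
        cdrh2_seq=cdr2,
        cdrh3_seq=cdr3,
        v_mutation_count=len(aligned) - n_match,
        repertoire_id=raw.repertoire_id,
    )


def _chimera_check(
    seq_v: str, ref: GermlineReference, cfg: SeqQcConfig
) -> bool:
    """True if the two V halves best-match different germlines decisively."""
    split = cfg.chimera_split
    scores1, scores2, names = [], [], []
    for name in ref.names:
        g = ref.ungapped(name)
        if len(g) != len(seq_v):
            continue
        half1 = sum(a == b for a, b in zip(seq_v[:split], g[:split])) / split
        half2 = sum(
            a == b for a, b in zip(seq_v[split:], g[split:])
        ) / (len(g) - split)
        names.append(name)
        scores1.append(half1)
        scores2.append(half2)
    if len(names) < 2:
        return False
    s1 = np.array(scores1)
    s2 = np.array(scores2)
    i1, i2 = int(np.argmax(s1)), int(np.argmax(s2))
    if names[i1] == names[i2]:
        return False
    margin1 = s1[i1] - s1[i2]
    margin2 = s2[i2] - s2[i1]
    return margin1 >= cfg.chimera_margin and margin2 >= cfg.chimera_margin


_aligner = PairwiseAligner()
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5
_aligner.mode = "local"


def _number_by_alignment(
    raw: RawSequenceRecord, ref: GermlineReference, cfg: SeqQcConfig
) -> NumberedSequence | Rejection:
    """Affine-gap fallback for sequences failing the ungapped fast path."""
    seq = raw.sequence.replace("X", "A")  # BLOSUM rows lack X; filters re-check
    best = None
    for name in ref.names:
        g = ref.ungapped(name)
        try:
            aln = _aligner.align(g, seq)[0]
        except (IndexError, ValueError):
            continue
        ident = _alignment_identity(aln)
        if best is None or aln.score > best[0]:
            best = (aln.score, ident, name, aln)
    if best is None or best[1] < cfg.fast_path_min_identity * 0.7:
        return Rejection(raw.id, "no_alignment")
    _, _, name, aln = best
    g_positions = ref.positions_of(name)
    # walk the alignment; detect gaps relative to the germline scaffold
    g_blocks, s_blocks = aln.aligned
    v_pairs: list[tuple[str, str]] = []
    prev_g_end = prev_s_end = None
    for (g0, g1), (s0, s1) in zip(g_blocks, s_blocks):
        if prev_g_end is not None:
            g_gap = g0 - prev_g_end
            s_gap = s0 - prev_s_end
            if g_gap or s_gap:
                # indel relative to the scaffold: locate it
                pos = g_positions[min(g0, len(g_positions) - 1)]
                if imgt.region_of(pos).startswith("fw"):
                    return Rejection(raw.id, "indel_in_framework")
                if s_gap:  # insertion inside a CDR: give insertion codes
                    base = g_positions[prev_g_end - 1]
                    for k in range(s_gap):
                        v_pairs.append(
                            (f"{base}.{k + 1}", raw.sequence[prev_s_end + k])
                        )
        for gi, si in zip(range(g0, g1), range(s0, s1)):
            v_pairs.append((g_positions[gi], raw.sequence[si]))
        prev_g_end, prev_s_end = g1, s1
    if not v_pairs or v_pairs[-1][0] != str(V_END):
        return Rejection(raw.id, "no_alignment")
    v_end_idx = prev_s_end  # query index one past IMGT 104
    tail = raw.sequence[v_end_idx:]
    j_ref = ref.j_tail
    j_at = _find_j(tail, j_ref, cfg)
    if j_at is None:
        return Rejection(raw.id, "missing_cdr")
    cdr3 = tail[:j_at]
    j_seq = tail[j_at : j_at + len(j_ref)]
    if not cdr3:
        return Rejection(raw.id, "missing_cdr")
    v_str = "".join(r for _, r in v_pairs)
    if _chimera_check(v_str, ref, cfg):
        return Rejection(raw.id, "chimeric")
    return _build_numbered(raw, ref, name, v_pairs, cdr3, j_seq, cfg)


def _alignment_identity(aln) -> float:
    g_blocks, s_blocks = aln.aligned
    n = m = 0
    for (g0, g1), (s0, s1) in zip(g_blocks, s_blocks):
        a = aln.target[g0:g1]
        b = aln.query[s0:s1]
        m += sum(x == y for x, y in zip(a, b))
        n += g1 - g0
    return m / n if n else 0.0


def _find_j(tail: str, j_ref: str, cfg: SeqQcConfig) -> int | None:
    """Offset of the framework-4 start within the post-V tail, or None."""
    L = len(j_ref)
    if len(tail) <= L:
        return None
    best_at, best_id = None, -1.0
    for at in range(1, len(tail) - L + 1):
        window = tail[at : at + L]
        ident = sum(a == b for a, b in zip(window, j_ref)) / L
        if ident > best_id:
            best_id, best_at = ident, at
    if best_id >= cfg.j_min_identity:
        return best_at
    return None


def number_repertoire(
    records: list[RawSequenceRecord],
    ref: GermlineReference,
    cfg: SeqQcConfig | None = None,
    report: QcReport | None = None,
) -> list[NumberedSequence]:
    """Number and filter a whole repertoire (vectorized ungapped fast path).

    All germline V genes sharing one ungapped length are compared in a
    single matrix pass; sequences below the fast-path identity floor fall
    back to affine-gap alignment.
    """
    cfg = cfg or SeqQcConfig()
    if report is None:
        report = QcReport()
    report.n_input += len(records)
    if not records:
        return []
    names = ref.names
    glens = {len(ref.ungapped(n)) for n in names}
    out: list[NumberedSequence] = []
    seqs = [r.sequence for r in records]
    j_ref = ref.j_tail
    split = cfg.chimera_split

    # identity of each sequence prefix against each germline (per V length)
    n_seq = len(records)
    best_ident = np.zeros(n_seq)
    best_name = np.full(n_seq, "", dtype=object)
    half1_all = np.zeros((n_seq, len(names)))
    half2_all = np.zeros((n_seq, len(names)))
    seq_lens = np.array([len(s) for s in seqs])
    for vlen in sorted(glens):
        idx = [i for i, n in enumerate(names) if len(ref.ungapped(n)) == vlen]
        gmat = _encode([ref.ungapped(names[i]) for i in idx], vlen)
        smat = _encode(seqs, vlen)
        long_enough = seq_lens > vlen + len(j_ref)
        eq = smat[:, None, :] == gmat[None, :, :]        # (n_seq, n_g, vlen)
        ident = eq.mean(axis=2)
        ident[~long_enough, :] = 0.0
        h1 = eq[:, :, :split].mean(axis=2)
        h2 = eq[:, :, split:].mean(axis=2)
        for k, gi in enumerate(idx):
            half1_all[:, gi] = h1[:, k]
            half2_all[:, gi] = h2[:, k]
        gbest = ident.argmax(axis=1)
        gident = ident[np.arange(n_seq), gbest]
        better = gident > best_ident
        best_ident = np.where(better, gident, best_ident)
        for i in np.nonzero(better)[0]:
            best_name[i] = names[idx[gbest[i]]]

    for i, raw in enumerate(records):
        if best_ident[i] < cfg.fast_path_min_identity:
            res = _number_by_alignment(raw, ref, cfg)
        else:
            name = str(best_name[i])
            vlen = len(ref.ungapped(name))
            tail = raw.sequence[vlen:]
            j_at = _find_j_fast(tail, j_ref, cfg)
            if j_at is None:
                res = Rejection(raw.id, "missing_cdr")
            else:
                # chimera: argmax per half with decisive margins
                i1 = int(np.argmax(half1_all[i]))
                i2 = int(np.argmax(half2_all[i]))
                chim = (
                    names[i1] != names[i2]
                    and half1_all[i, i1] - half1_all[i, i2] >= cfg.chimera_margin
                    and half2_all[i, i2] - half2_all[i, i1] >= cfg.chimera_margin
                )
                if chim:
                    res = Rejection(raw.id, "chimeric")
                else:
                    v_pairs = list(
                        zip(ref.positions_of(name), raw.sequence[:vlen])
                    )
                    cdr3 = tail[:j_at]
                    j_seq = tail[j_at : j_at + len(j_ref)]
                    res = _build_numbered(raw, ref, name, v_pairs, cdr3, j_seq, cfg)
        if isinstance(res, Rejection):
            report.rejections[res.reason] += 1
        else:
            out.append(res)
    report.n_numbered += len(out)
    report.n_pass_filters += len(out)
    return out


def _find_j_fast(tail: str, j_ref: str, cfg: SeqQcConfig) -> int | None:
    """J is expected flush with the sequence end; scan only as a fallback."""
    L = len(j_ref)
    if len(tail) <= L:
        return None
    at = len(tail) - L
    ident = sum(a == b for a, b in zip(tail[at:], j_ref)) / L
    if ident >= cfg.j_min_identity:
        return at
    return _find_j(tail, j_ref, cfg)


def number_and_filter(
    raw: RawSequenceRecord,
    ref: GermlineReference,
    cfg: SeqQcConfig | None = None,
) -> NumberedSequence | Rejection:
    """Number one sequence; returns the numbered record or a typed rejection."""
    report = QcReport()
    res = number_repertoire([raw], ref, cfg=cfg, report=report)
    if res:
        return res[0]
    reason = next(iter(report.rejections))
    return Rejection(raw.id, reason)


def select_modellable(
    seqs: list[NumberedSequence],
    min_len: int = 5,
    max_len: int = 16,
    report: QcReport | None = None,
) -> list[NumberedSequence]:
    """Keep sequences whose CDR-H3 length is within [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept = []
    for s in seqs:
        L = len(s.cdrh3_seq)
        if min_len <= L <= max_len:
            kept.append(s)
        elif report is not None:
            report.length_removals[L] += 1
    if report is not None:
        report.n_in_length_range += len(kept)
    return kept


# ---------------------------------------------------------------------------
# germline reference I/O


def read_germline_fasta(path: str | Path) -> GermlineReference:
    """Germline reference from FASTA of IMGT-gapped V genes plus a J entry.

    V-gene records hold 104 characters ('.' marks an unoccupied position);
    a record whose id starts with "IGHJ" supplies the framework-4 tail.
    """
    v_genes: dict[str, dict[str, str]] = {}
    j_tail = ""
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rec.id.upper().startswith("IGHJ"):
            j_tail = seq
            continue
        posmap = {
            str(i + 1): aa for i, aa in enumerate(seq) if aa not in ".-"
        }
        v_genes[rec.id] = posmap
    if not j_tail:
        raise ValueError(f"{path}: no IGHJ record found")
    return GermlineReference(v_genes=v_genes, j_tail=j_tail)


def write_germline_fasta(ref: GermlineReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in ref.names:
            posmap = ref.v_genes[name]
            row = "".join(posmap.get(p, ".") for p in imgt.v_positions())
            fh.write(f">{name}\n{row}\n")
        fh.write(f">IGHJ4\n{ref.j_tail}\n")


def annotations_frame(seqs: list[NumberedSequence]) -> pd.DataFrame:
    """Per-sequence annotation table keyed on sequence_id (AIRR-mergeable)."""
    return pd.DataFrame(
        dict(
            sequence_id=[s.id for s in seqs],
            repertoire_id=[s.repertoire_id for s in seqs],
            v_call=[s.v_gene for s in seqs],
            v_identity=[s.v_identity for s in seqs],
            v_mutation_count=[s.v_mutation_count for s in seqs],
            cdr1_aa=[s.cdrh1_seq for s in seqs],
            cdr2_aa=[s.cdrh2_seq for s in seqs],
            cdr3_aa=[s.cdrh3_seq for s in seqs],
        )
    )
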