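"""CDR-H3 template library: records, metadata TSV, and PDB coordinate I/O.

A template is one crystallographically-solved CDR-H3 loop: its sequence,
ordered backbone coordinates, the species of the source antibody and the
framework sequence of its chain.  The library indexes templates by loop
length (template search never crosses lengths) and by template id.

Coordinates live in PDB-format files (ATOM records, chain + residue-range
selection), read and written through biotite; the searchable metadata is a
single TSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .imgt import AA_SET
from .loopgeom import BackboneLoop

BACKBONE_ATOMS = ("N", "CA", "C")
MIN_LOOP_LEN = 5
MAX_LOOP_LEN = 16


@dataclass(frozen=True)
class TemplateRecord:
    """One solved CDR-H3 loop (id format "pdb_chain", e.g. "5myx_B")."""

    template_id: str
    cdrh3_seq: str
    loop: BackboneLoop
    species: str
    framework_seq: str

    def __post_init__(self) -> None:
        if len(self.loop) != len(self.cdrh3_seq):
            raise ValueError(
                f"{self.template_id}: backbone has {len(self.loop)} residues "
                f"but sequence has {len(self.cdrh3_seq)}"
            )
        if not (MIN_LOOP_LEN <= len(self.cdrh3_seq) <= MAX_LOOP_LEN):
            raise ValueError(
                f"{self.template_id}: loop length {len(self.cdrh3_seq)} "
                f"outside [{MIN_LOOP_LEN}, {MAX_LOOP_LEN}]"
            )
        if not set(self.cdrh3_seq) <= AA_SET:
            raise ValueError(f"{self.template_id}: non-standard residue in loop")

    @property
    def length(self) -> int:
        return len(self.cdrh3_seq)

    @property
    def chain(self) -> str:
        return self.template_id.rsplit("_", 1)[-1]


@dataclass
class TemplateLibrary:
    """Searchable collection of CDR-H3 templates."""

    templates: dict[str, TemplateRecord]
    provenance: str = ""
    _by_length: dict[int, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_len: dict[int, list[str]] = {}
        for tid, rec in self.templates.items():
            if tid != rec.template_id:
                raise ValueError("library key does not match template_id")
            by_len.setdefault(rec.length, []).append(tid)
        self._by_length = {L: sorted(tids) for L, tids in by_len.items()}

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, template_id: str) -> TemplateRecord:
        return self.templates[template_id]

    def __contains__(self, template_id: str) -> bool:
        return template_id in self.templates

    @property
    def template_ids(self) -> list[str]:
        return sorted(self.templates)

    def of_length(self, length: int) -> list[TemplateRecord]:
        """Templates of one loop length, in lexicographic id order."""
        return [self.templates[t] for t in self._by_length.get(length, [])]

    def species_composition(self) -> dict[str, float]:
        """Fraction of library templates per species label."""
        counts: dict[str, int] = {}
        for rec in self.templates.values():
            counts[rec.species] = counts.get(rec.species, 0) + 1
        n = len(self.templates)
        return {sp: c / n for sp, c in sorted(counts.items())}


def loop_to_atom_array(rec: TemplateRecord) -> struc.AtomArray:
    """Backbone loop as a biotite AtomArray (N, CA, C per residue)."""
    n_res = rec.length
    arr = struc.AtomArray(n_res * 3)
    arr.coord = rec.loop.coords.reshape(-1, 3)
    arr.chain_id = np.repeat(rec.chain, n_res * 3)
    arr.res_id = np.repeat(np.arange(1, n_res + 1), 3)
    arr.res_name = np.repeat(
        [_three_letter(aa) for aa in rec.cdrh3_seq], 3
    )
    arr.atom_name = np.tile(np.array(BACKBONE_ATOMS), n_res)
    arr.element = np.tile(np.array(["N", "C", "C"]), n_res)
    arr.hetero = np.zeros(n_res * 3, dtype=bool)
    return arr


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _three_letter(aa: str) -> str:
    return _AA3[aa]


def write_template_pdb(rec: TemplateRecord, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(loop_to_atom_array(rec))
    pdb.write(str(path))


def read_loop_from_pdb(
    path: str | Path, chain: str, res_start: int, res_end: int
) -> BackboneLoop:
    """Backbone loop from a PDB file: chain + inclusive residue range."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    mask = (
        (arr.chain_id == chain)
        & (arr.res_id >= res_start)
        & (arr.res_id <= res_end)
        & np.isin(arr.atom_name, BACKBONE_ATOMS)
    )
    sel = arr[mask]
    res_ids = np.unique(sel.res_id)
    coords = np.empty((len(res_ids), 3, 3))
    for i, rid in enumerate(res_ids):
        res = sel[sel.res_id == rid]
        for j, name in enumerate(BACKBONE_ATOMS):
            atom = res[res.atom_name == name]
            if len(atom) != 1:
                raise ValueError(
                    f"{path}: residue {rid} chain {chain} lacks a unique {name}"
                )
            coords[i, j] = atom.coord[0]
    return BackboneLoop(coords)


def write_library(library: TemplateLibrary, out_dir: str | Path) -> Path:
    """Write a library as metadata TSV + one PDB file per template.

    Returns the metadata TSV path.
    """
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tid in library.template_ids:
        rec = library[tid]
        pdb_path = pdb_dir / f"{tid}.pdb"
        write_template_pdb(rec, pdb_path)
        rows.append(
            dict(
                template_id=tid,
                length=rec.length,
                cdrh3_seq=rec.cdrh3_seq,
                species=rec.species,
                framework_seq=rec.framework_seq,
                pdb_path=str(pdb_path.relative_to(out_dir)),
                chain=rec.chain,
                res_start=1,
                res_end=rec.length,
            )
        )
    meta_path = out_dir / "templates.tsv"
    header = io.StringIO()
    if library.provenance:
        header.write(f"# provenance: {library.provenance}\n")
    pd.DataFrame(rows).to_csv(header, sep="\t", index=False)
    meta_path.write_text(header.getvalue())
    return meta_path


def read_library(meta_path: str | Path) -> TemplateLibrary:
    """Load a library from its metadata TSV (PDB paths relative to it)."""
    meta_path = Path(meta_path)
    provenance = ""
    with open(meta_path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
    df = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"template_id": str})
    templates: dict[str, TemplateRecord] = {}
    for row in df.itertuples(index=False):
        loop = read_loop_from_pdb(
            meta_path.parent / row.pdb_path, str(row.chain),
            int(row.res_start), int(row.res_end),
        )
        rec = TemplateRecord(
            template_id=row.template_id,
            cdrh3_seq=row.cdrh3_seq,
            loop=loop,
            species=row.species,
            framework_seq=row.framework_seq,
        )
        templates[rec.template_id] = rec
    return TemplateLibrary(templates=templates, provenance=provenance)
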