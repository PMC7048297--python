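"""IMGT unique-numbering helpers for heavy-chain variable domains.

The package works on a fixed-occupancy scaffold: framework and CDR-H1/H2
positions 1-104, the CDR-H3 junction 105-117 (with insertion codes for
loops longer than 13 residues), and framework 4 from position 118.
Positions are represented as strings ("104", "111.1") so insertion codes
sort and serialize naturally.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)
ALPHABET = AA_SET | {"X"}

# region boundaries (inclusive) on the scaffold used throughout the package
CDR1_RANGE = (27, 38)
CDR2_RANGE = (56, 65)
CDR3_RANGE = (105, 117)
V_END = 104          # last V-gene position
FW4_START = 118      # first framework-4 position (conserved W/F)

#: default conserved-residue checks: IMGT Cys23, Trp41, Cys104, W/F 118
CONSERVED_POSITIONS: tuple[tuple[str, str], ...] = (
    ("23", "C"),
    ("41", "W"),
    ("104", "C"),
    ("118", "WF"),
)


def v_positions() -> list[str]:
    """Ordered V-domain positions 1..104 on the fixed scaffold."""
    return [str(i) for i in range(1, V_END + 1)]


def region_of(pos: str) -> str:
    """Region label (fw1, cdr1, fw2, cdr2, fw3, cdr3, fw4) of a position."""
    base = int(pos.split(".")[0])
    if base < CDR1_RANGE[0]:
        return "fw1"
    if base <= CDR1_RANGE[1]:
        return "cdr1"
    if base < CDR2_RANGE[0]:
        return "fw2"
    if base <= CDR2_RANGE[1]:
        return "cdr2"
    if base < CDR3_RANGE[0]:
        return "fw3"
    if base <= CDR3_RANGE[1]:
        return "cdr3"
    return "fw4"


def cdr3_positions(length: int) -> list[str]:
    """Ordered IMGT positions occupied by a CDR-H3 of the given length.

    For length <= 13 the loop fills 105.. and ..117 symmetrically from the
    anchors inward (the apex positions 111/112 are vacated first).  Longer
    loops gain insertion codes 111.1.. / ..112.1 at the apex.
    """
    if length < 1:
        raise ValueError("CDR-H3 length must be positive")
    left = [str(p) for p in range(105, 112)]    # 105..111
    right = [str(p) for p in range(112, 118)]   # 112..117
    if length <= 13:
        a = (length + 1) // 2
        b = length - a
        return left[:a] + (right[-b:] if b else [])
    n_ins = length - 13
    n_right = (n_ins + 1) // 2
    n_left = n_ins - n_right
    ins_left = [f"111.{i}" for i in range(1, n_left + 1)]
    ins_right = [f"112.{i}" for i in range(n_right, 0, -1)]
    return left + ins_left + ins_right + right


def fw4_positions(length: int) -> list[str]:
    """Ordered framework-4 positions 118.. for a J tail of the given length."""
    return [str(i) for i in range(FW4_START, FW4_START + length)]
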