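"""Variant RING zinc-finger detection and classification.

The canonical RING pattern is C-x2-C-x(9..39)-C-x(1..3)-H-x(2..3)-C-x2-C-
x(4..48)-C-x2-C: eight coordinating residues ("slots") arranged in a
cross-brace, with slots 1, 2, 5, 6 forming active site S1 and slots 3, 4,
7, 8 forming site S2; each intact site chelates one zinc ion. Functional
variants substitute serine/threonine (RING-S/T) or glycine (RING-G) at
coordinating slots; families showing both substitution types, or sites too
degraded to identify, lose zinc coordination.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .logos import LogoMatrix

S1_SLOTS = (1, 2, 5, 6)
S2_SLOTS = (3, 4, 7, 8)
COORDINATING = set("CH")
IDENTIFIABLE = set("CHSTG")
SPACER_BOUNDS = ((2, 2), (9, 39), (1, 3), (2, 3), (2, 2), (4, 48), (2, 2))
# default C-terminal search window for MAEA-like RING-like regions
C_TERMINAL_WINDOW = 120

VARIANTS = ("RING-HC", "RING-S/T", "RING-G", "mixed", "degenerate", "none")


@dataclass(frozen=True)
class RingMatch:
    """The eight coordinating positions of one RING pattern match."""

    sequence_id: str
    slot_positions: tuple[int, ...]  # 1-based residue indices, slots 1-8
    slot_residues: tuple[str, ...]

    def __post_init__(self):
        if len(self.slot_positions) != 8 or len(self.slot_residues) != 8:
            raise ValueError("a RING match has exactly 8 slots")
        if any(b <= a for a, b in zip(self.slot_positions, self.slot_positions[1:])):
            raise ValueError("slot positions must be strictly increasing")

    @property
    def spacer_lengths(self) -> tuple[int, ...]:
        return tuple(
            self.slot_positions[i + 1] - self.slot_positions[i] - 1
            for i in range(7)
        )

    @property
    def s1_residues(self) -> tuple[str, ...]:
        return tuple(self.slot_residues[i - 1] for i in S1_SLOTS)

    @property
    def s2_residues(self) -> tuple[str, ...]:
        return tuple(self.slot_residues[i - 1] for i in S2_SLOTS)


@dataclass(frozen=True)
class RingClassification:
    variant: str
    zinc_ions: int
    slot_residues: tuple[str, ...]
    s1_intact: bool
    s2_intact: bool


def _slot_pattern(slot: int, relaxed_slots: set[int] | None) -> str:
    base = "H" if slot == 4 else "C"
    if relaxed_slots and slot in relaxed_slots:
        return f"[{base}STG]"
    return base


def _build_regex(relaxed_slots: set[int] | None) -> re.Pattern:
    parts = []
    for slot in range(1, 9):
        parts.append(f"({_slot_pattern(slot, relaxed_slots)})")
        if slot < 8:
            lo, hi = SPACER_BOUNDS[slot - 1]
            lazy = "?" if lo != hi else ""
            parts.append(f".{{{lo},{hi}}}{lazy}" if lo != hi else f".{{{lo}}}")
    return re.compile("".join(parts))


def match_ring_pattern(
    sequence: str,
    sequence_id: str = "query",
    relaxed_slots: set[int] | None = None,
    c_terminal_window: int | None = None,
) -> RingMatch | None:
    """Leftmost (shortest-spacer) match of the RING spacing pattern.

    ``relaxed_slots`` lists slot numbers (1–8) where S, T or G may stand in
    for the canonical residue. ``c_terminal_window`` restricts the search to
    the final N residues — the default place to look for the elongated
    RING-like regions of MAEA-type proteins. Positions are always reported
    in full-sequence 1-based coordinates. No match returns ``None``.
    """
    offset = 0
    region = sequence.upper()
    if c_terminal_window is not None and len(region) > c_terminal_window:
        offset = len(region) - c_terminal_window
        region = region[offset:]
    found = _build_regex(relaxed_slots).search(region)
    if found is None:
        return None
    positions = tuple(found.start(g) + 1 + offset for g in range(1, 9))
    residues = tuple(found.group(g) for g in range(1, 9))
    return RingMatch(sequence_id, positions, residues)


def classify_ring_variant(slot_residues) -> RingClassification:
    """Classify eight slot consensus residues into a RING variant.

    Residues may come from a single sequence's pattern match or from a
    family logo's top residues ('?' marks slots with no residue conserved
    above the identification threshold). Zinc count = number of sites
    whose four slots are all C/H.
    """
    residues = tuple(str(r).upper() for r in slot_residues)
    if len(residues) != 8:
        raise ValueError(f"expected 8 slot residues, got {len(residues)}")

    def site(slots):
        return [residues[i - 1] for i in slots]

    def intact(slots):
        return all(r in COORDINATING for r in site(slots))

    s1_ok, s2_ok = intact(S1_SLOTS), intact(S2_SLOTS)
    zinc = int(s1_ok) + int(s2_ok)
    canonical = all(
        residues[i - 1] == ("H" if i == 4 else "C") for i in range(1, 9)
    )
    s_subs = sum(1 for r in residues if r in "ST")
    g_subs = sum(1 for r in residues if r == "G")

    def st_site(slots):
        return sum(1 for r in site(slots) if r in "ST") >= 2

    def g_site(slots):
        return sum(1 for r in site(slots) if r == "G") >= 2

    if canonical:
        variant = "RING-HC"
    elif s_subs and g_subs:
        variant = "mixed"
    elif (st_site(S1_SLOTS) and s2_ok) or (st_site(S2_SLOTS) and s1_ok):
        variant = "RING-S/T"
    elif (g_site(S1_SLOTS) and s2_ok) or (g_site(S2_SLOTS) and s1_ok):
        variant = "RING-G"
    else:
        identifiable = [
            sum(1 for r in site(slots) if r in IDENTIFIABLE)
            for slots in (S1_SLOTS, S2_SLOTS)
        ]
        variant = "degenerate" if min(identifiable) < 3 or zinc == 0 else (
            "RING-S/T" if s_subs else ("RING-G" if g_subs else "degenerate")
        )
    return RingClassification(variant, zinc, residues, s1_ok, s2_ok)


def slot_consensus_from_logo(
    logo: LogoMatrix, slot_columns: tuple[int, ...], min_bits: float = 1.0
) -> tuple[str, ...]:
    """Family-level slot residues: top logo residue where height >= min_bits.

    ``slot_columns`` are 1-based logo positions of the eight slots; slots
    conserved below the threshold come back as '?'.
    """
    if len(slot_columns) != 8:
        raise ValueError("need 8 slot columns")
    residues = []
    for col in slot_columns:
        residue, height = logo.top_residue(col - 1)
        residues.append(residue if height >= min_bits else "?")
    return tuple(residues)


def conserved_prolines(
    family_logo: LogoMatrix,
    slot_columns: tuple[int, ...],
    min_bits: float = 2.0,
) -> list[tuple[int, str, float]]:
    """Logo positions with a proline conserved above ``min_bits``.

    Returns (1-based logo position, label relative to the nearest slot,
    e.g. 'slot7+1', height in bits).
    """
    flagged = []
    for col in range(family_logo.n_columns):
        if family_logo.n_effective[col] == 0:
            continue
        residue, height = family_logo.top_residue(col)
        if residue != "P" or height < min_bits:
            continue
        position = col + 1
        nearest = min(range(8), key=lambda k: abs(slot_columns[k] - position))
        delta = position - slot_columns[nearest]
        label = f"slot{nearest + 1}{delta:+d}" if delta else f"slot{nearest + 1}"
        flagged.append((position, label, height))
    return flagged


def classification_report(classifications: dict[str, RingClassification]) -> str:
    """TSV report: id, variant, zinc count, slot residues."""
    lines = ["id\tvariant\tzinc_ions\tslot_residues\ts1_intact\ts2_intact"]
    for seq_id in sorted(classifications):
        c = classifications[seq_id]
        lines.append(
            f"{seq_id}\t{c.variant}\t{c.zinc_ions}\t{''.join(c.slot_residues)}"
            f"\t{c.s1_intact}\t{c.s2_intact}"
        )
    return "\n".join(lines) + "\n"
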