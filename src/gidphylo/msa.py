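"""Progressive multiple sequence alignment over a UPGMA guide tree.

A deterministic, desk-scale progressive aligner: pairwise k-mer distances
feed average-linkage (UPGMA) clustering; profiles are merged bottom-up with
an affine-gap Gotoh recursion over expected sum-of-pairs BLOSUM scores.
Once a gap is introduced into a profile it is never removed. Input order is
canonicalised (sorted by id) so results do not depend on file order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio_align import AMINO_ACIDS, ProteinRecord, ScoringScheme

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MultipleAlignment:
    """Ordered gapped rows of equal length."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def row(self, rec_id: str) -> str:
        return self.rows[rec_id]

    def degapped(self, rec_id: str) -> str:
        return self.rows[rec_id].replace("-", "")

    def column(self, index: int) -> str:
        return "".join(self.rows[i][index] for i in self.ids)

    def to_fasta(self, destination) -> None:
        def emit(fh):
            for rec_id in self.ids:
                fh.write(f">{rec_id}\n")
                seq = self.rows[rec_id]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

        if hasattr(destination, "write"):
            emit(destination)
        else:
            with open(destination, "w") as fh:
                emit(fh)


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

def _kmer_profile(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_distance_matrix(records: list[ProteinRecord], k: int = 3) -> np.ndarray:
    """1 − shared-k-mer fraction, a fast guide-tree distance."""
    profiles = [_kmer_profile(r.sequence, min(k, len(r.sequence))) for r in records]
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(profiles[i]), len(profiles[j]))
            shared = len(profiles[i] & profiles[j]) / denom if denom else 0.0
            dist[i, j] = dist[j, i] = 1.0 - shared
    return dist


def build_guide_tree(records: list[ProteinRecord], k: int = 3):
    """Rooted UPGMA guide tree as nested tuples of record ids.

    Leaves are ids; internal nodes are ``(left, right)`` pairs. Input is
    sorted by id first, so the tree is order-independent.
    """
    if len(records) < 2:
        raise ValueError("guide tree needs at least 2 records")
    records = sorted(records, key=lambda r: r.id)
    dist = kmer_distance_matrix(records, k)
    merges = linkage(squareform(dist, checks=False), method="average")
    nodes: list = [r.id for r in records]
    for left, right, _, _ in merges:
        nodes.append((nodes[int(left)], nodes[int(right)]))
    return nodes[-1]


def _tree_leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _tree_leaves(node[0]) + _tree_leaves(node[1])


# ---------------------------------------------------------------------------
# Profile alignment
# ---------------------------------------------------------------------------

def _profile(alignment: dict[str, str], ids: list[str]) -> np.ndarray:
    """Columns × 20 residue frequency matrix (gaps and X contribute zero)."""
    n_cols = len(alignment[ids[0]])
    prof = np.zeros((n_cols, 20))
    for rec_id in ids:
        for col, letter in enumerate(alignment[rec_id]):
            idx = _AA_INDEX.get(letter)
            if idx is not None:
                prof[col, idx] += 1.0
    return prof / max(len(ids), 1)


def _substitution_array(scheme: ScoringScheme) -> np.ndarray:
    matrix = scheme.matrix
    sub = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sub[i, j] = matrix[a][b]
    return sub


def _align_profiles(
    prof_a: np.ndarray, prof_b: np.ndarray, scheme: ScoringScheme
) -> list[tuple[bool, bool]]:
    """Gotoh affine DP over expected column scores.

    Returns the traceback as a list of (consume_a, consume_b) column
    operations. Ties prefer match over gap-in-b over gap-in-a.
    """
    sub = _substitution_array(scheme)
    score = prof_a @ sub @ prof_b.T
    la, lb = score.shape
    go, ge = scheme.gap_open, scheme.gap_extend
    neg = -np.inf
    m = np.full((la + 1, lb + 1), neg)
    gap_a = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    gap_b = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    m[0, 0] = 0.0
    for j in range(1, lb + 1):
        gap_a[0, j] = -go - (j - 1) * ge
    for i in range(1, la + 1):
        gap_b[i, 0] = -go - (i - 1) * ge
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best_prev = max(m[i - 1, j - 1], gap_a[i - 1, j - 1], gap_b[i - 1, j - 1])
            m[i, j] = best_prev + score[i - 1, j - 1]
            gap_a[i, j] = max(m[i, j - 1] - go, gap_a[i, j - 1] - ge)
            gap_b[i, j] = max(m[i - 1, j] - go, gap_b[i - 1, j] - ge)
    ops: list[tuple[bool, bool]] = []
    i, j = la, lb
    state = int(np.argmax([m[i, j], gap_b[i, j], gap_a[i, j]]))
    while i > 0 or j > 0:
        if i == 0:
            ops.append((False, True))
            j -= 1
            continue
        if j == 0:
            ops.append((True, False))
            i -= 1
            continue
        if state == 0:
            ops.append((True, True))
            prev = [m[i - 1, j - 1], gap_b[i - 1, j - 1], gap_a[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # gap in B, consume A
            ops.append((True, False))
            if m[i - 1, j] - scheme.gap_open >= gap_b[i - 1, j] - scheme.gap_extend:
                state = 0
            i -= 1
        else:  # gap in A, consume B
            ops.append((False, True))
            if m[i, j - 1] - scheme.gap_open >= gap_a[i, j - 1] - scheme.gap_extend:
                state = 0
            j -= 1
    ops.reverse()
    return ops


def _merge(
    aln_a: dict[str, str], ids_a: list[str],
    aln_b: dict[str, str], ids_b: list[str],
    scheme: ScoringScheme,
) -> dict[str, str]:
    ops = _align_profiles(_profile(aln_a, ids_a), _profile(aln_b, ids_b), scheme)
    merged: dict[str, str] = {}
    for rec_id in ids_a:
        src = aln_a[rec_id]
        pos = 0
        out = []
        for take_a, _ in ops:
            if take_a:
                out.append(src[pos])
                pos += 1
            else:
                out.append("-")
        merged[rec_id] = "".join(out)
    for rec_id in ids_b:
        src = aln_b[rec_id]
        pos = 0
        out = []
        for _, take_b in ops:
            if take_b:
                out.append(src[pos])
                pos += 1
            else:
                out.append("-")
        merged[rec_id] = "".join(out)
    return merged


def progressive_msa(
    records: list[ProteinRecord], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Align records progressively along the UPGMA guide tree.

    Row order in the result follows the guide tree's leaf order.
    """
    if not records:
        raise ValueError("no records to align")
    scheme = scheme or ScoringScheme()
    if len(records) == 1:
        rec = records[0]
        return MultipleAlignment([rec.id], {rec.id: rec.sequence})
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")
    tree = build_guide_tree(records)

    def align_node(node) -> tuple[dict[str, str], list[str]]:
        if isinstance(node, str):
            return {node: by_id[node].sequence}, [node]
        left, ids_l = align_node(node[0])
        right, ids_r = align_node(node[1])
        return _merge(left, ids_l, right, ids_r, scheme), ids_l + ids_r

    aln, ids = align_node(tree)
    return MultipleAlignment(ids, aln)


# ---------------------------------------------------------------------------
# Reference-region mapping
# ---------------------------------------------------------------------------

def map_reference_region(
    msa: MultipleAlignment, ref_id: str, ref_range: tuple[int, int]
) -> dict[str, tuple[int, int] | None]:
    """Project a reference's 1-based inclusive residue range onto all rows.

    Returns per-row 1-based inclusive intervals in each row's own ungapped
    coordinates; rows entirely gapped across the region map to ``None``.
    """
    if ref_id not in msa.rows:
        raise KeyError(f"unknown reference id {ref_id!r}")
    start, end = ref_range
    ref_row = msa.rows[ref_id]
    ref_len = len(ref_row.replace("-", ""))
    if not (1 <= start <= end <= ref_len):
        raise ValueError(f"range {start}-{end} outside reference length {ref_len}")
    # alignment columns occupied by reference residues start..end
    residue = 0
    col_start = col_end = None
    for col, letter in enumerate(ref_row):
        if letter != "-":
            residue += 1
            if residue == start:
                col_start = col
            if residue == end:
                col_end = col
                break
    assert col_start is not None and col_end is not None
    result: dict[str, tuple[int, int] | None] = {}
    for rec_id in msa.ids:
        row = msa.rows[rec_id]
        before = sum(1 for c in row[:col_start] if c != "-")
        inside = sum(1 for c in row[col_start : col_end + 1] if c != "-")
        result[rec_id] = None if inside == 0 else (before + 1, before + inside)
    return result


def extract_region_records(
    msa: MultipleAlignment, ref_id: str, ref_range: tuple[int, int]
) -> MultipleAlignment:
    """Slice the alignment to the columns spanned by a reference range."""
    if ref_id not in msa.rows:
        raise KeyError(f"unknown reference id {ref_id!r}")
    start, end = ref_range
    ref_row = msa.rows[ref_id]
    residue = 0
    col_start = col_end = None
    for col, letter in enumerate(ref_row):
        if letter != "-":
            residue += 1
            if residue == start:
                col_start = col
            if residue == end:
                col_end = col
                break
    if col_start is None or col_end is None:
        raise ValueError("reference range outside alignment")
    rows = {i: msa.rows[i][col_start : col_end + 1] for i in msa.ids}
    return MultipleAlignment(list(msa.ids), rows)
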