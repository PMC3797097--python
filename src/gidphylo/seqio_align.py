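"""Protein sequence I/O, pairwise alignment and molecular-mass prediction.

Pairwise alignment follows the Gotoh affine-gap formulation (three-state
dynamic programming) as exposed by :class:`Bio.Align.PairwiseAligner`;
global alignments penalise end gaps by default so that percent identities
are computed over a true end-to-end alignment. Scores use BLOSUM62 with
gap-open 10 and gap-extend 0.5 unless a different :class:`ScoringScheme`
is supplied.

Coordinates are 0-based half-open internally; everything user-facing
(reports, domain tables) is 1-based inclusive.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = set(AMINO_ACIDS) | {"X"}

# Average (isotope-abundance-weighted) residue masses in daltons.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576,
    "N": 114.1026, "D": 115.0874, "Q": 128.1292, "K": 128.1723,
    "E": 129.1155, "M": 131.1961, "H": 137.1393, "F": 147.1739,
    "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}
WATER_MASS = 18.0153
# mean over the 20 residue masses; used for X only when explicitly enabled
AVERAGE_UNKNOWN_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with species and taxonomy lineage labels.

    ``lineage`` is ordered from the broadest label (supergroup) down to the
    species.
    """

    id: str
    sequence: str
    species: str = ""
    lineage: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, letter in enumerate(self.sequence):
            if letter not in ALLOWED_LETTERS:
                raise ValueError(
                    f"record {self.id!r}: illegal character {letter!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. With
    ``end_gaps`` true (default) terminal gaps are penalised like internal
    ones, giving a true end-to-end global alignment.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps: bool = True

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored pairwise alignment with gapped rows of equal length."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str = "global"

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)

    @property
    def identical_columns(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def identity_fraction(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return self.identical_columns / self.alignment_length

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, tuple[str, ...]]:
    """Split an ``id|species|lineage`` header; lineage labels separated by ';'."""
    parts = header.split("|")
    rec_id = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 else ""
    lineage: tuple[str, ...] = ()
    if len(parts) > 2 and parts[2].strip():
        lineage = tuple(x.strip() for x in parts[2].split(";") if x.strip())
    return rec_id, species, lineage


def read_fasta(source) -> list[ProteinRecord]:
    """Read protein records from a FASTA path or text stream.

    Headers may carry species and lineage as ``id|species|g1;g2;...``.
    Sequences are upper-cased and a single trailing ``'*'`` stop character
    is stripped. Duplicate ids and illegal characters raise ``ValueError``;
    an empty file returns an empty list with a warning.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        rec_id, species, lineage = _parse_header(header)
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(ProteinRecord(rec_id, seq, species, lineage))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise ValueError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        warnings.warn("FASTA input contained no records")
    return records


def write_fasta(records, destination, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""

    def emit(fh):
        for rec in records:
            header = rec.id
            if rec.species or rec.lineage:
                header += f"|{rec.species}"
            if rec.lineage:
                header += "|" + ";".join(rec.lineage)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")

    if hasattr(destination, "write"):
        emit(destination)
    else:
        with open(destination, "w") as fh:
            emit(fh)


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    aligner.mode = mode
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    if mode == "global" and not scheme.end_gaps:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _check_sequences(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")


def _clean(seq: str) -> str:
    """Residues absent from the matrix alphabet are treated as X."""
    return "".join(c if c in ALLOWED_LETTERS else "X" for c in seq.upper())


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    The first alignment in the aligner's deterministic enumeration order is
    reported, giving a reproducible canonical traceback.
    """
    scheme = scheme or ScoringScheme()
    _check_sequences(a, b)
    a, b = _clean(a), _clean(b)
    aligner = _make_aligner(scheme, "global")
    alignments = aligner.align(a, b)
    best = alignments[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), best.score, "global")


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Smith–Waterman local alignment; score is never negative.

    When no residue pair scores positively the empty alignment with score 0
    is returned.
    """
    scheme = scheme or ScoringScheme()
    _check_sequences(a, b)
    a, b = _clean(a), _clean(b)
    aligner = _make_aligner(scheme, "local")
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return PairwiseAlignment("", "", 0.0, "local")
    if best.score <= 0:
        return PairwiseAlignment("", "", 0.0, "local")
    return PairwiseAlignment(str(best[0]), str(best[1]), best.score, "local")


def percent_identity(
    alignment: PairwiseAlignment, denominator: str = "alignment_length"
) -> float:
    """Percent identity of a pairwise alignment.

    ``denominator`` is ``alignment_length`` (EMBOSS convention, default) or
    ``shorter_sequence``.
    """
    if alignment.alignment_length == 0:
        raise ValueError("empty alignment has no percent identity")
    if denominator == "alignment_length":
        denom = alignment.alignment_length
    elif denominator == "shorter_sequence":
        ua, ub = alignment.degapped()
        denom = min(len(ua), len(ub))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * alignment.identical_columns / denom


def molecular_mass(
    sequence: str,
    residue_range: tuple[int, int] | None = None,
    allow_unknown: bool = False,
) -> float:
    """Predicted average molecular mass in daltons.

    ``residue_range`` is 1-based inclusive. ``X`` residues raise unless
    ``allow_unknown`` substitutes the mean residue mass.
    """
    if residue_range is not None:
        start, end = residue_range
        if not (1 <= start <= end <= len(sequence)):
            raise ValueError(
                f"range {start}-{end} outside sequence of length {len(sequence)}"
            )
        sequence = sequence[start - 1 : end]
    total = WATER_MASS
    for pos, letter in enumerate(sequence.upper()):
        if letter in AVERAGE_RESIDUE_MASS:
            total += AVERAGE_RESIDUE_MASS[letter]
        elif letter == "X" and allow_unknown:
            total += AVERAGE_UNKNOWN_MASS
        else:
            raise ValueError(f"no mass for residue {letter!r} at position {pos + 1}")
    return total


def alignment_report(alignment: PairwiseAlignment, id_a: str = "A", id_b: str = "B") -> str:
    """EMBOSS-needle-like text report of a pairwise alignment."""
    ident = alignment.identical_columns
    length = alignment.alignment_length
    pct = 100.0 * ident / length if length else 0.0
    out = io.StringIO()
    out.write(f"# Aligned: {id_a} vs {id_b}\n")
    out.write(f"# Length: {length}\n")
    out.write(f"# Identity: {ident}/{length} ({pct:.1f}%)\n")
    out.write(f"# Score: {alignment.score:.1f}\n")
    for i in range(0, length, 60):
        out.write(f"{id_a:<12}{alignment.aligned_a[i:i + 60]}\n")
        out.write(f"{id_b:<12}{alignment.aligned_b[i:i + 60]}\n\n")
    return out.getvalue()
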