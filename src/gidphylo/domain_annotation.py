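"""Domain annotations, architectures and the fixed-window fall-back.

Annotations use 1-based inclusive residue coordinates, matching the
InterProScan-style tables they are parsed from. When only one of the
LisH/CTLH pair is annotated, the missing partner is inferred from a fixed
window: 50 aa N-terminal to a CTLH domain is taken as LisH, 70 aa
C-terminal to a LisH domain as CTLH. Windows are clipped at sequence
bounds and at neighbouring annotations rather than rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqio_align import AMINO_ACIDS

DOMAIN_TYPES = (
    "LisH", "CTLH", "CRA", "RING", "SPRY", "kelch",
    "WD40", "armadillo", "discoidin", "other",
)

LISH_WINDOW = 50   # aa N-terminal to CTLH taken to correspond to LisH
CTLH_WINDOW = 70   # aa C-terminal to LisH taken to correspond to CTLH

# default external id -> internal type map (InterPro / SMART / Pfam ids)
DEFAULT_DOMAIN_ID_MAP = {
    "IPR006594": "LisH", "SM00667": "LisH", "PF08513": "LisH", "LisH": "LisH",
    "IPR006595": "CTLH", "SM00668": "CTLH", "PF10607": "CTLH", "CTLH": "CTLH",
    "IPR013144": "CRA", "SM00757": "CRA", "CRA": "CRA",
    "IPR001841": "RING", "SM00184": "RING", "PF13639": "RING", "RING": "RING",
    "IPR003877": "SPRY", "SM00449": "SPRY", "SPRY": "SPRY",
    "IPR006652": "kelch", "SM00612": "kelch", "kelch": "kelch",
    "IPR001680": "WD40", "SM00320": "WD40", "WD40": "WD40",
    "IPR000225": "armadillo", "SM00185": "armadillo", "armadillo": "armadillo",
    "IPR002049": "discoidin", "SM00231": "discoidin", "discoidin": "discoidin",
}

# Reference architecture templates for the eight complex components.
ARCHITECTURE_TEMPLATES: dict[str, tuple[str, ...]] = {
    "TWA1": ("LisH", "CTLH", "CRA"),
    "RanBPM": ("SPRY", "LisH", "CTLH", "CRA"),
    "Rmnd5": ("LisH", "CTLH", "CRA", "RING"),
    "MAEA": ("LisH", "CTLH", "CRA", "RING"),
    "muskelin": ("discoidin", "LisH", "CTLH", "kelch", "kelch", "kelch",
                 "kelch", "kelch", "kelch"),
    "Armc8": ("armadillo", "armadillo", "armadillo"),
    "WDR26": ("LisH", "CTLH", "WD40", "WD40"),
    "c17orf39": ("other", "other"),  # two generic conserved regions
}

COMPONENTS = tuple(ARCHITECTURE_TEMPLATES)


@dataclass(frozen=True)
class DomainAnnotation:
    """A typed domain interval on a protein, 1-based inclusive."""

    protein_id: str
    domain_type: str
    start: int
    end: int
    score: float | None = None
    source: str = "annotated"  # annotated | inferred_window | pssm_scan

    def __post_init__(self):
        if self.domain_type not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid interval {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ArchitectureMatch:
    matched: bool
    matched_domains: int
    order_violations: int


def parse_domain_table(
    source,
    domain_id_map: dict[str, str] | None = None,
    sequence_lengths: dict[str, int] | None = None,
) -> list[DomainAnnotation]:
    """Parse an InterProScan-like TSV (protein id, domain id, start, end, score).

    Unmapped domain ids are retained as type ``other``. Rows with start > end
    or coordinates beyond the known sequence length raise with the offending
    rows listed.
    """
    id_map = dict(DEFAULT_DOMAIN_ID_MAP)
    if domain_id_map:
        id_map.update(domain_id_map)
    table = pd.read_csv(
        source, sep="\t", header=None,
        names=["protein_id", "domain_id", "start", "end", "score"],
        comment="#",
    )
    bad: list[str] = []
    annotations: list[DomainAnnotation] = []
    for row in table.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start > end or start < 1:
            bad.append(f"{row.protein_id} {row.domain_id} {start}-{end}")
            continue
        if sequence_lengths and row.protein_id in sequence_lengths:
            if end > sequence_lengths[row.protein_id]:
                bad.append(
                    f"{row.protein_id} {row.domain_id} {start}-{end} "
                    f"(length {sequence_lengths[row.protein_id]})"
                )
                continue
        score = None if pd.isna(row.score) else float(row.score)
        annotations.append(DomainAnnotation(
            row.protein_id, id_map.get(str(row.domain_id), "other"),
            start, end, score,
        ))
    if bad:
        raise ValueError("invalid domain rows: " + "; ".join(bad))
    annotations.sort(key=lambda a: (a.protein_id, a.start, a.end))
    return annotations


def write_domain_table(annotations, destination) -> None:
    """BED-like TSV output (1-based inclusive coordinates)."""
    frame = pd.DataFrame(
        [(a.protein_id, a.domain_type, a.start, a.end, a.score, a.source)
         for a in annotations],
        columns=["protein_id", "domain_type", "start", "end", "score", "source"],
    )
    frame.to_csv(destination, sep="\t", index=False)


def infer_missing_domain(
    annotations: list[DomainAnnotation], protein_length: int
) -> list[DomainAnnotation]:
    """Add the missing partner of an isolated LisH or CTLH annotation.

    Given only CTLH at [s, e]: LisH is placed at [s-50, s-1]; given only
    LisH at [s, e]: CTLH at [e+1, e+70]. Windows are clipped to sequence
    bounds and truncated at neighbouring annotations; a window that
    collapses to zero length adds nothing. Idempotent: proteins already
    carrying both domains (or neither) pass through unchanged.
    """
    anns = sorted(annotations, key=lambda a: a.start)
    has_lish = any(a.domain_type == "LisH" for a in anns)
    has_ctlh = any(a.domain_type == "CTLH" for a in anns)
    if has_lish == has_ctlh:
        if not anns or (has_lish and has_ctlh):
            pass
        else:
            warnings.warn("neither or both of LisH/CTLH present; nothing inferred")
        return anns
    if has_ctlh:
        ctlh = next(a for a in anns if a.domain_type == "CTLH")
        start = max(1, ctlh.start - LISH_WINDOW)
        end = ctlh.start - 1
        # truncate at the nearest annotation ending before the CTLH
        for other in anns:
            if other is not ctlh and other.end < ctlh.start:
                start = max(start, other.end + 1)
        if end < start:
            warnings.warn(f"{ctlh.protein_id}: inferred LisH window collapsed")
            return anns
        new = DomainAnnotation(ctlh.protein_id, "LisH", start, end,
                               source="inferred_window")
    else:
        lish = next(a for a in anns if a.domain_type == "LisH")
        start = lish.end + 1
        end = min(protein_length, lish.end + CTLH_WINDOW)
        for other in anns:
            if other is not lish and other.start > lish.end:
                end = min(end, other.start - 1)
        if end < start:
            warnings.warn(f"{lish.protein_id}: inferred CTLH window collapsed")
            return anns
        new = DomainAnnotation(lish.protein_id, "CTLH", start, end,
                               source="inferred_window")
    return sorted(anns + [new], key=lambda a: a.start)


# ---------------------------------------------------------------------------
# PSSM scan
# ---------------------------------------------------------------------------

class Pssm:
    """Log-odds position-specific scoring matrix over the 20 amino acids.

    Built from aligned example sequences with per-cell pseudocount 0.5 and a
    uniform 1/20 background.
    """

    def __init__(self, log_odds: np.ndarray, domain_type: str = "other"):
        if log_odds.ndim != 2 or log_odds.shape[1] != 20:
            raise ValueError("log-odds matrix must be columns x 20")
        self.log_odds = log_odds
        self.domain_type = domain_type

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_sequences(cls, sequences: list[str], domain_type: str = "other",
                       pseudocount: float = 0.5) -> "Pssm":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("PSSM training sequences must be equal length")
        width = lengths.pop()
        counts = np.full((width, 20), pseudocount)
        index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for seq in sequences:
            for col, letter in enumerate(seq.upper()):
                if letter in index:
                    counts[col, index[letter]] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.log2(freqs / (1.0 / 20.0)), domain_type)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        total = 0.0
        for col, letter in enumerate(window.upper()):
            if letter in index:
                total += self.log_odds[col, index[letter]]
            # X / unknown contributes 0 (background)
        return total


def scan_motif(
    sequence: str, pssm: Pssm, threshold: float,
    protein_id: str = "query",
) -> list[DomainAnnotation]:
    """All windows scoring >= threshold, greedily non-overlapping best-first."""
    width = len(pssm)
    if width > len(sequence):
        warnings.warn("PSSM longer than sequence; no scan performed")
        return []
    hits: list[tuple[float, int]] = []
    for offset in range(len(sequence) - width + 1):
        score = pssm.score_window(sequence[offset : offset + width])
        if score >= threshold:
            hits.append((score, offset))
    hits.sort(key=lambda h: (-h[0], h[1]))
    chosen: list[DomainAnnotation] = []
    occupied: list[tuple[int, int]] = []
    for score, offset in hits:
        span = (offset, offset + width - 1)
        if any(not (span[1] < s or span[0] > e) for s, e in occupied):
            continue
        occupied.append(span)
        chosen.append(DomainAnnotation(
            protein_id, pssm.domain_type, offset + 1, offset + width,
            score=score, source="pssm_scan",
        ))
    chosen.sort(key=lambda a: a.start)
    return chosen


def architecture_match(
    annotations: list[DomainAnnotation],
    template: str | tuple[str, ...],
    min_domains: int = 2,
) -> ArchitectureMatch:
    """Does the protein carry >= min_domains of the template types in order?

    Subsequence match on domain types: extra, non-template domains are
    ignored. The two-domain lower limit mirrors the dataset-curation rule
    that single-domain candidates (e.g. a lone RING) are not accepted.
    """
    if isinstance(template, str):
        if template not in ARCHITECTURE_TEMPLATES:
            raise KeyError(f"unknown architecture template {template!r}")
        template_types = ARCHITECTURE_TEMPLATES[template]
    else:
        template_types = tuple(template)
    observed = [a.domain_type for a in sorted(annotations, key=lambda a: a.start)]
    # longest-common-subsequence style greedy walk through the template
    t_pos = 0
    matched = 0
    violations = 0
    for dom in observed:
        if dom not in template_types:
            continue
        advanced = False
        for k in range(t_pos, len(template_types)):
            if template_types[k] == dom:
                matched += 1
                t_pos = k + 1
                advanced = True
                break
        if not advanced:
            violations += 1
    return ArchitectureMatch(
        matched=matched >= min_domains and violations == 0,
        matched_domains=matched,
        order_violations=violations,
    )


def architecture_of(annotations: list[DomainAnnotation]) -> tuple[str, ...]:
    """Ordered domain-type tuple of a protein's annotations."""
    return tuple(a.domain_type for a in sorted(annotations, key=lambda a: a.start))
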