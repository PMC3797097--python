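"""Sequence-logo statistics for domain alignments.

Per-column information content follows the Schneider–Stephens measure used
by WebLogo: R_i = log2(20) − (H_i + e_n), with H_i the Shannon entropy of
the column's residue frequencies and e_n = 19 / (2 ln2 · n) the
small-sample correction for n observed (non-gap) residues. Residue letter
heights are f(a, i) · R_i. Conserved-position calls use a bit threshold on
the top residue's height (the figures' convention is ≥ 2 bits) and a fixed
residue-class colouring: basic K/R/H, acidic D/E, amide N/Q, polar
S/T/C/G/Y, hydrophobic A/V/L/I/P/W/F/M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .msa import MultipleAlignment
from .seqio_align import AMINO_ACIDS

MAX_BITS = math.log2(20)

RESIDUE_CLASSES = {
    "basic": set("KRH"),
    "acidic": set("DE"),
    "amide": set("NQ"),
    "polar": set("STCGY"),
    "hydrophobic": set("AVLIPWFM"),
}


def residue_class(residue: str) -> str:
    for name, members in RESIDUE_CLASSES.items():
        if residue in members:
            return name
    return "other"


@dataclass(frozen=True)
class ConservedPosition:
    column: int          # 1-based logo position
    residue: str
    residue_class: str
    bits: float          # height of the top residue


class LogoMatrix:
    """Column frequencies, information content and residue heights."""

    def __init__(self, frequencies: np.ndarray, n_effective: np.ndarray,
                 small_sample_correction: bool = True):
        if frequencies.ndim != 2 or frequencies.shape[1] != 20:
            raise ValueError("frequency matrix must be columns x 20")
        self.frequencies = frequencies
        self.n_effective = np.asarray(n_effective, dtype=float)
        self.small_sample_correction = small_sample_correction

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    @property
    def information(self) -> np.ndarray:
        return np.array([
            information_content(self.frequencies[i], self.n_effective[i],
                                self.small_sample_correction)
            if self.n_effective[i] > 0 else 0.0
            for i in range(self.n_columns)
        ])

    @property
    def heights(self) -> np.ndarray:
        """Columns × 20 matrix of residue letter heights, summing to R_i."""
        return self.frequencies * self.information[:, None]

    def top_residue(self, column: int) -> tuple[str, float]:
        """(residue, height) of the tallest letter in a 0-based column."""
        heights = self.heights[column]
        idx = int(heights.argmax())
        return AMINO_ACIDS[idx], float(heights[idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        info = self.information
        for col in range(self.n_columns):
            for idx, residue in enumerate(AMINO_ACIDS):
                h = self.heights[col, idx]
                if h > 0:
                    rows.append((col + 1, residue, h, info[col]))
        return pd.DataFrame(rows, columns=["position", "residue", "height", "information"])


def column_frequencies(
    msa: MultipleAlignment, gap_policy: str = "ignore_gaps"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue frequencies and effective counts.

    ``ignore_gaps`` normalises over non-gap residues only; with
    ``count_as_missing`` gaps still carry no residue mass but the effective
    count stays at the row count, deflating the information content of
    ragged columns. All-gap columns get zero frequencies and n = 0.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    if gap_policy not in ("ignore_gaps", "count_as_missing"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    n_cols = msa.n_columns
    counts = np.zeros((n_cols, 20))
    non_gap = np.zeros(n_cols)
    for rec_id in msa.ids:
        for col, letter in enumerate(msa.rows[rec_id]):
            if letter == "-":
                continue
            non_gap[col] += 1
            if letter in index:
                counts[col, index[letter]] += 1
    freqs = np.zeros_like(counts)
    present = non_gap > 0
    freqs[present] = counts[present] / counts[present].sum(axis=1, keepdims=True)
    n_eff = non_gap if gap_policy == "ignore_gaps" else np.full(n_cols, float(msa.n_rows))
    n_eff = np.where(present, n_eff, 0.0)
    return freqs, n_eff


def information_content(
    frequencies: np.ndarray, n: float, small_sample_correction: bool = True
) -> float:
    """R_i in bits, clamped to [0, log2 20]."""
    if n < 1:
        raise ValueError("need at least one observed residue")
    f = np.asarray(frequencies, dtype=float)
    nz = f[f > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    correction = 19.0 / (2.0 * math.log(2.0) * n) if small_sample_correction else 0.0
    return float(min(max(MAX_BITS - (entropy + correction), 0.0), MAX_BITS))


def logo_from_msa(
    msa: MultipleAlignment, gap_policy: str = "ignore_gaps",
    small_sample_correction: bool = True,
) -> LogoMatrix:
    freqs, n_eff = column_frequencies(msa, gap_policy)
    return LogoMatrix(freqs, n_eff, small_sample_correction)


def conserved_positions(
    logo: LogoMatrix, min_bits: float = 2.0,
    classes_of_interest: set[str] | None = None,
) -> list[ConservedPosition]:
    """Positions whose top residue's height reaches ``min_bits``.

    Restrict to ``classes_of_interest`` (e.g. {"basic", "acidic"}) to
    reproduce the charged-residue structure-mapping selection.
    """
    calls: list[ConservedPosition] = []
    for col in range(logo.n_columns):
        if logo.n_effective[col] == 0:
            continue
        residue, height = logo.top_residue(col)
        if height < min_bits:
            continue
        klass = residue_class(residue)
        if classes_of_interest is not None and klass not in classes_of_interest:
            continue
        calls.append(ConservedPosition(col + 1, residue, klass, height))
    return calls


def compare_logos(logo_a: LogoMatrix, logo_b: LogoMatrix) -> tuple[np.ndarray, float]:
    """Per-column Jensen–Shannon divergence in bits plus the mean.

    Columns must already be matched (same count); the measure is symmetric
    and zero iff the column distributions agree.
    """
    if logo_a.n_columns != logo_b.n_columns:
        raise ValueError("logo column counts differ")
    profile = np.empty(logo_a.n_columns)
    for col in range(logo_a.n_columns):
        fa, fb = logo_a.frequencies[col], logo_b.frequencies[col]
        if fa.sum() == 0 or fb.sum() == 0:
            profile[col] = 0.0
            continue
        profile[col] = jensenshannon(fa, fb, base=2) ** 2
    return profile, float(profile.mean())


def render_logo(logo: LogoMatrix, path) -> pd.DataFrame:
    """Write the machine-readable logo TSV and a stacked-letter image.

    ``path`` is the TSV destination; a PNG with the same stem is drawn
    alongside when the path is a filesystem path. Returns the TSV frame.
    """
    if logo.n_columns == 0:
        raise ValueError("cannot render an empty logo")
    frame = logo.to_frame()
    frame.to_csv(path, sep="\t", index=False)
    if not hasattr(path, "write"):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = {"basic": "tab:blue", "acidic": "tab:red", "amide": "tab:pink",
                  "polar": "tab:green", "hydrophobic": "black", "other": "grey"}
        fig, ax = plt.subplots(figsize=(max(4, logo.n_columns * 0.3), 3))
        for col in range(logo.n_columns):
            heights = logo.heights[col]
            order = np.argsort(heights)
            base = 0.0
            for idx in order:
                h = heights[idx]
                if h <= 0:
                    continue
                residue = AMINO_ACIDS[idx]
                ax.text(col + 1, base + h / 2, residue,
                        ha="center", va="center", fontsize=9,
                        color=colors[residue_class(residue)],
                        fontweight="bold")
                base += h
        ax.set_xlim(0.5, logo.n_columns + 0.5)
        ax.set_ylim(0, MAX_BITS)
        ax.set_xlabel("position")
        ax.set_ylabel("bits")
        fig.tight_layout()
        fig.savefig(str(path).rsplit(".", 1)[0] + ".png", dpi=100)
        plt.close(fig)
    return frame
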