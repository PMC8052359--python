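"""Sequence-context analysis of edited adenines.

Nine-nucleotide transcript-orientation windows centered on the edited A
are stratified by editing efficiency and summarised as position
frequency matrices with per-column information content (2 - Shannon
entropy, bits) — the quantities a sequence logo draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from beredit.edit_calling import CallSet
from beredit.synthetic_data import BASES, Transcriptome

BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ContextIntegrityError(ValueError):
    """Center of an extracted window is not A — an upstream strand bug."""


@dataclass(frozen=True)
class ContextWindow:
    chrom: str
    pos: int
    window: str  # length 2*flank+1, transcript orientation, center A
    efficiency: float


@dataclass
class MotifMatrix:
    """Position frequency matrix (rows A,C,G,T) and information content."""

    pfm: np.ndarray        # (4, width) column-stochastic when n > 0
    ic: np.ndarray         # (width,) bits in [0, 2]
    n_sequences: int

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def consensus(self) -> str:
        if self.n_sequences == 0:
            return ""
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))

    def to_frame(self) -> pd.DataFrame:
        w = self.width
        offsets = np.arange(w) - w // 2
        df = pd.DataFrame(self.pfm.T, columns=list(BASES))
        df.insert(0, "offset", offsets)
        df["ic_bits"] = self.ic
        return df

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# n_sequences={self.n_sequences}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def extract_contexts(
    calls: CallSet,
    tx: Transcriptome,
    flank: int = 4,
) -> tuple[list[ContextWindow], int]:
    """Transcript-orientation windows of 2*flank+1 nt around each call.

    Minus-strand genes are read through the stored transcript sequence,
    i.e. already reverse-complemented.  Calls closer than ``flank`` to a
    transcript end are dropped; the drop count is returned alongside.
    """
    out: list[ContextWindow] = []
    dropped = 0
    for c in calls:
        rec = tx[c.transcript_id]
        tpos = rec.transcript_pos(c.pos)
        if tpos <= flank or tpos + flank > len(rec.sequence):
            dropped += 1
            continue
        win = rec.sequence[tpos - 1 - flank: tpos + flank]
        if win[flank] != "A":
            raise ContextIntegrityError(
                f"{c.chrom}:{c.pos} ({rec.id} {rec.strand}): center base "
                f"{win[flank]!r}, expected A"
            )
        out.append(ContextWindow(
            chrom=c.chrom, pos=c.pos, window=win, efficiency=c.efficiency,
        ))
    return out, dropped


def build_motif(
    contexts: Sequence[ContextWindow],
    efficiency_threshold: float | None = None,
) -> MotifMatrix:
    """PFM + information content for contexts edited strictly above threshold.

    Non-ACGT characters are excluded per column with renormalisation.
    IC_j = 2 - H_j bits, no small-sample correction.  An empty stratum
    yields an all-zero matrix with n_sequences = 0.
    """
    if efficiency_threshold is not None:
        contexts = [c for c in contexts
                    if c.efficiency > efficiency_threshold]
    if not contexts:
        width = 9
        return MotifMatrix(np.zeros((4, width)), np.zeros(width), 0)
    width = len(contexts[0].window)
    if any(len(c.window) != width for c in contexts):
        raise ValueError("context windows have inconsistent widths")

    counts = np.zeros((4, width))
    for c in contexts:
        for j, b in enumerate(c.window):
            i = BASE_INDEX.get(b)
            if i is not None:
                counts[i, j] += 1
    col = counts.sum(axis=0)
    pfm = np.divide(counts, col, out=np.zeros_like(counts), where=col > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    entropy = -plogp.sum(axis=0)
    ic = np.where(col > 0, 2.0 - entropy, 0.0)
    return MotifMatrix(pfm=pfm, ic=np.clip(ic, 0.0, 2.0),
                       n_sequences=len(contexts))


def motif_similarity(m1: MotifMatrix, m2: MotifMatrix) -> np.ndarray:
    """Per-position total variation distance between two PFMs.

    Symmetric, zero iff the matrices agree column-wise; ranges in [0, 1].
    """
    if m1.width != m2.width:
        raise ValueError(f"width mismatch: {m1.width} != {m2.width}")
    return 0.5 * np.abs(m1.pfm - m2.pfm).sum(axis=0)


def plot_logo(matrix: MotifMatrix, path: str | Path,
              title: str = "") -> None:
    """Render an IC-scaled letter logo (matplotlib; no pseudocounts)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(0.6 * matrix.width + 1, 2.5))
    offsets = np.arange(matrix.width) - matrix.width // 2
    for j in range(matrix.width):
        heights = matrix.pfm[:, j] * matrix.ic[j]
        order = np.argsort(heights)
        y = 0.0
        for i in order:
            h = heights[i]
            if h <= 0:
                continue
            ax.text(offsets[j], y + h / 2, BASES[i],
                    ha="center", va="center", fontsize=6 + 14 * h / 2,
                    color=colors[BASES[i]], family="monospace")
            y += h
    ax.set_xlim(offsets[0] - 0.6, offsets[-1] + 0.6)
    ax.set_ylim(0, 2.05)
    ax.set_ylabel("bits")
    ax.set_xlabel("offset from edited A")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
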