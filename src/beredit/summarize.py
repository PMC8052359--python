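"""Summary surfaces over call sets: counts, efficiency distributions,
Manhattan tables and cross-editor comparisons."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beredit.edit_calling import CallSet

STRATA = (0.2, 0.4)  # strict >, matching the motif stratification


@dataclass
class SummaryTable:
    sample_id: str
    n_edits: int
    mean_frequency: float
    histogram: np.ndarray  # 10 bins of width 0.1 over [0, 1]; 1.0 in the last
    strata_counts: dict[float, int]

    def to_frame(self) -> pd.DataFrame:
        row = {
            "sample_id": self.sample_id,
            "n_edits": self.n_edits,
            "mean_frequency": self.mean_frequency,
        }
        for t in sorted(self.strata_counts):
            row[f"n_gt_{int(t * 100)}pct"] = self.strata_counts[t]
        return pd.DataFrame([row])

    def histogram_frame(self) -> pd.DataFrame:
        edges = np.linspace(0, 1, 11)
        return pd.DataFrame({
            "bin_low": edges[:-1], "bin_high": edges[1:],
            "count": self.histogram.astype(int),
        })


def summarize_callset(calls: CallSet, sample_id: str | None = None) -> SummaryTable:
    """Edit count, mean efficiency, 10%-wide histogram and >20%/>40% strata."""
    eff = calls.efficiencies()
    n = len(calls)
    hist, _ = np.histogram(eff, bins=np.linspace(0, 1, 11))
    return SummaryTable(
        sample_id=sample_id if sample_id is not None else calls.sample_id,
        n_edits=n,
        mean_frequency=float(eff.mean()) if n else 0.0,
        histogram=hist,
        strata_counts={t: int((eff > t).sum()) for t in STRATA},
    )


def natural_chrom_order(chroms: Sequence[str]) -> list[str]:
    def key(c: str):
        parts = re.split(r"(\d+)", c)
        return [int(p) if p.isdigit() else p for p in parts]

    return sorted(set(chroms), key=key)


def manhattan_table(
    calls: CallSet,
    chrom_lengths: Mapping[str, int],
    chrom_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-edit cumulative genomic coordinate and efficiency.

    Cumulative coordinate = sum of preceding chromosome lengths + position;
    output sorted by cumulative coordinate.  Calls on chromosomes missing
    from ``chrom_lengths`` raise.
    """
    order = list(chrom_order) if chrom_order is not None else (
        natural_chrom_order(list(chrom_lengths)))
    offsets: dict[str, int] = {}
    cum = 0
    for c in order:
        offsets[c] = cum
        cum += int(chrom_lengths[c])
    rows = []
    for call in calls:
        if call.chrom not in offsets:
            raise KeyError(f"chromosome {call.chrom!r} not in chrom_lengths")
        rows.append({
            "chrom": call.chrom, "pos": call.pos,
            "cumulative_pos": offsets[call.chrom] + call.pos,
            "efficiency": call.efficiency,
        })
    df = pd.DataFrame(rows, columns=["chrom", "pos", "cumulative_pos",
                                     "efficiency"])
    return df.sort_values("cumulative_pos").reset_index(drop=True)


def compare_variants(
    tables: Mapping[str, SummaryTable],
    reference: str,
) -> pd.DataFrame:
    """Cross-editor comparison with edit-count ratios to a reference editor."""
    if len(tables) < 2:
        raise ValueError("need summaries for at least two editors")
    if reference not in tables:
        raise ValueError(f"reference editor {reference!r} not among "
                         f"{sorted(tables)}")
    ref_n = tables[reference].n_edits
    rows = []
    for label, t in tables.items():
        row = {
            "editor": label,
            "n_edits": t.n_edits,
            "mean_frequency": t.mean_frequency,
            "ratio_to_reference": (t.n_edits / ref_n) if ref_n else float("nan"),
        }
        for thr in sorted(t.strata_counts):
            row[f"n_gt_{int(thr * 100)}pct"] = t.strata_counts[thr]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_manhattan(df: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=False)):
        ax.scatter(sub["cumulative_pos"], sub["efficiency"], s=4,
                   color=f"C{i % 2}", label=None)
    ax.set_xlabel("cumulative genomic position")
    ax.set_ylabel("editing efficiency")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
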