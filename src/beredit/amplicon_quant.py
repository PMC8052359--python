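"""On-target amplicon quantification: global alignment, per-position
conversion rates, indel frequency, window summaries and fold changes.

Protospacer positions use PAM-distal numbering: position 1 is the most
PAM-distal nucleotide, regardless of protospacer strand on the amplicon.
Indel frequency = indel-containing reads / total mapped reads, with an
indel counted only when it places inserted or deleted bases inside the
protospacer interval.  Substitution rates come from reads without
protospacer indels, whose alignment columns are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from beredit.synthetic_data import COMPLEMENT, BASES


class NoMappedReadsError(RuntimeError):
    """Every read fell below the mapping-score threshold."""


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap: float = -5.0  # linear


@dataclass(frozen=True)
class AmpliconTarget:
    """Amplicon reference with a 20-nt protospacer interval.

    ``proto_start``/``proto_end`` are 1-based inclusive amplicon
    coordinates; ``strand`` says whether the protospacer reads sense (+)
    or antisense (-) on the amplicon.  PAM-distal numbering maps
    position 1 to ``proto_start`` on plus, ``proto_end`` on minus.
    """

    name: str
    sequence: str
    proto_start: int
    proto_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.proto_end - self.proto_start + 1 != 20:
            raise ValueError("protospacer must be exactly 20 nt")
        if not (1 <= self.proto_start and self.proto_end <= len(self.sequence)):
            raise ValueError("protospacer interval outside amplicon")

    def amplicon_index(self, p: int) -> int:
        """0-based amplicon index of protospacer position p (1..20)."""
        if not 1 <= p <= 20:
            raise ValueError("protospacer position must be in 1..20")
        if self.strand == "+":
            return self.proto_start - 1 + (p - 1)
        return self.proto_end - 1 - (p - 1)

    def protospacer_base(self, p: int) -> str:
        """Protospacer-orientation base at position p."""
        b = self.sequence[self.amplicon_index(p)]
        return b if self.strand == "+" else b.translate(COMPLEMENT)

    def protospacer(self) -> str:
        return "".join(self.protospacer_base(p) for p in range(1, 21))


@dataclass
class ReadAlignment:
    """Global alignment as (op, length) runs; op in M (match/mismatch),
    I (read insertion), D (read deletion relative to the reference)."""

    read_id: str
    ops: list[tuple[str, int]]
    score: float

    def consumed(self) -> tuple[int, int]:
        """(read length, reference length) implied by the op string."""
        r = sum(n for op, n in self.ops if op in "MI")
        f = sum(n for op, n in self.ops if op in "MD")
        return r, f

    def ref_columns(self, read: str) -> dict[int, str]:
        """Read base aligned to each 1-based reference position (D -> '-')."""
        out: dict[int, str] = {}
        ri = fi = 0
        for op, n in self.ops:
            if op == "M":
                for k in range(n):
                    out[fi + k + 1] = read[ri + k]
                ri += n
                fi += n
            elif op == "I":
                ri += n
            else:
                for k in range(n):
                    out[fi + k + 1] = "-"
                fi += n
        return out

    def indel_positions(self) -> tuple[list[int], list[int]]:
        """(deleted 1-based ref positions, insertion anchor ref positions).

        An insertion between reference positions k and k+1 is anchored
        at k (0 for an insertion before the first base).
        """
        dels: list[int] = []
        ins: list[int] = []
        fi = 0
        for op, n in self.ops:
            if op == "M":
                fi += n
            elif op == "D":
                dels.extend(range(fi + 1, fi + n + 1))
                fi += n
            else:
                ins.append(fi)
        return dels, ins


def align_global(read: str, ref: str, scoring: Scoring = Scoring(),
                 read_id: str = "") -> ReadAlignment:
    """Needleman–Wunsch global alignment with linear gap penalty.

    Tie-break on equal score during traceback prefers match/mismatch
    over deletion (gap in the read) over insertion (gap in the
    reference), which places gaps as close to the sequence starts as
    possible.
    """
    if not read or not ref:
        raise ValueError("sequences must be non-empty")
    n, m = len(read), len(ref)
    g = scoring.gap
    r_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    f_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    sub = np.where(r_arr[:, None] == f_arr[None, :],
                   scoring.match, scoring.mismatch)

    H = np.empty((n + 1, m + 1))
    H[0, :] = g * np.arange(m + 1)
    H[:, 0] = g * np.arange(n + 1)
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        # resolve the in-row (deletion) dependency with a running max of
        # A[j] - g*j, where A[j] = best score entering column j from above
        A = np.empty(m + 1)
        A[0] = H[i, 0]
        A[1:] = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + g)
        B = A - g * j_idx
        np.maximum.accumulate(B, out=B)
        H[i] = B + g * j_idx

    ops_rev: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            ops_rev.append("M")
            i -= 1
            j -= 1
        elif j > 0 and h == H[i, j - 1] + g:
            ops_rev.append("D")
            j -= 1
        else:
            ops_rev.append("I")
            i -= 1

    runs: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return ReadAlignment(read_id=read_id, ops=runs, score=float(H[n, m]))


@dataclass
class WindowSpec:
    """Inclusive protospacer position window."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= 20:
            raise ValueError("window must satisfy 1 <= start <= end <= 20")

    def positions(self) -> range:
        return range(self.start, self.end + 1)


REPORT_WINDOW = WindowSpec(4, 8)
HEATMAP_WINDOW = WindowSpec(2, 9)


@dataclass
class PositionEditTable:
    """Per-protospacer-position conversion counts and rates.

    ``table`` is indexed by protospacer position 1..20 (PAM-distal
    numbering) with the protospacer-orientation reference base and
    counts/rates for A->G and the A->C / A->T byproducts.  Rates use the
    indel-free mapped read count as denominator; ``indel_frequency``
    uses all mapped reads.
    """

    table: pd.DataFrame
    n_reads_total: int
    n_reads_indel: int
    n_reads_substitution: int

    @property
    def indel_frequency(self) -> float:
        return self.n_reads_indel / self.n_reads_total

    def rate(self, position: int, kind: str = "a_to_g") -> float:
        return float(self.table.loc[position, kind])

    def a_to_nong_mean(self) -> float:
        a_rows = self.table[self.table["ref"] == "A"]
        return float(a_rows["a_to_nong"].mean()) if len(a_rows) else 0.0

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(
                f"# n_reads_total={self.n_reads_total}\t"
                f"n_reads_indel={self.n_reads_indel}\t"
                f"indel_frequency={self.indel_frequency:.6g}\n"
            )
            self.table.to_csv(fh, sep="\t", index=True, index_label="position")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def quantify_amplicon(
    reads: Sequence[tuple[str, str]] | str | Path,
    target: AmpliconTarget,
    scoring: Scoring = Scoring(),
    min_score_fraction: float = 0.6,
) -> PositionEditTable:
    """Align reads to the amplicon and tabulate protospacer editing.

    A read maps when its global alignment scores at least
    ``min_score_fraction`` of its self-alignment score (length x match).
    Reads identical to the reference skip the dynamic program.

    Minus-strand protospacers are quantified in protospacer orientation
    (reads and reference reverse-complemented), so gap tie-breaking and
    PAM-distal numbering are orientation-invariant and a minus-strand
    target on reverse-complemented reads reproduces the plus-strand
    result exactly.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    if target.strand == "-":
        from beredit.synthetic_data import revcomp

        L = len(target.sequence)
        canonical = AmpliconTarget(
            name=target.name, sequence=revcomp(target.sequence),
            proto_start=L - target.proto_end + 1,
            proto_end=L - target.proto_start + 1, strand="+",
        )
        rc_reads = [(rid, revcomp(seq)) for rid, seq in reads]
        return quantify_amplicon(rc_reads, canonical, scoring,
                                 min_score_fraction)
    ps, pe = target.proto_start, target.proto_end
    ref = target.sequence

    n_mapped = 0
    n_indel = 0
    sub_reads = 0
    conv = {p: {"a_to_g": 0, "a_to_c": 0, "a_to_t": 0, "other": 0}
            for p in range(1, 21)}

    for rid, seq in reads:
        if seq == ref:
            n_mapped += 1
            sub_reads += 1
            continue
        aln = align_global(seq, ref, scoring, read_id=rid)
        if aln.score < min_score_fraction * scoring.match * len(seq):
            continue
        n_mapped += 1
        dels, ins_anchors = aln.indel_positions()
        has_proto_indel = any(ps <= d <= pe for d in dels) or any(
            ps <= a < pe for a in ins_anchors)
        if has_proto_indel:
            n_indel += 1
            continue
        sub_reads += 1
        cols = aln.ref_columns(seq)
        for p in range(1, 21):
            fi = target.amplicon_index(p) + 1
            b = cols.get(fi, "-")
            if b == "-":
                continue
            refb = target.protospacer_base(p)
            readb = b if target.strand == "+" else b.translate(COMPLEMENT)
            if readb == refb:
                continue
            if refb == "A" and readb == "G":
                conv[p]["a_to_g"] += 1
            elif refb == "A" and readb == "C":
                conv[p]["a_to_c"] += 1
            elif refb == "A" and readb == "T":
                conv[p]["a_to_t"] += 1
            else:
                conv[p]["other"] += 1

    if n_mapped == 0:
        raise NoMappedReadsError(
            f"no reads mapped to {target.name} at "
            f"min_score_fraction={min_score_fraction}"
        )

    rows = []
    for p in range(1, 21):
        c = conv[p]
        denom = max(sub_reads, 1)
        rows.append({
            "ref": target.protospacer_base(p),
            "n_a_to_g": c["a_to_g"], "n_a_to_c": c["a_to_c"],
            "n_a_to_t": c["a_to_t"], "n_other": c["other"],
            "a_to_g": c["a_to_g"] / denom,
            "a_to_c": c["a_to_c"] / denom,
            "a_to_t": c["a_to_t"] / denom,
            "a_to_nong": (c["a_to_c"] + c["a_to_t"]) / denom,
            "other": c["other"] / denom,
        })
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, 21, name="position"))
    return PositionEditTable(
        table=table, n_reads_total=n_mapped, n_reads_indel=n_indel,
        n_reads_substitution=sub_reads,
    )


@dataclass
class WindowResult:
    position: int | None
    rate: float
    empty: bool = False


def window_summary(table: PositionEditTable,
                   window: WindowSpec = REPORT_WINDOW) -> WindowResult:
    """Maximum A-to-G rate over reference adenines in the window.

    Ties break toward the smaller (more PAM-distal) position; a window
    without adenines returns a flagged empty result.
    """
    best: WindowResult | None = None
    for p in window.positions():
        if table.table.loc[p, "ref"] != "A":
            continue
        r = float(table.table.loc[p, "a_to_g"])
        if best is None or r > best.rate:
            best = WindowResult(position=p, rate=r)
    if best is None:
        return WindowResult(position=None, rate=float("nan"), empty=True)
    return best


def log2fc_table(
    variant_rates: Mapping[int, float] | pd.Series,
    reference_rates: Mapping[int, float] | pd.Series,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-position log2((variant + pc) / (reference + pc)).

    Zero whenever the variant equals the reference; the pseudocount
    keeps unedited positions finite.
    """
    v = pd.Series(dict(variant_rates) if not isinstance(variant_rates, pd.Series)
                  else variant_rates, dtype=float).sort_index()
    r = pd.Series(dict(reference_rates) if not isinstance(reference_rates, pd.Series)
                  else reference_rates, dtype=float).sort_index()
    if not v.index.equals(r.index):
        raise ValueError("variant and reference positions do not match")
    if (v < 0).any() or (r < 0).any():
        raise ValueError("rates must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((v + pseudocount) / (r + pseudocount))
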