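"""RNA A-to-I edit calling from treated/control pileups, plus call-set algebra.

A site is called when, inside an annotated transcript whose
transcript-orientation reference base is A, the treated sample shows
sufficient depth and A-to-G (transcript orientation) evidence while the
control sample is well covered and essentially reference-only (>= 99%
reference reads by default).  ``germline_like`` mode additionally floors
the detectable efficiency at 10%, emulating the behaviour of
germline-oriented callers that miss low-allele-fraction RNA edits;
``somatic_like`` applies no such floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from beredit.synthetic_data import COMPLEMENT, PILEUP_COLUMNS

CALLSET_COLUMNS = [
    "chrom", "pos", "transcript_id", "strand",
    "efficiency", "depth", "alt_reads", "sample_id",
]


class AnnotationMismatchError(ValueError):
    """Pileup chromosomes absent from the annotation."""


class CallSetParseError(ValueError):
    """Malformed external call set (VCF)."""


@dataclass
class FilterParams:
    """Filter thresholds for edit calling.

    ``min_depth`` and ``control_ref_fraction`` follow the published
    pipeline (10x depth; 99% reference reads in the wild-type sample);
    ``min_alt_reads``/``min_alt_fraction`` keep sequencing error from
    flooding the candidate list.  ``germline_min_efficiency`` is the
    emulated detection floor of germline-oriented calling.
    """

    min_depth: int = 10
    control_ref_fraction: float = 0.99
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.01
    mode: str = "somatic_like"
    germline_min_efficiency: float = 0.10

    def validate(self) -> None:
        errs = []
        if self.min_depth < 1:
            errs.append("min_depth must be >= 1")
        for name in ("control_ref_fraction", "min_alt_fraction",
                     "germline_min_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1]")
        if self.min_alt_reads < 0:
            errs.append("min_alt_reads must be >= 0")
        if self.mode not in ("somatic_like", "germline_like"):
            errs.append("mode must be somatic_like or germline_like")
        if errs:
            raise ValueError("; ".join(errs))


@dataclass(frozen=True)
class EditCall:
    chrom: str
    pos: int
    transcript_id: str
    strand: str
    efficiency: float
    depth: int
    alt_reads: int
    sample_id: str = ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class CallSet:
    """Edits for one sample, keyed by (chrom, pos)."""

    sample_id: str = ""
    editor_label: str = ""
    calls: dict[tuple[str, int], EditCall] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls.values())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.calls

    def add(self, call: EditCall) -> None:
        self.calls[call.key] = call

    def efficiencies(self) -> np.ndarray:
        return np.array([c.efficiency for c in self], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(c) for c in self]
        df = pd.DataFrame(rows, columns=CALLSET_COLUMNS)
        return df.sort_values(["chrom", "pos"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "",
                   editor_label: str = "") -> "CallSet":
        cs = cls(sample_id=sample_id, editor_label=editor_label)
        for r in df.itertuples():
            cs.add(EditCall(
                chrom=str(r.chrom), pos=int(r.pos),
                transcript_id=str(r.transcript_id), strand=str(r.strand),
                efficiency=float(r.efficiency), depth=int(r.depth),
                alt_reads=int(r.alt_reads),
                sample_id=str(getattr(r, "sample_id", sample_id)),
            ))
        return cs

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, sample_id: str = "",
                 editor_label: str = "") -> "CallSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(df, sample_id=sample_id, editor_label=editor_label)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 into the internal 1-based inclusive annotation frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end", "transcript_id", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "start": df["start0"].astype(int) + 1,
        "end": df["end"].astype(int),
        "strand": df["strand"].astype(str),
        "transcript_id": df["transcript_id"].astype(str),
    })


def _annotate(df: pd.DataFrame, annotation: pd.DataFrame):
    """Map pileup rows to transcripts; returns (tx_id, strand, in_tx mask).

    Positions covered by transcripts on both strands are treated as
    strand-ambiguous and masked out (the transcribed-strand rule is
    undefined there).
    """
    anno_chroms = set(annotation["chrom"])
    pile_chroms = set(df["chrom"])
    if pile_chroms - anno_chroms:
        raise AnnotationMismatchError(
            f"pileup chromosomes {sorted(pile_chroms - anno_chroms)} "
            "absent from annotation"
        )
    tx_id = np.full(len(df), "", dtype=object)
    strand = np.full(len(df), "", dtype=object)
    ambiguous = np.zeros(len(df), dtype=bool)
    for chrom, sub in annotation.groupby("chrom"):
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = df.loc[sel, "pos"].to_numpy()
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        # detect same-position coverage by a second transcript (overlap on
        # the other strand); with sorted non-overlapping intervals this is
        # impossible, but guard against overlapping annotations
        if (np.diff(starts) <= (ends[:-1] - starts[:-1])).any():
            prev = idx - 1
            over = (prev >= 0) & ok & (pos <= ends[np.clip(prev, 0, None)])
            ambiguous[np.flatnonzero(sel)[over]] = True
        rows = np.flatnonzero(sel)[ok]
        tx_id[rows] = sub["transcript_id"].to_numpy()[idx[ok]]
        strand[rows] = sub["strand"].to_numpy()[idx[ok]]
    in_tx = (tx_id != "") & ~ambiguous
    return tx_id, strand, in_tx


def call_edits(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    annotation: pd.DataFrame,
    params: FilterParams | None = None,
    sample_id: str = "treated",
    editor_label: str = "",
) -> CallSet:
    """Call A-to-I edits from treated vs control pileup tables.

    Both tables use reference-plus-strand base counts; edits in
    minus-strand genes are read as T->C on the plus strand and reported
    in transcript orientation (ref A, alt G).
    """
    params = params or FilterParams()
    params.validate()
    out = CallSet(sample_id=sample_id, editor_label=editor_label)
    if treated.empty:
        return out

    tx_id, strand, in_tx = _annotate(treated, annotation)
    df = treated.loc[in_tx].copy()
    df["transcript_id"] = tx_id[in_tx]
    df["strand"] = strand[in_tx]

    # transcript-orientation reference must be A: plus genes ref A, minus genes ref T
    is_a = ((df["strand"] == "+") & (df["ref"] == "A")) | (
        (df["strand"] == "-") & (df["ref"] == "T"))
    df = df.loc[is_a]
    if df.empty:
        return out

    merged = df.merge(
        control, on=["chrom", "pos"], how="left",
        suffixes=("", "_ctrl"),
    )

    alt = np.where(merged["strand"] == "+", merged["G"], merged["C"])
    depth = merged["depth"].to_numpy()
    eff = np.divide(alt, depth, out=np.zeros_like(alt, dtype=float),
                    where=depth > 0)

    ctrl_depth = merged["depth_ctrl"].fillna(0).to_numpy()
    ref_count = np.zeros(len(merged))
    for b in "ACGT":
        mask = (merged["ref"] == b).to_numpy()
        col = merged[f"{b}_ctrl"].fillna(0).to_numpy()
        ref_count[mask] = col[mask]
    ctrl_ref_frac = np.divide(
        ref_count, ctrl_depth, out=np.zeros_like(ref_count), where=ctrl_depth > 0
    )

    keep = (
        (depth >= params.min_depth)
        & (alt >= params.min_alt_reads)
        & (eff >= params.min_alt_fraction)
        & (ctrl_depth >= params.min_depth)
        & (ctrl_ref_frac >= params.control_ref_fraction)
    )
    if params.mode == "germline_like":
        keep &= eff >= params.germline_min_efficiency

    for i in np.flatnonzero(keep):
        r = merged.iloc[i]
        out.add(EditCall(
            chrom=str(r["chrom"]), pos=int(r["pos"]),
            transcript_id=str(r["transcript_id"]), strand=str(r["strand"]),
            efficiency=float(eff[i]), depth=int(depth[i]),
            alt_reads=int(alt[i]), sample_id=sample_id,
        ))
    return out


def detect_endogenous(
    control: pd.DataFrame,
    annotation: pd.DataFrame,
    params: FilterParams | None = None,
    sample_id: str = "control",
) -> CallSet:
    """Identify endogenous A-to-I sites directly from the control pileup.

    A site qualifies when the control itself shows transcript-orientation
    A-to-G evidence at or above the alt-read/alt-fraction floors — the
    in-silico analogue of profiling the untreated transcriptome.
    """
    params = params or FilterParams()
    out = CallSet(sample_id=sample_id)
    if control.empty:
        return out
    tx_id, strand, in_tx = _annotate(control, annotation)
    df = control.loc[in_tx].copy()
    df["transcript_id"] = tx_id[in_tx]
    df["strand"] = strand[in_tx]
    is_a = ((df["strand"] == "+") & (df["ref"] == "A")) | (
        (df["strand"] == "-") & (df["ref"] == "T"))
    df = df.loc[is_a]
    alt = np.where(df["strand"] == "+", df["G"], df["C"])
    depth = df["depth"].to_numpy()
    eff = np.divide(alt, depth, out=np.zeros_like(alt, dtype=float),
                    where=depth > 0)
    keep = (depth >= params.min_depth) & (alt >= params.min_alt_reads) & (
        eff >= params.min_alt_fraction)
    for row_i in np.flatnonzero(keep):
        r = df.iloc[row_i]
        out.add(EditCall(
            chrom=str(r["chrom"]), pos=int(r["pos"]),
            transcript_id=str(r["transcript_id"]), strand=str(r["strand"]),
            efficiency=float(eff[row_i]), depth=int(depth[row_i]),
            alt_reads=int(alt[row_i]), sample_id=sample_id,
        ))
    return out


def subtract_endogenous(calls: CallSet, endogenous: CallSet) -> CallSet:
    """Drop calls whose (chrom, pos) also appears in the endogenous set."""
    out = CallSet(sample_id=calls.sample_id, editor_label=calls.editor_label)
    for c in calls:
        if c.key not in endogenous:
            out.add(c)
    return out


def overlap_callsets(
    a: CallSet, b: CallSet
) -> tuple[CallSet, CallSet, CallSet, CallSet]:
    """Split two call sets into (overlapped, a-specific, b-specific, merged).

    Keyed on (chrom, pos); overlapped calls carry a's records, merged
    holds a's records plus b-specific ones, so
    ``len(merged) == len(a) + len(b) - len(overlapped)``.
    """
    overlapped = CallSet(sample_id=a.sample_id, editor_label=a.editor_label)
    a_spec = CallSet(sample_id=a.sample_id, editor_label=a.editor_label)
    b_spec = CallSet(sample_id=b.sample_id, editor_label=b.editor_label)
    merged = CallSet(sample_id=a.sample_id, editor_label=a.editor_label)
    for c in a:
        (overlapped if c.key in b else a_spec).add(c)
        merged.add(c)
    for c in b:
        if c.key not in a:
            b_spec.add(c)
            merged.add(c)
    return overlapped, a_spec, b_spec, merged


def read_callset_vcf(
    path: str | Path,
    annotation: pd.DataFrame,
    sample_id: str = "",
    editor_label: str = "",
) -> CallSet:
    """Ingest an external single-sample VCF as a CallSet.

    Keeps SNV records that read A>G in plus-strand genes or T>C in
    minus-strand genes (both are transcript-orientation A-to-G);
    everything else, and records outside the annotation, is dropped.
    Efficiency is taken from FORMAT/AF, then INFO/AF, then FORMAT/AD.
    """
    import pysam

    out = CallSet(sample_id=sample_id, editor_label=editor_label)
    anno = annotation.sort_values(["chrom", "start"])
    by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(),
            g["strand"].to_numpy(), g["transcript_id"].to_numpy())
        for c, g in anno.groupby("chrom")
    }

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise CallSetParseError(f"{path}: cannot parse VCF header: {e}") from e

    with vcf:
        it = vcf.fetch() if vcf.index is not None else iter(vcf)
        for i, rec in enumerate(_wrap_records(it, path), start=1):
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if ref is None or len(ref) != 1 or len(alt) != 1:
                continue
            chrom, pos = str(rec.chrom), int(rec.pos)
            if chrom not in by_chrom:
                continue
            starts, ends, strands, tids = by_chrom[chrom]
            j = int(np.searchsorted(starts, pos, side="right")) - 1
            if j < 0 or pos > ends[j]:
                continue
            strand, tid = str(strands[j]), str(tids[j])
            if (strand, ref, alt) not in (("+", "A", "G"), ("-", "T", "C")):
                continue
            eff, depth, alt_reads = _vcf_efficiency(rec)
            out.add(EditCall(
                chrom=chrom, pos=pos, transcript_id=tid, strand=strand,
                efficiency=eff, depth=depth, alt_reads=alt_reads,
                sample_id=sample_id,
            ))
    return out


def _wrap_records(it, path):
    i = 0
    while True:
        i += 1
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as e:
            raise CallSetParseError(f"{path}: record {i}: {e}") from e


def _vcf_efficiency(rec) -> tuple[float, int, int]:
    eff, depth, alt_reads = float("nan"), 0, 0
    samples = list(rec.samples.values()) if rec.samples else []
    if samples:
        s = samples[0]
        ad = s.get("AD")
        if ad is not None and len(ad) >= 2 and ad[0] is not None:
            depth = int(sum(x for x in ad if x is not None))
            alt_reads = int(ad[1] or 0)
            if depth > 0:
                eff = alt_reads / depth
        af = s.get("AF")
        if af is not None:
            eff = float(af[0] if isinstance(af, tuple) else af)
    if np.isnan(eff) and "AF" in rec.info:
        v = rec.info["AF"]
        eff = float(v[0] if isinstance(v, tuple) else v)
    if np.isnan(eff):
        eff = 1.0  # presence-only record
    return eff, depth, alt_reads


@dataclass
class FoldResult:
    fold: float
    n_somatic: int
    n_germline: int
    flagged: bool = False


def sensitivity_fold(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    annotation: pd.DataFrame,
    params: FilterParams | None = None,
) -> FoldResult:
    """Ratio of somatic_like to germline_like call counts on the same input.

    Germline-like calls are a subset of somatic-like calls by
    construction, so the fold is >= 1; a zero germline denominator is
    returned flagged rather than raised.
    """
    params = params or FilterParams()
    som = call_edits(treated, control, annotation,
                     dataclasses.replace(params, mode="somatic_like"))
    germ = call_edits(treated, control, annotation,
                      dataclasses.replace(params, mode="germline_like"))
    if len(germ) == 0:
        return FoldResult(float("nan"), len(som), 0, flagged=True)
    return FoldResult(len(som) / len(germ), len(som), len(germ))
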