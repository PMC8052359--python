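"""Ground-truth synthetic data: toy transcriptomes, pileups and amplicon reads.

The generator emulates the statistical structure of base-editor RNA
off-target experiments: a transcriptome in which a minority of adenines
sit in the TadA-preferred ``UACGA`` context (DNA ``TACGA``, edited A
last) and are edited at high efficiency, a large background of
low-efficiency edits, endogenous A-to-I sites shared with the control
sample, negative-binomial sequencing depth and a small residual
substitution error.  Amplicon reads carry planted per-position A-to-G
conversion, A-to-nonG byproduct and protospacer indel rates.

All randomness flows through a single seed; fixed seed means
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = ("A", "C", "G", "T")
MOTIF_5P = "TACG"  # 5' context planted before the edited A (DNA strand)

PILEUP_COLUMNS = ["chrom", "pos", "ref", "depth", "A", "C", "G", "T"]
TRUTH_COLUMNS = [
    "chrom", "pos", "transcript_id", "strand",
    "true_efficiency", "motif_site", "endogenous",
]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One intron-less transcript: a stranded genomic interval plus its
    transcript-orientation sequence (1-based inclusive coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start + 1}"
            )

    def genomic_pos(self, tpos: int) -> int:
        """Genomic coordinate of 1-based transcript position ``tpos``."""
        if self.strand == "+":
            return self.start + tpos - 1
        return self.end - tpos + 1

    def transcript_pos(self, gpos: int) -> int:
        """1-based transcript position of genomic coordinate ``gpos``."""
        if not self.start <= gpos <= self.end:
            raise ValueError(f"{gpos} outside {self.id} [{self.start},{self.end}]")
        if self.strand == "+":
            return gpos - self.start + 1
        return self.end - gpos + 1


@dataclass
class Transcriptome:
    transcripts: list[TranscriptRecord]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        self._by_id = {t.id: t for t in self.transcripts}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> TranscriptRecord:
        return self._by_id[tid]

    def annotation_frame(self) -> pd.DataFrame:
        """Stranded 1-based inclusive interval table (the caller's annotation)."""
        return pd.DataFrame(
            {
                "chrom": [t.chrom for t in self.transcripts],
                "start": [t.start for t in self.transcripts],
                "end": [t.end for t in self.transcripts],
                "strand": [t.strand for t in self.transcripts],
                "transcript_id": [t.id for t in self.transcripts],
            }
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.id} {t.chrom}:{t.start}-{t.end}({t.strand})\n")
                for i in range(0, len(t.sequence), 70):
                    fh.write(t.sequence[i:i + 70] + "\n")

    def write_bed(self, path: str | Path) -> None:
        """BED6: 0-based half-open, transcript id as name, strand in col 6."""
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(
                    f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.id}\t0\t{t.strand}\n"
                )


@dataclass(frozen=True)
class EditTruth:
    """A planted edit: genomic location, transcript context and true efficiency."""

    chrom: str
    pos: int
    transcript_id: str
    strand: str
    true_efficiency: float
    motif_site: bool
    endogenous: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_efficiency <= 1.0:
            raise ValueError("true_efficiency must be in [0, 1]")


@dataclass
class SimParams:
    """Study conditions for the synthetic RNA-seq arm.

    Efficiency mixtures emulate the observed editor signature: motif-context
    adenines (UACGA) edited at high efficiency, a large background of
    low-efficiency edits, and endogenous (ADAR-like) sites at moderate
    efficiency shared with the control.  Depth is negative-binomial
    (RNA-seq overdispersion); ``per_base_error_rate`` is the residual
    substitution error after upstream base/mapping quality filtering.
    """

    n_transcripts: int = 2000
    transcript_length: tuple[int, int] = (200, 600)
    motif_site_count: int = 100
    background_site_count: int = 360
    endogenous_site_count: int = 40
    motif_eff_distribution: tuple[float, float] = (10.0, 2.0)
    background_eff_distribution: tuple[float, float] = (0.2, 60.0)
    endogenous_eff_distribution: tuple[float, float] = (5.0, 8.0)
    mean_depth: float = 50.0
    depth_dispersion: float = 20.0
    per_base_error_rate: float = 1e-4
    n_chroms: int = 5
    intergenic_gap: int = 100
    seed: int = 0

    def validate(self) -> None:
        errs = []
        for name in ("n_transcripts", "motif_site_count",
                     "background_site_count", "endogenous_site_count"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        lo, hi = self.transcript_length
        if not (0 < lo <= hi):
            errs.append("transcript_length must satisfy 0 < min <= max")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            errs.append("per_base_error_rate must be in [0, 1]")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            errs.append("mean_depth and depth_dispersion must be > 0")
        for name in ("motif_eff_distribution", "background_eff_distribution",
                     "endogenous_eff_distribution"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                errs.append(f"{name} Beta parameters must be > 0")
        if errs:
            raise ValueError("; ".join(errs))


def _rng(params_or_seed) -> np.random.Generator:
    if isinstance(params_or_seed, np.random.Generator):
        return params_or_seed
    return np.random.default_rng(params_or_seed)


def simulate_transcriptome(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[Transcriptome, list[EditTruth]]:
    """Generate a toy transcriptome with planted edit sites.

    Motif sites get the 5' DNA context ``TACG`` immediately before the
    edited A (transcript orientation); background and endogenous sites
    are forced to A.  Sites on the same transcript are kept >= 9 nt
    apart so context windows never overlap another planted site.
    """
    params.validate()
    rng = _rng(rng if rng is not None else params.seed)

    lo, hi = params.transcript_length
    n_sites = (params.motif_site_count + params.background_site_count
               + params.endogenous_site_count)
    if params.n_transcripts == 0:
        if n_sites > 0:
            raise ValueError("cannot place edit sites in an empty transcriptome")
        return Transcriptome([]), []
    if lo < 20 and n_sites > 0:
        raise ValueError("transcripts shorter than 20 nt cannot host edit sites")

    lengths = rng.integers(lo, hi + 1, size=params.n_transcripts)
    strands = np.where(rng.random(params.n_transcripts) < 0.5, "+", "-")
    seqs = [
        "".join(rng.choice(list(BASES), size=L)) for L in lengths
    ]

    # lay transcripts head-to-tail on n_chroms chromosomes
    cursors = {f"chr{i + 1}": 0 for i in range(params.n_chroms)}
    records: list[TranscriptRecord] = []
    for i, (L, sd, seq) in enumerate(zip(lengths, strands, seqs)):
        chrom = f"chr{(i % params.n_chroms) + 1}"
        start = cursors[chrom] + params.intergenic_gap + 1
        cursors[chrom] = start + int(L) - 1
        records.append(TranscriptRecord(
            id=f"TX{i:05d}", chrom=chrom, start=start,
            end=start + int(L) - 1, strand=str(sd), sequence=seq,
        ))

    # site placement: (transcript index, transcript position), min spacing 9
    occupied: dict[int, list[int]] = {}

    def place(count: int) -> list[tuple[int, int]]:
        out = []
        attempts = 0
        while len(out) < count:
            attempts += 1
            if attempts > 1000 * max(count, 1):
                raise ValueError(
                    "could not place requested sites; transcripts too "
                    "short or site counts too high"
                )
            ti = int(rng.integers(0, params.n_transcripts))
            L = int(lengths[ti])
            if L < 20:
                continue
            tpos = int(rng.integers(6, L - 4))  # room for 9-nt window + motif
            if any(abs(tpos - p) < 9 for p in occupied.get(ti, ())):
                continue
            occupied.setdefault(ti, []).append(tpos)
            out.append((ti, tpos))
        return out

    motif_sites = place(params.motif_site_count)
    background_sites = place(params.background_site_count)
    endogenous_sites = place(params.endogenous_site_count)

    mutable = [list(s) for s in seqs]
    for ti, tpos in motif_sites:
        mutable[ti][tpos - 5:tpos - 1] = list(MOTIF_5P)
        mutable[ti][tpos - 1] = "A"
    for ti, tpos in background_sites + endogenous_sites:
        mutable[ti][tpos - 1] = "A"

    records = [
        dataclasses.replace(r, sequence="".join(s))
        for r, s in zip(records, mutable)
    ]
    tx = Transcriptome(records)

    def effs(dist: tuple[float, float], n: int) -> np.ndarray:
        a, b = dist
        return rng.beta(a, b, size=n) if n else np.empty(0)

    truth: list[EditTruth] = []
    for (sites, dist, is_motif, is_endo) in (
        (motif_sites, params.motif_eff_distribution, True, False),
        (background_sites, params.background_eff_distribution, False, False),
        (endogenous_sites, params.endogenous_eff_distribution, False, True),
    ):
        es = effs(dist, len(sites))
        for (ti, tpos), e in zip(sites, es):
            r = records[ti]
            truth.append(EditTruth(
                chrom=r.chrom, pos=r.genomic_pos(tpos), transcript_id=r.id,
                strand=r.strand, true_efficiency=float(e),
                motif_site=is_motif, endogenous=is_endo,
            ))
    truth.sort(key=lambda t: (t.chrom, t.pos))
    return tx, truth


def truth_frame(truth: Sequence[EditTruth]) -> pd.DataFrame:
    df = pd.DataFrame(
        [dataclasses.asdict(t) for t in truth], columns=TRUTH_COLUMNS
    )
    return df.astype({"pos": "int64", "true_efficiency": "float64",
                      "motif_site": "bool", "endogenous": "bool"})


def truth_from_frame(df: pd.DataFrame) -> list[EditTruth]:
    return [
        EditTruth(
            chrom=str(r.chrom), pos=int(r.pos),
            transcript_id=str(r.transcript_id), strand=str(r.strand),
            true_efficiency=float(r.true_efficiency),
            motif_site=bool(r.motif_site), endogenous=bool(r.endogenous),
        )
        for r in df.itertuples()
    ]


def _base_codes(seq_arr: np.ndarray) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[seq_arr]


def simulate_pileups(
    tx: Transcriptome,
    truth: Sequence[EditTruth],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate quality-filtered base counts for treated and control samples.

    Reference-plus-strand convention: an edit in a minus-strand gene
    appears as T (ref) -> C (alt).  Endogenous sites are edited in both
    samples at the same efficiency; all other positions in the control,
    and non-site positions in the treated sample, accumulate only
    substitution error (rate/3 to each non-reference base).
    """
    params.validate()
    rng = _rng(rng if rng is not None else params.seed + 1)

    for t in truth:
        rec = tx[t.transcript_id]
        if not rec.start <= t.pos <= rec.end:
            raise ValueError(f"truth site {t.chrom}:{t.pos} outside {rec.id}")

    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    refs: list[np.ndarray] = []
    for rec in tx.transcripts:
        n = rec.end - rec.start + 1
        gpos = np.arange(rec.start, rec.end + 1)
        tseq = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        if rec.strand == "+":
            plus = tseq
        else:
            plus = np.frombuffer(
                rec.sequence.translate(COMPLEMENT).encode(), dtype=np.uint8
            )[::-1]
        chroms.append(np.full(n, rec.chrom, dtype=object))
        poss.append(gpos)
        refs.append(_base_codes(plus))
    if not chroms:
        empty = pd.DataFrame(columns=PILEUP_COLUMNS)
        return empty, empty.copy()

    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    ref = np.concatenate(refs)
    npos = len(pos)

    index = {(c, int(p)): i for i, (c, p) in enumerate(zip(chrom, pos))}

    def sample_counts(edited: Mapping[int, tuple[float, int]]) -> pd.DataFrame:
        """edited maps row index -> (efficiency, alt base code)."""
        r, m = params.depth_dispersion, params.mean_depth
        depth = rng.negative_binomial(r, r / (r + m), size=npos)
        depth = np.maximum(depth, 1)
        counts = np.zeros((npos, 4), dtype=np.int64)

        alt_reads = np.zeros(npos, dtype=np.int64)
        alt_base = np.full(npos, -1, dtype=np.int64)
        if edited:
            idx = np.fromiter(edited.keys(), dtype=np.int64)
            eff = np.array([edited[i][0] for i in idx])
            ab = np.array([edited[i][1] for i in idx])
            alt_reads[idx] = rng.binomial(depth[idx], eff)
            alt_base[idx] = ab

        rest = depth - alt_reads
        nerr = rng.binomial(rest, params.per_base_error_rate)
        # split errors uniformly over the 3 non-reference bases
        e1 = rng.binomial(nerr, 1 / 3)
        e2 = rng.binomial(nerr - e1, 1 / 2)
        e3 = nerr - e1 - e2
        err = np.stack([e1, e2, e3], axis=1)

        rows = np.arange(npos)
        counts[rows, ref] = rest - nerr
        nonref = np.array([[b for b in range(4) if b != r0] for r0 in range(4)])
        tgt = nonref[ref]  # (npos, 3) base codes receiving error
        for k in range(3):
            np.add.at(counts, (rows, tgt[:, k]), err[:, k])
        has_alt = alt_base >= 0
        np.add.at(counts, (rows[has_alt], alt_base[has_alt]), alt_reads[has_alt])

        df = pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": np.array(list(BASES))[ref],
            "depth": depth,
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
        })
        return df

    treated_sites: dict[int, tuple[float, int]] = {}
    control_sites: dict[int, tuple[float, int]] = {}
    for t in truth:
        i = index[(t.chrom, t.pos)]
        alt = 2 if t.strand == "+" else 1  # G on plus genes, C on minus genes
        treated_sites[i] = (t.true_efficiency, alt)
        if t.endogenous:
            control_sites[i] = (t.true_efficiency, alt)

    treated = sample_counts(treated_sites)
    control = sample_counts(control_sites)
    return treated, control


def write_pileup_tsv(df: pd.DataFrame, path: str | Path,
                     header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table {path} missing columns {sorted(missing)}")
    return df


def simulate_amplicon_reads(
    target,
    profile: Mapping[int, float],
    nonG_rate: float = 0.0,
    indel_rate: float = 0.0,
    error_rate: float = 0.0,
    n_reads: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> list[tuple[str, str]]:
    """Simulate amplicon reads with planted editing.

    ``profile`` maps protospacer positions (PAM-distal numbering, 1..20)
    to A-to-G conversion probabilities applied independently per read.
    Unconverted protospacer adenines become C or T with ``nonG_rate``.
    A fraction ``indel_rate`` of reads receives one 1-3 nt insertion or
    deletion at a uniform position inside the protospacer.  Returns
    (read id, sequence) pairs; use :func:`write_fastq` to persist.
    """
    from beredit.amplicon_quant import AmpliconTarget  # circular-import guard

    assert isinstance(target, AmpliconTarget)
    rng = _rng(rng)
    for p, v in profile.items():
        if not 1 <= p <= 20:
            raise ValueError(f"profile position {p} outside protospacer 1..20")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"profile probability {v} outside [0, 1]")
    for name, v in (("nonG_rate", nonG_rate), ("indel_rate", indel_rate),
                    ("error_rate", error_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    ref = target.sequence
    proto_a = [
        p for p in range(1, 21)
        if target.protospacer_base(p) == "A"
    ]
    reads: list[tuple[str, str]] = []
    others = {b: [x for x in BASES if x != b] for b in BASES}
    for i in range(n_reads):
        seq = list(ref)
        for p in proto_a:
            j = target.amplicon_index(p)
            if rng.random() < profile.get(p, 0.0):
                new = "G"
            elif nonG_rate and rng.random() < nonG_rate:
                new = "C" if rng.random() < 0.5 else "T"
            else:
                continue
            # convert in protospacer orientation; complement on minus strand
            seq[j] = new if target.strand == "+" else new.translate(COMPLEMENT)
        if error_rate:
            for j in range(len(seq)):
                if rng.random() < error_rate:
                    seq[j] = others[seq[j]][int(rng.integers(0, 3))]
        if rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            lo = target.proto_start - 1
            hi = target.proto_end  # 0-based half-open protospacer
            if rng.random() < 0.5:  # deletion inside protospacer
                start = int(rng.integers(lo, max(hi - length, lo) + 1))
                del seq[start:start + length]
            else:  # insertion inside protospacer
                at = int(rng.integers(lo + 1, hi))
                ins = "".join(rng.choice(list(BASES), size=length))
                seq[at:at] = list(ins)
        reads.append((f"read{i:06d}", "".join(seq)))
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality: int = 30) -> None:
    """Write reads as Sanger Phred+33 FASTQ with constant quality."""
    q = chr(quality + 33)
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{q * len(seq)}\n")
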