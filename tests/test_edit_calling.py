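"""Edit-caller filters, set algebra, VCF ingestion and mode nesting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from beredit.edit_calling import (
    AnnotationMismatchError, CallSet, EditCall, FilterParams, call_edits,
    detect_endogenous, overlap_callsets, read_bed, read_callset_vcf,
    sensitivity_fold, subtract_endogenous,
)

ANNO = pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr2"],
    "start": [1, 201, 1],
    "end": [100, 300, 150],
    "strand": ["+", "-", "+"],
    "transcript_id": ["TXA", "TXB", "TXC"],
})


def pileup_row(chrom, pos, ref, counts):
    a, c, g, t = counts
    return {"chrom": chrom, "pos": pos, "ref": ref,
            "depth": a + c + g + t, "A": a, "C": c, "G": g, "T": t}


def frame(rows):
    return pd.DataFrame(rows)


def clean_control(sites):
    """Control rows 100% reference at the given (chrom,pos,ref)."""
    rows = []
    for chrom, pos, ref in sites:
        counts = [0, 0, 0, 0]
        counts["ACGT".index(ref)] = 100
        rows.append(pileup_row(chrom, pos, ref, counts))
    return frame(rows)


def test_empty_pileups_empty_callset():
    empty = pd.DataFrame(columns=["chrom", "pos", "ref", "depth",
                                  "A", "C", "G", "T"])
    assert len(call_edits(empty, empty, ANNO)) == 0


def test_min_depth_excludes_nine_reads():
    treated = frame([pileup_row("chr1", 10, "A", (0, 0, 9, 0))])
    control = clean_control([("chr1", 10, "A")])
    assert len(call_edits(treated, control, ANNO)) == 0
    # one more read crosses the 10x floor
    treated = frame([pileup_row("chr1", 10, "A", (0, 0, 10, 0))])
    assert len(call_edits(treated, control, ANNO)) == 1


def test_control_ref_fraction_excludes_dirty_control():
    treated = frame([pileup_row("chr1", 10, "A", (0, 0, 100, 0))])
    dirty = frame([pileup_row("chr1", 10, "A", (98, 0, 2, 0))])  # 98% ref
    assert len(call_edits(treated, dirty, ANNO)) == 0
    clean = frame([pileup_row("chr1", 10, "A", (99, 0, 1, 0))])  # 99% ref
    assert len(call_edits(treated, clean, ANNO)) == 1


def test_only_transcribed_strand_a_to_g_called():
    treated = frame([
        pileup_row("chr1", 10, "A", (50, 0, 50, 0)),   # + gene A->G: called
        pileup_row("chr1", 20, "C", (0, 50, 0, 50)),   # + gene C->T: no
        pileup_row("chr1", 250, "T", (0, 50, 0, 50)),  # - gene T->C: called
        pileup_row("chr1", 260, "A", (50, 0, 50, 0)),  # - gene A->G: no (antisense)
        pileup_row("chr1", 150, "A", (50, 0, 50, 0)),  # intergenic: skipped
    ])
    sites = [(r["chrom"], r["pos"], r["ref"]) for r in treated.to_dict("records")]
    cs = call_edits(treated, clean_control(sites), ANNO)
    assert sorted(cs.calls) == [("chr1", 10), ("chr1", 250)]
    assert cs.calls[("chr1", 250)].strand == "-"
    assert cs.calls[("chr1", 250)].efficiency == 0.5


def test_chrom_mismatch_raises():
    treated = frame([pileup_row("chrX", 10, "A", (0, 0, 50, 0))])
    with pytest.raises(AnnotationMismatchError):
        call_edits(treated, clean_control([("chrX", 10, "A")]), ANNO)


def test_brute_force_refilter_oracle():
    """Caller output equals an independently written row-by-row filter on a
    random 50-site table."""
    rng = np.random.default_rng(42)
    rows_t, rows_c = [], []
    positions = rng.choice(np.arange(1, 101), size=25, replace=False)
    positions = np.concatenate([positions,
                                rng.choice(np.arange(201, 301), 25, False)])
    for pos in positions:
        ref = "A" if pos <= 100 else rng.choice(list("AT"))
        depth = int(rng.integers(5, 60))
        alt = int(rng.integers(0, depth + 1) * (rng.random() < 0.5))
        counts = [0, 0, 0, 0]
        alt_base = "G" if pos <= 100 else "C"
        counts["ACGT".index(ref)] = depth - alt
        counts["ACGT".index(alt_base)] += alt
        rows_t.append(pileup_row("chr1", int(pos), ref, counts))
        cdepth = int(rng.integers(5, 60))
        calt = int(rng.integers(0, 3))
        ccounts = [0, 0, 0, 0]
        ccounts["ACGT".index(ref)] = cdepth - calt
        ccounts["ACGT".index(alt_base)] += calt
        rows_c.append(pileup_row("chr1", int(pos), ref, ccounts))
    treated, control = frame(rows_t), frame(rows_c)
    params = FilterParams()
    got = sorted(call_edits(treated, control, ANNO, params).calls)

    expected = []
    for rt, rc in zip(rows_t, rows_c):
        pos = rt["pos"]
        strand = "+" if pos <= 100 else "-"
        if strand == "+" and rt["ref"] != "A":
            continue
        if strand == "-" and rt["ref"] != "T":
            continue
        alt = rt["G"] if strand == "+" else rt["C"]
        ref_c = rc[rt["ref"]]
        if (rt["depth"] >= 10 and alt >= 3 and alt / rt["depth"] >= 0.01
                and rc["depth"] >= 10
                and ref_c / rc["depth"] >= 0.99):
            expected.append(("chr1", pos))
    assert got == sorted(expected)


@pytest.mark.parametrize("field,values", [
    ("min_depth", [5, 10, 20, 40]),
    ("min_alt_reads", [0, 2, 4, 8]),
    ("min_alt_fraction", [0.0, 0.01, 0.05, 0.2]),
    ("control_ref_fraction", [0.9, 0.95, 0.99, 1.0]),
])
def test_filter_monotonicity(small_run, field, values):
    """Tightening any threshold never increases the number of calls."""
    tx, _, treated, control = small_run
    anno = tx.annotation_frame()
    counts = []
    for v in values:
        params = dataclasses.replace(FilterParams(), **{field: v})
        counts.append(len(call_edits(treated, control, anno, params)))
    assert counts == sorted(counts, reverse=True)


def test_germline_nested_in_somatic(small_run):
    tx, _, treated, control = small_run
    anno = tx.annotation_frame()
    som = call_edits(treated, control, anno,
                     FilterParams(mode="somatic_like"))
    germ = call_edits(treated, control, anno,
                      FilterParams(mode="germline_like"))
    assert set(germ.calls) <= set(som.calls)
    assert all(c.efficiency >= 0.10 for c in germ)


def test_calls_respect_strand_convention(small_run):
    """Calls in minus-strand genes correspond to plus-strand T->C patterns."""
    tx, _, treated, control = small_run
    cs = call_edits(treated, control, tx.annotation_frame())
    assert len(cs) > 0
    tidx = treated.set_index(["chrom", "pos"])
    for c in cs:
        row = tidx.loc[c.key]
        if c.strand == "-":
            assert row["ref"] == "T" and row["C"] == c.alt_reads
        else:
            assert row["ref"] == "A" and row["G"] == c.alt_reads


# --- endogenous subtraction ------------------------------------------------


def _callset(keys, sample="s"):
    cs = CallSet(sample_id=sample)
    for chrom, pos in keys:
        cs.add(EditCall(chrom=chrom, pos=pos, transcript_id="TX",
                        strand="+", efficiency=0.5, depth=50, alt_reads=25,
                        sample_id=sample))
    return cs


def test_subtract_endogenous_identity_and_annihilation():
    calls = _callset([("chr1", 1), ("chr1", 2)])
    assert set(subtract_endogenous(calls, CallSet()).calls) == set(calls.calls)
    assert len(subtract_endogenous(calls, calls)) == 0


def test_planted_endogenous_never_in_final_calls(small_run):
    tx, truth, treated, control = small_run
    anno = tx.annotation_frame()
    final = subtract_endogenous(
        call_edits(treated, control, anno),
        detect_endogenous(control, anno),
    )
    endo_keys = {(t.chrom, t.pos) for t in truth if t.endogenous}
    assert not endo_keys & set(final.calls)


# --- set algebra ------------------------------------------------------------


def test_overlap_identical_and_disjoint():
    a = _callset([("chr1", i) for i in range(1, 11)])
    ov, a_sp, b_sp, merged = overlap_callsets(a, a)
    assert set(ov.calls) == set(a.calls)
    assert len(a_sp) == len(b_sp) == 0 and len(merged) == len(a)
    b = _callset([("chr2", i) for i in range(1, 6)])
    ov, a_sp, b_sp, merged = overlap_callsets(a, b)
    assert len(ov) == 0 and len(merged) == len(a) + len(b)


def test_overlap_identity_random_sets():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = _callset({("chr1", int(p)) for p in rng.integers(1, 400, 200)})
        b = _callset({("chr1", int(p)) for p in rng.integers(1, 400, 200)})
        ov, a_sp, b_sp, merged = overlap_callsets(a, b)
        assert len(merged) == len(a) + len(b) - len(ov)
        assert set(ov.calls) <= set(a.calls) and set(ov.calls) <= set(b.calls)
        assert set(a_sp.calls) | set(ov.calls) == set(a.calls)
        assert set(b_sp.calls) | set(ov.calls) == set(b.calls)


# --- VCF ingestion -----------------------------------------------------------


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##contig=<ID=chrM,length=1000>
##INFO=<ID=AF,Number=A,Type=Float,Description="allele frequency">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t10\t.\tA\tG\t.\tPASS\t.\tAD\t70,30
chr1\t20\t.\tC\tT\t.\tPASS\t.\tAD\t50,50
chr1\t30\t.\tA\tC\t.\tPASS\t.\tAD\t50,50
chr1\t250\t.\tT\tC\t.\tPASS\tAF=0.25\tAD\t75,25
chr1\t260\t.\tA\tG\t.\tPASS\t.\tAD\t50,50
chr1\t150\t.\tA\tG\t.\tPASS\t.\tAD\t50,50
chr1\t40\t.\tA\tAG\t.\tPASS\t.\tAD\t50,50
chr1\t50\t.\tG\tA\t.\tPASS\t.\tAD\t50,50
chrM\t5\t.\tA\tG\t.\tPASS\t.\tAD\t50,50
chr1\t60\t.\tA\tG\t.\tPASS\t.\tAD\t90,10
"""


def test_read_callset_vcf_keeps_transcribed_strand_a_to_g(tmp_path):
    """Hand-classified 10-record VCF: keep A>G in + genes and T>C in -
    genes; drop other substitutions, indels and off-annotation records."""
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_TEXT)
    anno = ANNO[ANNO["chrom"] == "chr1"]
    cs = read_callset_vcf(path, anno, sample_id="s1")
    assert sorted(cs.calls) == [("chr1", 10), ("chr1", 60), ("chr1", 250)]
    assert cs.calls[("chr1", 10)].efficiency == pytest.approx(0.3)
    assert cs.calls[("chr1", 250)].strand == "-"
    assert cs.calls[("chr1", 250)].efficiency == pytest.approx(0.25)


def test_read_callset_vcf_single_record(tmp_path):
    head, body = VCF_TEXT.split("#CHROM")
    path = tmp_path / "one.vcf"
    path.write_text(head + "#CHROM" + body.split("\n")[0] + "\n"
                    + "chr1\t10\t.\tA\tG\t.\tPASS\t.\tAD\t70,30\n")
    assert len(read_callset_vcf(path, ANNO)) == 1


# --- sensitivity fold --------------------------------------------------------


def _high_eff_tables(effs, depth=200):
    rows_t, sites = [], []
    for i, e in enumerate(effs):
        pos = 10 + 9 * i
        alt = int(round(depth * e))
        rows_t.append(pileup_row("chr1", pos, "A",
                                 (depth - alt, 0, alt, 0)))
        sites.append(("chr1", pos, "A"))
    return frame(rows_t), clean_control(sites)


def test_fold_is_one_when_all_edits_efficient():
    treated, control = _high_eff_tables([0.2, 0.5, 0.9])
    res = sensitivity_fold(treated, control, ANNO)
    assert not res.flagged and res.fold == 1.0


def test_fold_flagged_on_empty_germline():
    treated, control = _high_eff_tables([0.03, 0.05])
    res = sensitivity_fold(treated, control, ANNO)
    assert res.flagged and res.n_somatic == 2 and res.n_germline == 0


def test_bed_round_trip(small_run, tmp_path):
    tx, _, _, _ = small_run
    tx.write_bed(tmp_path / "tx.bed")
    anno = read_bed(tmp_path / "tx.bed")
    pd.testing.assert_frame_equal(
        anno.sort_values("transcript_id").reset_index(drop=True),
        tx.annotation_frame().sort_values("transcript_id").reset_index(drop=True),
        check_like=True,
    )
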