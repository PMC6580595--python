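"""Junction-read trimming, mapping, insertion calling, and deduplication."""

import numpy as np
import pytest

import sbscreen as sb
from sbscreen.genome import ReferenceGenome, reverse_complement
from sbscreen.reads import (
    InsertionDataset,
    JunctionRead,
    Rejected,
    attrition_balanced,
    call_insertion,
    deduplicate_and_filter,
    load_alignments,
    map_read_exact,
    merge_samples,
    process_sample,
    trim_read,
    TrimmedRead,
)

TAG = "GTGTATGTAAACTTCC"
ADAPTER = "AGATCGGAAGAGC"


# ---------------------------------------------------------------------------
# Trimming


def test_trim_exact_tag_and_adapter_roundtrip():
    genomic = "TAGGGAAACCCTTTGG"
    read = JunctionRead("r1", TAG + genomic + ADAPTER)
    out = trim_read(read, TAG, ADAPTER, min_genomic_len=10)
    assert isinstance(out, TrimmedRead)
    assert out.genomic_sequence == genomic
    assert out.tag_found and out.tag_mismatches == 0


def test_trim_missing_tag_rejected():
    read = JunctionRead("r1", "CCCCCCCCCCCCCCCC" + "TAGGGAAACCCTTTGG")
    assert trim_read(read, TAG, ADAPTER) == Rejected("no_tag")


@pytest.mark.parametrize("max_mm, expect_ok", [(1, True), (0, False)])
def test_trim_tag_mismatch_threshold_boundary(max_mm, expect_ok):
    tag_1mm = "A" + TAG[1:]
    read = JunctionRead("r1", tag_1mm + "TAGGGAAACCCTTTGGACGT")
    out = trim_read(read, TAG, "", max_tag_mismatches=max_mm)
    if expect_ok:
        assert isinstance(out, TrimmedRead) and out.tag_mismatches == 1
    else:
        assert out == Rejected("no_tag")


def test_trim_short_genomic_portion_rejected():
    read = JunctionRead("r1", TAG + "TAGG" + ADAPTER)
    assert trim_read(read, TAG, ADAPTER, min_genomic_len=10) == Rejected("too_short")


def test_trim_partial_adapter_only_as_read_suffix():
    genomic = "TACCGGTTAACCGGTTAACC"
    # adapter 8-mer prefix at the very end of the read: trimmed
    read = JunctionRead("r1", TAG + genomic + ADAPTER[:8])
    out = trim_read(read, TAG, ADAPTER, min_genomic_len=10)
    assert out.genomic_sequence == genomic
    # the same 8-mer internal (not a suffix, not full adapter): NOT adapter evidence
    read2 = JunctionRead("r2", TAG + genomic + ADAPTER[:8] + "TTTTTTTT")
    out2 = trim_read(read2, TAG, ADAPTER, min_genomic_len=10)
    assert out2.genomic_sequence == genomic + ADAPTER[:8] + "TTTTTTTT"


def test_trim_rejects_invalid_characters():
    with pytest.raises(ValueError, match="r1"):
        trim_read(JunctionRead("r1", TAG + "TAXX"), TAG)


# ---------------------------------------------------------------------------
# Mapping


@pytest.fixture(scope="module")
def map_genome():
    rng = np.random.default_rng(12)
    chr1 = "".join(rng.choice(list("ACGT"), size=400))
    chr2 = "".join(rng.choice(list("ACGT"), size=400))
    return ReferenceGenome.from_dict({"chr1": chr1, "chr2": chr2})


def test_map_unique_forward_hit(map_genome):
    kmer = map_genome.sequences["chr1"][17:37]
    out = map_read_exact(TrimmedRead("r", kmer, True, 0), map_genome)
    assert out == ("chr1", 17, 37, "+")


def test_map_reverse_complement_symmetry(map_genome):
    kmer = map_genome.sequences["chr1"][17:37]
    out = map_read_exact(TrimmedRead("r", reverse_complement(kmer), True, 0), map_genome)
    assert out == ("chr1", 17, 37, "-")


def test_map_ambiguous_and_absent():
    genome = ReferenceGenome.from_dict(
        {"c": "ACGTACGTACGTCCCCCCCCACGTACGTACGT"}
    )
    assert map_read_exact(TrimmedRead("r", "ACGTACGTACGT", True, 0), genome) == Rejected("multimapped")
    assert map_read_exact(TrimmedRead("r", "TTTTTTTTTTTT", True, 0), genome) == Rejected("unmapped")


# ---------------------------------------------------------------------------
# SAM ingestion


def test_load_alignments_sam_conventions(tmp_path, map_genome):
    sam = tmp_path / "a.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        "@SQ\tSN:chr1\tLN:400\n"
        "@SQ\tSN:chr2\tLN:400\n"
        "r_fwd\t0\tchr1\t101\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        "r_rev\t16\tchr1\t151\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        "r_sec\t256\tchr1\t201\t60\t20M\t*\t0\t0\t*\t*\n"
        "r_lowq\t0\tchr2\t11\t3\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        "r_unmap\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t*\n"
    )
    recs = list(load_alignments(sam, "S1", genome=map_genome, min_mapq=10))
    assert recs == [
        ("r_fwd", "chr1", 100, 120, "+"),
        ("r_rev", "chr1", 150, 170, "-"),
    ]


def test_load_alignments_unknown_reference_errors(tmp_path, map_genome):
    sam = tmp_path / "a.sam"
    sam.write_text("@SQ\tSN:chr9\tLN:400\n")
    with pytest.raises(ValueError, match="chr9"):
        list(load_alignments(sam, "S1", genome=map_genome))


# ---------------------------------------------------------------------------
# Insertion calling


def test_call_insertion_conventions():
    genome = ReferenceGenome.from_dict({"c": "G" * 100 + "TACCGGAACCGGAACCGGTACCG" + "G" * 77})
    # + strand read starting at the TA at offset 100
    assert call_insertion(("c", 100, 120, "+"), genome) == ("c", 100, "+")
    # - strand read whose mapped interval ends at a ...TA at 118
    assert call_insertion(("c", 100, 120, "-"), genome) == ("c", 118, "-")
    # orientation flip inverts the reported orientation only
    assert call_insertion(("c", 100, 120, "+"), genome, orientation_flip=True) == ("c", 100, "-")


def test_call_insertion_requires_ta():
    genome = ReferenceGenome.from_dict({"c": "GGGGGGGGGGGGGGGGGGGG"})
    assert call_insertion(("c", 5, 15, "+"), genome, require_ta=True) == Rejected("no_ta")
    assert call_insertion(("c", 5, 15, "+"), genome, require_ta=False) == ("c", 5, "+")
    with pytest.raises(ValueError):
        call_insertion(("c", 15, 25, "+"), genome)


# ---------------------------------------------------------------------------
# Deduplication and merging


def test_dedup_collapses_and_counts_reads():
    cands = [("c", 10, "+")] * 3 + [("c", 50, "-")]
    ds, att = deduplicate_and_filter(cands, "S1")
    assert ds.n_total == 2
    row = ds.calls.set_index("pos").loc[10]
    assert row["read_count"] == 3
    assert att["duplicate_reads"] == 2 and att["retained_calls"] == 2


def test_dedup_min_reads_threshold():
    ds, att = deduplicate_and_filter([("c", 10, "+")], "S1", min_reads=2)
    assert ds.n_total == 0 and att["low_support"] == 1


def test_dedup_opposite_orientations_distinct_by_default():
    ds, _ = deduplicate_and_filter([("c", 10, "+"), ("c", 10, "-")], "S1")
    assert ds.n_total == 2
    ds2, _ = deduplicate_and_filter(
        [("c", 10, "+"), ("c", 10, "+"), ("c", 10, "-")], "S1",
        merge_opposite_orientations=True,
    )
    assert ds2.n_total == 1
    assert ds2.calls.iloc[0]["read_count"] == 3
    assert ds2.calls.iloc[0]["orientation"] == "+"  # majority orientation kept


def test_dedup_blacklist_removal():
    ds, att = deduplicate_and_filter(
        [("c", 10, "+"), ("c", 500, "+")], "S1", blacklist_regions=[("c", 0, 100)]
    )
    assert ds.calls["pos"].tolist() == [500]
    assert att["blacklisted"] == 1


def test_dedup_idempotent():
    cands = [("c", 10, "+")] * 3 + [("c", 50, "-")] * 2
    ds1, _ = deduplicate_and_filter(cands, "S1")
    again = [(r.chrom, r.pos, r.orientation) for r in ds1.calls.itertuples(index=False)]
    ds2, _ = deduplicate_and_filter(again, "S1")
    assert ds1.calls[["chrom", "pos", "orientation"]].equals(
        ds2.calls[["chrom", "pos", "orientation"]]
    )


def test_merge_samples_keeps_events_independent():
    a, _ = deduplicate_and_filter([("c", 10, "+")], "S1")
    b, _ = deduplicate_and_filter([("c", 10, "+")], "S2")
    merged = merge_samples({"S1": a, "S2": b}, {"S1": "selected", "S2": "selected"})
    assert merged.n_total == 2  # identical site in two samples = two events


def test_merge_samples_union_sizes_and_sheet_errors():
    a, _ = deduplicate_and_filter([("c", i * 3, "+") for i in range(10)], "S1")
    b, _ = deduplicate_and_filter([("c", 1000 + i * 3, "-") for i in range(5)], "S2")
    merged = merge_samples({"S1": a, "S2": b}, {"S1": "selected", "S2": "control"})
    assert merged.n_total == 15
    assert merged.has_arm("control")
    with pytest.raises(ValueError, match="S2"):
        merge_samples({"S1": a, "S2": b}, {"S1": "selected"})


def test_dataset_sample_sheet_consistency():
    a, _ = deduplicate_and_filter([("c", 10, "+")], "S1")
    with pytest.raises(ValueError, match="S1"):
        InsertionDataset(calls=a.calls, samples={"S9": "selected"})


# ---------------------------------------------------------------------------
# Whole-sample pipeline on a small synthetic screen


def test_pipeline_roundtrip_and_attrition_ledger(toy_bundle):
    from sbscreen import synth

    genome, _, ta_index, genes = toy_bundle
    truth = sb.plant_screen(
        genome, genes, [], n_background=50, n_selected_samples=2,
        n_control_samples=0, seed=5, ta_index=ta_index,
    )
    fq = sb.synthesize_reads(truth, genome, reads_per_insertion=2, seed=5)
    per_sample = {}
    for sample_id, recs in fq.items():
        jreads = [JunctionRead(n, s, q) for n, s, q in recs]
        ds, att = process_sample(jreads, genome, sample_id, synth.DEFAULT_TAG, synth.DEFAULT_ADAPTER)
        assert attrition_balanced(att)
        assert att["raw_reads"] == len(jreads)
        per_sample[sample_id] = ds
    merged = merge_samples(per_sample, truth.sample_sheet)
    key = ["sample_id", "chrom", "pos", "orientation"]
    got = merged.calls[key].sort_values(key).reset_index(drop=True)
    want = truth.to_dataset().calls[key].sort_values(key).reset_index(drop=True)
    assert got.equals(want)
    assert (merged.calls["read_count"] == 2).all()
    # every retained call sits on a genomic TA
    for r in merged.calls.itertuples(index=False):
        assert genome.sequences[r.chrom][r.pos : r.pos + 2] == "TA"
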