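"""Coverage vector construction, background noise, import/export."""
import numpy as np
import pysam
import pytest

from sinescout.coverage import (
    CoverageError,
    CoverageTrack,
    background_value,
    build_coverage_vector,
    compute_background,
    export_coverage,
    import_coverage,
    region_mean_coverage,
)

from conftest import write_sam


def pair_rows(qname, chrom, pos1, pos2, cigar1="76M", cigar2="76M", nh=1,
              mapq=60, read1_reverse=True):
    """A proper fr-firststrand pair for a '+' transcript by default."""
    seq = "A" * 76
    qual = "I" * 76
    f1 = 0x1 | 0x2 | 0x40 | (0x10 if read1_reverse else 0x20)
    f2 = 0x1 | 0x2 | 0x80 | (0x20 if read1_reverse else 0x10)
    return [
        (qname, f2, chrom, pos1, mapq, cigar1, "=", pos2, 200, seq, qual, f"NH:i:{nh}"),
        (qname, f1, chrom, pos2, mapq, cigar2, "=", pos1, -200, seq, qual, f"NH:i:{nh}"),
    ]


def test_single_forward_mate1_fr_secondstrand_piles_on_plus(tmp_path):
    # one 76M read, NH=1, mate-1 forward => 76 positions at depth 1 on '+'
    sam = write_sam(
        tmp_path / "one.sam", {"chr1": 1000},
        [("r1", 0x1 | 0x2 | 0x40 | 0x20, "chr1", 101, 60, "76M", "=", 101, 76,
          "A" * 76, "I" * 76, "NH:i:1")],
    )
    track = build_coverage_vector(sam, "fr-secondstrand")
    plus = track.array("chr1", "+")
    assert plus[100:176].sum() == 76
    assert plus.sum() == 76
    assert track.array("chr1", "-").sum() == 0


def test_multimapping_reads_contribute_nothing(tmp_path):
    rows = pair_rows("u", "chr1", 101, 225) + pair_rows("m", "chr1", 301, 425, nh=2)
    sam = write_sam(tmp_path / "nh.sam", {"chr1": 1000}, rows)
    track = build_coverage_vector(sam)
    assert track.total_signal == 152.0
    assert track.array("chr1", "+")[300:501].sum() == 0


def test_mapq_fallback_when_nh_missing(tmp_path):
    rows = [
        ("hi", 0x1 | 0x2 | 0x40 | 0x20, "chr1", 101, 60, "76M", "=", 101, 76,
         "A" * 76, "I" * 76),
        ("lo", 0x1 | 0x2 | 0x40 | 0x20, "chr1", 301, 5, "76M", "=", 301, 76,
         "A" * 76, "I" * 76),
    ]
    sam = write_sam(tmp_path / "mapq.sam", {"chr1": 1000}, rows)
    track = build_coverage_vector(sam, "fr-secondstrand", mapq_min=30)
    assert track.total_signal == 76.0


def _naive_pileup(sam_path, strandedness, mapq_min=30):
    """Independent per-read, per-position counting oracle."""
    from sinescout.coverage import _is_unique, fragment_strand

    depth = {}
    with pysam.AlignmentFile(sam_path) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not _is_unique(read, mapq_min):
                continue
            strand = fragment_strand(read, strandedness)
            for pos in read.get_reference_positions():
                key = (read.reference_name, strand, pos)
                depth[key] = depth.get(key, 0) + 1
    return depth


def test_spliced_read_covers_blocks_not_gap(tmp_path):
    rows = [("s", 0x1 | 0x2 | 0x40 | 0x20, "chr1", 101, 60, "30M100N46M", "=",
             101, 176, "A" * 76, "I" * 76, "NH:i:1")]
    sam = write_sam(tmp_path / "spliced.sam", {"chr1": 1000}, rows)
    track = build_coverage_vector(sam, "fr-secondstrand")
    plus = track.array("chr1", "+")
    assert plus[100:130].sum() == 30
    assert plus[130:230].sum() == 0
    assert plus[230:276].sum() == 46
    oracle = _naive_pileup(sam, "fr-secondstrand")
    for (chrom, strand, pos), d in oracle.items():
        assert track.array(chrom, strand)[pos] == d
    assert track.total_signal == sum(oracle.values())


@pytest.mark.parametrize(
    "total,size,stranded,expected",
    [(6e9, 3e9, False, 2.0), (6e9, 3e9, True, 1.0)],
)
def test_background_three_vs_six_billion_rule(total, size, stranded, expected):
    est = background_value(total, size, stranded)
    assert est.value == expected
    assert est.value * est.denominator == total


def test_background_zero_signal_and_zero_genome(tmp_path, caplog):
    track = CoverageTrack({"chr1": 100}, "unstranded")
    with caplog.at_level("WARNING"):
        est = compute_background(track)
    assert est.value == 0.0
    with pytest.raises(CoverageError):
        background_value(10.0, 0, False)


class TestRegionMean:
    def test_uniform_and_mixed_intervals(self):
        track = CoverageTrack({"chr1": 10}, "unstranded")
        track.array("chr1")[:] = 3.0
        assert region_mean_coverage(track, "chr1", 2, 8) == 3.0
        track.array("chr1")[0:4] = [0, 0, 6, 6]
        assert region_mean_coverage(track, "chr1", 0, 4) == 3.0

    def test_empty_and_out_of_bounds_intervals_error(self):
        track = CoverageTrack({"chr1": 10}, "unstranded")
        with pytest.raises(CoverageError):
            region_mean_coverage(track, "chr1", 5, 5)
        with pytest.raises(CoverageError):
            region_mean_coverage(track, "chr1", 5, 11)


@pytest.mark.parametrize("fmt", ["bedgraph", "bigwig"])
def test_export_import_round_trip(tmp_path, fmt):
    track = CoverageTrack({"chrA": 50, "chrB": 30}, "fr-firststrand")
    track.array("chrA", "+")[0:10] = 2
    track.array("chrA", "-")[10:15] = 7
    track.array("chrB", "+")[29] = 1
    export_coverage(track, tmp_path / "cov", fmt)
    back = import_coverage(tmp_path / "cov", strandedness="fr-firststrand")
    for key, arr in track.arrays.items():
        np.testing.assert_array_equal(back.arrays[key], arr)
    assert compute_background(back).value == compute_background(track).value


def test_bedgraph_intervals_fill_arrays(tmp_path):
    (tmp_path / "cov.bedgraph").write_text("chr1\t0\t10\t2\nchr1\t10\t15\t0\n")
    track = import_coverage(
        tmp_path / "cov", chrom_sizes={"chr1": 15}, strandedness="unstranded"
    )
    np.testing.assert_array_equal(track.array("chr1"), [2] * 10 + [0] * 5)


def test_missing_strand_file_is_fatal(tmp_path):
    (tmp_path / "cov.plus.bedgraph").write_text("chr1\t0\t5\t1\n")
    with pytest.raises(CoverageError, match="minus"):
        import_coverage(tmp_path / "cov", {"chr1": 10}, "fr-firststrand")


def test_negative_values_in_file_are_fatal(tmp_path):
    (tmp_path / "cov.bedgraph").write_text("chr1\t0\t5\t-1\n")
    with pytest.raises(CoverageError, match="negative"):
        import_coverage(tmp_path / "cov", {"chr1": 10}, "unstranded")


def test_strand_partition_sums_to_unstranded(mini_files):
    stranded = build_coverage_vector(mini_files["sam"], "fr-firststrand")
    unstranded = build_coverage_vector(mini_files["sam"], "unstranded")
    for chrom in stranded.chrom_sizes:
        both = stranded.array(chrom, "+") + stranded.array(chrom, "-")
        np.testing.assert_array_equal(both, unstranded.array(chrom))
    # total signal conservation: every retained pair contributes 2*76 bases
    assert stranded.total_signal == mini_files["stats"]["aligned_bases"]


def test_duplicating_reads_doubles_signal_and_background(tmp_path):
    rows = pair_rows("a", "chr1", 101, 225) + pair_rows("b", "chr1", 401, 525)
    sam1 = write_sam(tmp_path / "x1.sam", {"chr1": 1000}, rows)
    doubled = rows + [(r[0] + "_dup",) + r[1:] for r in rows]
    doubled.sort(key=lambda r: r[3])
    sam2 = write_sam(tmp_path / "x2.sam", {"chr1": 1000}, doubled)
    t1 = build_coverage_vector(sam1)
    t2 = build_coverage_vector(sam2)
    assert t2.total_signal == 2 * t1.total_signal
    assert compute_background(t2).value == 2 * compute_background(t1).value
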