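"""Needleman-Wunsch alignment, central-body inference, flanks, terminator."""
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from sinescout.annotations_io import ConsensusLibrary, GenomeSequence, SineAnnotation
from sinescout.body_mapping import (
    AlignmentScoring,
    CentralBody,
    define_flanking_regions,
    find_terminator,
    infer_central_body,
    needleman_wunsch,
    revcomp,
)

SCORING = AlignmentScoring()


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment as (a_aligned, b_aligned) gapped strings."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for qa, ba in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + qa, b[0] + ba
    if a:
        for qa, ba in enumerate_alignments(a[1:], b):
            yield a[0] + qa, "-" + ba
    if b:
        for qa, ba in enumerate_alignments(a, b[1:]):
            yield "-" + qa, b[0] + ba


def score_alignment(qa: str, ba: str, s: AlignmentScoring = SCORING) -> float:
    total = 0.0
    for x, y in zip(qa, ba):
        if "-" in (x, y):
            total += s.gap
        else:
            total += s.match if (x == y and x != "N") else s.mismatch
    return total


def exhaustive_best(a: str, b: str, s: AlignmentScoring = SCORING, _memo=None):
    """Best score by recursive exhaustive search over suffix alignments."""
    if _memo is None:
        _memo = {}
    key = (len(a), len(b))
    if key in _memo:
        return _memo[key]
    if not a and not b:
        return 0.0
    best = -float("inf")
    if a and b:
        sub = s.match if (a[0] == b[0] and a[0] != "N") else s.mismatch
        best = max(best, sub + exhaustive_best(a[1:], b[1:], s, _memo))
    if a:
        best = max(best, s.gap + exhaustive_best(a[1:], b, s, _memo))
    if b:
        best = max(best, s.gap + exhaustive_best(a, b[1:], s, _memo))
    _memo[key] = best
    return best


def test_exhaustive_oracle_agrees_with_literal_enumeration():
    """Validate the search oracle itself against brute enumeration at tiny n."""
    rng = random.Random(1)
    for _ in range(30):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
        literal = max(score_alignment(qa, ba) for qa, ba in enumerate_alignments(a, b))
        assert exhaustive_best(a, b) == literal


@pytest.mark.parametrize(
    "query,consensus,score,gapsum",
    [
        ("ACGT", "ACGT", 4.0, 0),   # identity: 4 matches
        ("A", "AAAA", -5.0, 3),     # 1 match + 3 terminal consensus gaps
        ("AGT", "ACGT", 1.0, 0),    # optimum A-GT/ACGT: internal gap only
    ],
)
def test_worked_examples(query, consensus, score, gapsum):
    aln = needleman_wunsch(query, consensus)
    assert aln.score == score
    assert aln.leading_consensus_gap + aln.trailing_consensus_gap == gapsum
    assert aln.query_aligned.replace("-", "") == query
    assert aln.consensus_aligned.replace("-", "") == consensus


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        needleman_wunsch("ACGT", "")


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=8),
    st.text(alphabet="ACGT", min_size=1, max_size=8),
)
def test_dp_score_matches_exhaustive_search(a, b):
    assert needleman_wunsch(a, b).score == exhaustive_best(a, b)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.text(alphabet="ACGTN", min_size=1, max_size=12),
    st.text(alphabet="ACGTN", min_size=1, max_size=12),
)
def test_score_symmetry(a, b):
    assert needleman_wunsch(a, b).score == needleman_wunsch(b, a).score


def test_score_matches_independent_aligner():
    """Cross-check against Biopython's global aligner on longer sequences."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    rng = random.Random(5)
    for _ in range(25):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
        assert needleman_wunsch(a, b).score == aligner.score(a, b)


# ---------------------------------------------------------------------------
# Central-body inference

def _setup(consensus, insert, strand, at, pad=600, rng_seed=0):
    rng = random.Random(rng_seed)
    chrom = "".join(rng.choice("ACGT") for _ in range(at + len(insert) + pad))
    chrom = chrom[:at] + insert + chrom[at + len(insert):]
    genome = GenomeSequence({"chr1": chrom})
    library = ConsensusLibrary({"AluSyn": consensus})
    ann = SineAnnotation("L", "chr1", at, at + len(insert), strand, "Alu", "AluSyn")
    return ann, genome, library


def _consensus(n=300, seed=2):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _truncatable_consensus(n, cut, side, seed=2):
    """Consensus whose truncated portion shares no alphabet with the rest,
    so the optimal alignment of the remaining fragment is unique and its
    terminal consensus gaps equal the truncation length exactly."""
    rng = random.Random(seed)
    body = "".join(rng.choice("AC") for _ in range(n - cut))
    return ("G" * cut + body) if side == "5p" else (body + "G" * cut)


def test_full_length_annotation_gets_no_extension():
    cons = _consensus()
    ann, genome, library = _setup(cons, cons, "+", 1000)
    body, aln = infer_central_body(ann, genome, library)
    assert (body.start, body.end) == (ann.start, ann.end)
    assert (body.extension_5p, body.extension_3p) == (0, 0)
    assert not body.fallback


def test_five_prime_truncated_fragment_extends_upstream():
    cons = _truncatable_consensus(300, 50, "5p")
    ann, genome, library = _setup(cons, cons[50:], "+", 1000)
    body, aln = infer_central_body(ann, genome, library)
    assert aln.leading_consensus_gap == 50
    assert body.start == ann.start - 50
    assert body.end == ann.end
    assert body.extension_5p == 50


def test_minus_strand_three_prime_truncation_extends_genomic_left():
    cons = _truncatable_consensus(260, 60, "3p")
    ann, genome, library = _setup(cons, revcomp(cons[:200]), "-", 1000)
    body, aln = infer_central_body(ann, genome, library)
    assert aln.trailing_consensus_gap == 60
    assert (body.start, body.end) == (ann.start - 60, ann.end)
    assert body.extension_3p == 60


def test_extension_clipped_at_chromosome_edge():
    cons = _truncatable_consensus(300, 50, "5p")
    ann, genome, library = _setup(cons, cons[50:], "+", 20)
    body, _ = infer_central_body(ann, genome, library)
    assert body.start == 0
    assert body.clipped


def test_poor_alignment_falls_back_to_annotation_interval():
    cons = _consensus()
    garbage = "G" * 150
    ann, genome, library = _setup(cons, garbage, "+", 1000)
    body, aln = infer_central_body(ann, genome, library)
    assert aln.score < 0
    assert body.fallback
    assert (body.start, body.end) == (ann.start, ann.end)


# ---------------------------------------------------------------------------
# Flanking regions

def test_plus_strand_flank_layout():
    body = CentralBody("chr1", 1000, 1300, "+", "L")
    fl = define_flanking_regions(body, 10_000, 100, 200, 100)
    assert fl.left == (900, 1000)
    assert fl.right == (1300, 1500)
    assert fl.out == (1500, 1600)
    assert not fl.clipped


def test_minus_strand_flank_layout_is_mirrored():
    body = CentralBody("chr1", 1000, 1300, "-", "L")
    fl = define_flanking_regions(body, 10_000, 100, 200, 100)
    assert fl.left == (1300, 1400)
    assert fl.right == (800, 1000)
    assert fl.out == (700, 800)


def test_left_flank_clipped_at_chromosome_start():
    body = CentralBody("chr1", 30, 330, "+", "L")
    fl = define_flanking_regions(body, 10_000, 100, 200, 100)
    assert fl.left == (0, 30)
    assert fl.clipped


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("start,end", [(1000, 1300), (2000, 2260), (5000, 5070)])
def test_flank_geometry_contiguous_and_disjoint(strand, start, end):
    body = CentralBody("chr1", start, end, strand, "L")
    fl = define_flanking_regions(body, 100_000, 100, 200, 100)
    intervals = sorted([fl.left, (body.start, body.end), fl.right, fl.out])
    for (s1, e1), (s2, e2) in itertools.pairwise(intervals):
        assert e1 == s2  # contiguous, hence disjoint
    total = intervals[-1][1] - intervals[0][0]
    assert total == (end - start) + 100 + 200 + 100


# ---------------------------------------------------------------------------
# Terminator scan

def test_terminator_found_downstream_on_plus():
    rng = random.Random(9)
    seq = "".join(rng.choice("ACG") for _ in range(400))
    seq = seq[:337] + "TTTT" + seq[341:]
    genome = GenomeSequence({"chr1": seq})
    body = CentralBody("chr1", 0, 300, "+", "L")
    hit = find_terminator(genome, body, max_scan=300, min_run=4)
    assert hit.found
    assert hit.offset == 37
    assert hit.length >= 4


def test_terminator_absent_within_scan_window():
    genome = GenomeSequence({"chr1": "ACG" * 300})
    body = CentralBody("chr1", 0, 300, "+", "L")
    assert not find_terminator(genome, body).found


def test_terminator_on_minus_strand_via_revcomp_oracle():
    rng = random.Random(13)
    upstream = "".join(rng.choice("CGT") for _ in range(300))
    # plant AAAA so the transcript-strand scan finds a T-run at offset 25
    upstream = upstream[:271] + "AAAA" + upstream[275:]
    seq = upstream + "".join(rng.choice("ACGT") for _ in range(300))
    genome = GenomeSequence({"chr1": seq})
    body = CentralBody("chr1", 300, 600, "-", "L")
    hit = find_terminator(genome, body, max_scan=300, min_run=4)
    # independent oracle: scan the reverse-complemented upstream window
    window = revcomp(seq[0:300])
    assert window[hit.offset:hit.offset + 4] == "TTTT"
    assert hit.found
    assert hit.offset == 25
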