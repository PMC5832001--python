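"""Central-body inference by global alignment to the family consensus.

Many annotated SINEs are fragments of their ancestral full-length element,
yet Pol III transcription runs from the element 5' end to the first
downstream poly(dT); the filter geometry therefore needs the footprint of
the *full-length* element, not the annotated fragment.  The annotated
sequence (in transcription orientation) is globally aligned to the family
consensus with the Needleman-Wunsch algorithm; consensus positions missing
from the query at the alignment's 5'/3' ends extend the body arithmetically
on the corresponding genomic side.

Scoring defaults are match +1 / mismatch -1 / linear gap -2; 'N' never
matches.  Traceback tie-breaking is deterministic: diagonal, then up
(query-consuming), then left (consensus-consuming).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap penalty must be negative")


@dataclass(frozen=True)
class GlobalAlignment:
    score: float
    query_aligned: str
    consensus_aligned: str
    leading_consensus_gap: int
    trailing_consensus_gap: int


def _nw_fill_impl(q, c, match, mismatch, gap):
    n = q.shape[0]
    m = c.shape[0]
    score = np.empty((n + 1, m + 1), dtype=np.float64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    score[0, 0] = 0.0
    for i in range(1, n + 1):
        score[i, 0] = i * gap
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = j * gap
        ptr[0, j] = 2
    nn = 78  # ord('N'): never a match
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qi == c[j - 1] and qi != nn) else mismatch
            best = score[i - 1, j - 1] + sub
            p = 0
            up = score[i - 1, j] + gap
            if up > best:
                best = up
                p = 1
            left = score[i, j - 1] + gap
            if left > best:
                best = left
                p = 2
            score[i, j] = best
            ptr[i, j] = p
    return score, ptr


try:  # numba accelerates the DP fill; the pure-Python fallback is identical
    from numba import njit

    _nw_fill = njit(cache=True)(_nw_fill_impl)
except ImportError:  # pragma: no cover
    _nw_fill = _nw_fill_impl


def needleman_wunsch(
    query_seq: str, consensus_seq: str, scoring: Optional[AlignmentScoring] = None
) -> GlobalAlignment:
    """Optimal global alignment of query vs consensus under linear gaps."""
    if not query_seq or not consensus_seq:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    query_seq = query_seq.upper()
    consensus_seq = consensus_seq.upper()
    q = np.frombuffer(query_seq.encode("ascii"), dtype=np.uint8)
    c = np.frombuffer(consensus_seq.encode("ascii"), dtype=np.uint8)
    score, ptr = _nw_fill(q, c, scoring.match, scoring.mismatch, scoring.gap)
    i, j = len(query_seq), len(consensus_seq)
    qa: list = []
    ca: list = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            qa.append(query_seq[i - 1])
            ca.append(consensus_seq[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and p == 1:
            qa.append(query_seq[i - 1])
            ca.append("-")
            i -= 1
        else:
            qa.append("-")
            ca.append(consensus_seq[j - 1])
            j -= 1
    query_aligned = "".join(reversed(qa))
    consensus_aligned = "".join(reversed(ca))
    leading = 0
    for ch in query_aligned:
        if ch != "-":
            break
        leading += 1
    trailing = 0
    for ch in reversed(query_aligned):
        if ch != "-":
            break
        trailing += 1
    return GlobalAlignment(
        score=float(score[len(query_seq), len(consensus_seq)]),
        query_aligned=query_aligned,
        consensus_aligned=consensus_aligned,
        leading_consensus_gap=leading,
        trailing_consensus_gap=trailing,
    )


@dataclass(frozen=True)
class CentralBody:
    """Inferred footprint of the ancestral full-length element."""

    chrom: str
    start: int
    end: int
    strand: str
    derived_from: str
    extension_5p: int = 0
    extension_3p: int = 0
    fallback: bool = False
    clipped: bool = False


class ConsensusUnresolvable(LookupError):
    """No consensus entry matches the annotation's subfamily or family."""


def infer_central_body(
    annotation,
    genome,
    consensus_library,
    scoring: Optional[AlignmentScoring] = None,
    score_floor: float = 0.0,
) -> Tuple[CentralBody, GlobalAlignment]:
    """Map an annotated (possibly fragmentary) SINE onto its full-length body.

    The annotated genomic sequence, reverse-complemented for '-' strand
    loci, is aligned to the consensus.  Leading consensus gaps extend the
    body on the transcript-5' genomic side, trailing gaps on the
    transcript-3' side; extensions are clipped at chromosome edges.  When
    the alignment score falls below ``score_floor`` the consensus mapping is
    considered unreliable and the body falls back to the annotation
    interval, flagged.
    """
    if annotation.chrom not in genome:
        raise ValueError(f"{annotation.locus_id}: chrom {annotation.chrom} not in genome")
    resolved = consensus_library.resolve(annotation.subfamily, annotation.family)
    if resolved is None:
        raise ConsensusUnresolvable(
            f"{annotation.locus_id}: no consensus for "
            f"{annotation.subfamily!r}/{annotation.family!r}"
        )
    _, consensus = resolved
    seq = genome.fetch(annotation.chrom, annotation.start, annotation.end)
    if annotation.strand == "-":
        seq = revcomp(seq)
    aln = needleman_wunsch(seq, consensus, scoring)
    chrom_len = genome.lengths[annotation.chrom]
    if aln.score < score_floor:
        body = CentralBody(
            chrom=annotation.chrom,
            start=annotation.start,
            end=annotation.end,
            strand=annotation.strand,
            derived_from=annotation.locus_id,
            fallback=True,
        )
        return body, aln
    ext5 = aln.leading_consensus_gap
    ext3 = aln.trailing_consensus_gap
    if annotation.strand == "+":
        start = annotation.start - ext5
        end = annotation.end + ext3
    else:
        start = annotation.start - ext3
        end = annotation.end + ext5
    clipped = start < 0 or end > chrom_len
    start_c = max(0, start)
    end_c = min(chrom_len, end)
    if annotation.strand == "+":
        ext5 = annotation.start - start_c
        ext3 = end_c - annotation.end
    else:
        ext5 = end_c - annotation.end
        ext3 = annotation.start - start_c
    body = CentralBody(
        chrom=annotation.chrom,
        start=start_c,
        end=end_c,
        strand=annotation.strand,
        derived_from=annotation.locus_id,
        extension_5p=ext5,
        extension_3p=ext3,
        clipped=clipped,
    )
    return body, aln


@dataclass(frozen=True)
class FlankingRegions:
    """left | body | right | out in transcription orientation.

    The right region (default 200 bp) immediately follows the full-length
    element and is where the poly(dT) terminator is expected; left and out
    lie outside the Pol III transcription unit.  Intervals are clipped at
    chromosome edges (possibly to empty) with the ``clipped`` flag set.
    """

    left: Tuple[int, int]
    right: Tuple[int, int]
    out: Tuple[int, int]
    left_len: int
    right_len: int
    out_len: int
    clipped: bool


def _clip(start: int, end: int, chrom_length: int) -> Tuple[Tuple[int, int], bool]:
    cs, ce = max(0, start), min(chrom_length, end)
    if cs > ce:
        cs = ce = min(max(start, 0), chrom_length)
    return (cs, ce), (cs, ce) != (start, end)


def define_flanking_regions(
    body: CentralBody,
    chrom_length: int,
    left_len: int = 100,
    right_len: int = 200,
    out_len: int = 100,
) -> FlankingRegions:
    if min(left_len, right_len, out_len) <= 0:
        raise ValueError("flank lengths must be positive")
    if body.start < 0 or body.end > chrom_length:
        raise ValueError("body outside chromosome")
    if body.strand == "+":
        left = (body.start - left_len, body.start)
        right = (body.end, body.end + right_len)
        out = (body.end + right_len, body.end + right_len + out_len)
    else:
        left = (body.end, body.end + left_len)
        right = (body.start - right_len, body.start)
        out = (body.start - right_len - out_len, body.start - right_len)
    left_c, cl = _clip(*left, chrom_length)
    right_c, cr = _clip(*right, chrom_length)
    out_c, co = _clip(*out, chrom_length)
    return FlankingRegions(
        left=left_c, right=right_c, out=out_c,
        left_len=left_len, right_len=right_len, out_len=out_len,
        clipped=cl or cr or co,
    )


@dataclass(frozen=True)
class TerminatorHit:
    offset: int
    length: int
    found: bool


def find_terminator(
    genome, body: CentralBody, max_scan: int = 300, min_run: int = 4
) -> TerminatorHit:
    """First run of >= min_run T on the transcript strand downstream of the body.

    Diagnostic only: the verdict logic never depends on it, because Pol III
    termination may legitimately occur anywhere within the right region.
    """
    chrom_len = genome.lengths[body.chrom]
    if body.strand == "+":
        window = genome.fetch(body.chrom, body.end, min(chrom_len, body.end + max_scan))
    else:
        window = revcomp(genome.fetch(body.chrom, max(0, body.start - max_scan), body.start))
    run_start = run_len = 0
    i = 0
    n = len(window)
    while i < n:
        if window[i] == "T":
            j = i
            while j < n and window[j] == "T":
                j += 1
            if j - i >= min_run:
                run_start, run_len = i, j - i
                return TerminatorHit(offset=run_start, length=run_len, found=True)
            i = j
        else:
            i += 1
    return TerminatorHit(offset=-1, length=0, found=False)
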