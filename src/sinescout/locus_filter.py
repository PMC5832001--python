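"""Per-locus verdicts: background gate plus the Flanking Region Filter.

A genuine, autonomously transcribed Pol III SINE produces a coverage island
over the element body that (i) rises above the genome-wide background noise
and (ii) is strongly enriched over its upstream 'left' and far-downstream
'out' flanks, while exceeding the adjacent 'right' region where Pol III
termination occurs.  A passenger SINE embedded in an expressed Pol II
transcript shares its coverage with its flanks and fails clause (ii).

The region statistic is the arithmetic mean depth, matching the
mean-per-base semantics of the background estimate.  "Highly enriched" is a
single fold factor f (default 10) applied to both left and out, with each
flank floored at the background so enrichment is anchored to the noise
floor; the right-region comparison is a plain strict inequality, since
partial signal there (the transcript's 3' tail up to the terminator) is
expected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .body_mapping import (
    AlignmentScoring,
    CentralBody,
    ConsensusUnresolvable,
    FlankingRegions,
    TerminatorHit,
    define_flanking_regions,
    find_terminator,
    infer_central_body,
)
from .coverage import BackgroundEstimate, CoverageTrack, region_mean_coverage

log = logging.getLogger(__name__)

PASS = "PASS"
FAIL_BACKGROUND = "FAIL_BACKGROUND"
FAIL_FLANK = "FAIL_FLANK"
SKIPPED = "SKIPPED"


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds and geometry of the filter."""

    bg_fold: float = 3.0        # the '-bg' value: body over background fold
    flank_enrich: float = 10.0  # fold required over left and out flanks
    left_len: int = 100
    right_len: int = 200
    out_len: int = 100
    mapq_min: int = 30
    strandedness: str = "fr-firststrand"
    max_scan: int = 300
    min_run: int = 4
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    score_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.bg_fold > 0:
            raise ValueError("bg_fold must be > 0")
        if not self.flank_enrich > 1:
            raise ValueError("flank_enrich must be > 1")
        if min(self.left_len, self.right_len, self.out_len) <= 0:
            raise ValueError("flank lengths must be positive")


@dataclass(frozen=True)
class RegionCoverages:
    body: float
    left: Optional[float]
    right: Optional[float]
    out: Optional[float]
    background: float


@dataclass
class LocusCall:
    annotation: object
    verdict: str
    coverages: RegionCoverages
    body: Optional[CentralBody] = None
    flanks: Optional[FlankingRegions] = None
    over_background: bool = False
    flank_pass: bool = False
    fail_reasons: List[str] = field(default_factory=list)
    expression: Optional[float] = None
    read_count: Optional[int] = None
    terminator: Optional[TerminatorHit] = None

    def report_row(self) -> tuple:
        ann = self.annotation
        body = self.body
        term = self.terminator
        return (
            ann.locus_id, ann.chrom, ann.start, ann.end, ann.strand,
            ann.subfamily, ann.family,
            self.verdict, self.over_background, self.flank_pass,
            ",".join(self.fail_reasons) if self.fail_reasons else None,
            self.coverages.background,
            body.start if body else None,
            body.end if body else None,
            body.fallback if body else None,
            (body.clipped or (self.flanks.clipped if self.flanks else False))
            if body else None,
            self.coverages.body,
            self.coverages.left,
            self.coverages.right,
            self.coverages.out,
            self.expression,
            term.found if term else None,
            term.offset if term and term.found else None,
        )


def background_gate(body_mean: float, background: float, n: float) -> bool:
    """True iff the locus coverage exceeds n times the background noise.

    The boundary is inclusive; with zero background any signal passes.
    """
    if background == 0:
        return body_mean > 0
    return body_mean >= n * background


def flanking_region_filter(
    rc: RegionCoverages, f: float
) -> Tuple[bool, List[str]]:
    """Apply the Flanking Region Filter to one locus.

    Pass iff body >= f * floor(left) and body >= f * floor(out) and
    body > right, where floor(x) = max(x, background).
    """
    floor = lambda x: max(x if x is not None else 0.0, rc.background)
    reasons: List[str] = []
    if not rc.body >= f * floor(rc.left):
        reasons.append("left")
    if not rc.body >= f * floor(rc.out):
        reasons.append("out")
    right = rc.right if rc.right is not None else 0.0
    if not rc.body > right:
        reasons.append("right")
    return (not reasons), reasons


def _mean_or_zero(track: CoverageTrack, chrom: str, interval, strand: str) -> float:
    start, end = interval
    if start >= end:
        return 0.0
    return region_mean_coverage(track, chrom, start, end, strand)


def call_locus(
    annotation,
    track: CoverageTrack,
    genome,
    library,
    params: PipelineParams,
    background: BackgroundEstimate,
) -> LocusCall:
    """Evaluate one annotated SINE through the full decision flow.

    The cheap background gate runs first on the annotated interval; only
    gated loci proceed to consensus alignment, flank layout and the
    Flanking Region Filter.
    """
    strand = "." if not track.stranded else annotation.strand
    chrom_len = track.chrom_sizes.get(annotation.chrom)
    if chrom_len is None or annotation.end > chrom_len:
        return LocusCall(
            annotation=annotation,
            verdict=SKIPPED,
            coverages=RegionCoverages(0.0, None, None, None, background.value),
            fail_reasons=["annotation outside coverage track"],
        )
    gate_mean = region_mean_coverage(
        track, annotation.chrom, annotation.start, annotation.end, strand
    )
    if not background_gate(gate_mean, background.value, params.bg_fold):
        return LocusCall(
            annotation=annotation,
            verdict=FAIL_BACKGROUND,
            coverages=RegionCoverages(gate_mean, None, None, None, background.value),
            over_background=False,
            fail_reasons=["background"],
        )
    try:
        body, _aln = infer_central_body(
            annotation, genome, library, params.scoring, params.score_floor
        )
    except ConsensusUnresolvable as exc:
        log.warning("%s", exc)
        return LocusCall(
            annotation=annotation,
            verdict=SKIPPED,
            coverages=RegionCoverages(gate_mean, None, None, None, background.value),
            over_background=True,
            fail_reasons=["consensus unresolvable"],
        )
    flanks = define_flanking_regions(
        body, chrom_len, params.left_len, params.right_len, params.out_len
    )
    rc = RegionCoverages(
        body=_mean_or_zero(track, annotation.chrom, (body.start, body.end), strand),
        left=_mean_or_zero(track, annotation.chrom, flanks.left, strand),
        right=_mean_or_zero(track, annotation.chrom, flanks.right, strand),
        out=_mean_or_zero(track, annotation.chrom, flanks.out, strand),
        background=background.value,
    )
    ok, reasons = flanking_region_filter(rc, params.flank_enrich)
    terminator = find_terminator(genome, body, params.max_scan, params.min_run)
    return LocusCall(
        annotation=annotation,
        verdict=PASS if ok else FAIL_FLANK,
        coverages=rc,
        body=body,
        flanks=flanks,
        over_background=True,
        flank_pass=ok,
        fail_reasons=reasons,
        expression=rc.body,
        terminator=terminator,
    )
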