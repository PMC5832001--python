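"""Genome expression coverage from uniquely mapped reads.

The coverage vector is the pipeline's primary signal: per-base read depth on
each strand of every chromosome, built from primary, non-supplementary,
uniquely mapped alignments.  A read is "unique" when its NH tag equals 1;
when no NH tag is present, MAPQ >= mapq_min (default 30) stands in, which is
the common convention across spliced aligners.

The background noise signal is the mean depth per strand-aware genomic
position: total aligned-base signal divided by genome size, doubled for
stranded protocols (for the human genome this is the familiar 3-vs-6 billion
denominator; here the genome size is always taken from the header so the
same rule applies to synthetic genomes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pysam

log = logging.getLogger(__name__)

STRANDEDNESS = ("unstranded", "fr-firststrand", "fr-secondstrand")

#: CIGAR operations that consume both read and reference (add depth)
_ALIGNED_OPS = frozenset((0, 7, 8))  # M, =, X
#: CIGAR operations that consume reference only (no depth)
_REF_SKIP_OPS = frozenset((2, 3))  # D, N


class CoverageError(ValueError):
    """Raised for unusable coverage inputs."""


class CoverageTrack:
    """Per (chrom, strand) base-resolution read-depth arrays.

    Stranded tracks keep separate '+' and '-' arrays; unstranded tracks use
    the single strand key '.'.
    """

    def __init__(self, chrom_sizes: Dict[str, int], strandedness: str):
        if strandedness not in STRANDEDNESS:
            raise CoverageError(f"unknown strandedness {strandedness!r}")
        self.chrom_sizes = dict(chrom_sizes)
        self.strandedness = strandedness
        self.strands: Tuple[str, ...] = (
            (".",) if strandedness == "unstranded" else ("+", "-")
        )
        self.arrays: Dict[Tuple[str, str], np.ndarray] = {
            (chrom, strand): np.zeros(size, dtype=np.float64)
            for chrom, size in self.chrom_sizes.items()
            for strand in self.strands
        }

    @property
    def stranded(self) -> bool:
        return self.strandedness != "unstranded"

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.arrays.values()))

    def array(self, chrom: str, strand: str = ".") -> np.ndarray:
        key = (chrom, "." if not self.stranded else strand)
        try:
            return self.arrays[key]
        except KeyError:
            raise CoverageError(f"no coverage array for {key}") from None


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean depth per strand-aware genomic position."""

    value: float
    denominator: float


def _is_unique(read: "pysam.AlignedSegment", mapq_min: int) -> bool:
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= mapq_min


def fragment_strand(read: "pysam.AlignedSegment", strandedness: str) -> str:
    """Transcriptional strand of the fragment a read derives from.

    Under fr-firststrand (dUTP), mate 2 carries the transcript orientation;
    under fr-secondstrand, mate 1 does.  Single-end reads follow the mate-1
    convention of their protocol.
    """
    if strandedness == "unstranded":
        return "."
    read_strand = "-" if read.is_reverse else "+"
    mate2_like = read.is_paired and read.is_read2
    sense_like = mate2_like if strandedness == "fr-firststrand" else not mate2_like
    if sense_like:
        return read_strand
    return "-" if read_strand == "+" else "+"


def build_coverage_vector(
    alignment_path,
    strandedness: str = "fr-firststrand",
    mapq_min: int = 30,
) -> CoverageTrack:
    """Stream a SAM/BAM file into a per-strand coverage vector.

    Only primary, mapped, non-supplementary, uniquely mapped alignments
    contribute; every aligned base (CIGAR M/=/X) adds 1 on the fragment's
    transcriptional strand, while splice gaps (N) and deletions (D) add
    nothing.  Both mates of a pair contribute independently (overlapping
    mate bases count twice; the downstream filter compares ratios between
    regions, which are insensitive to a uniform doubling inside overlaps).
    """
    alignment_path = str(alignment_path)
    with pysam.AlignmentFile(alignment_path) as af:
        if not af.references:
            raise CoverageError(f"{alignment_path}: header carries no chrom lengths")
        sizes = dict(zip(af.references, af.lengths))
        track = CoverageTrack(sizes, strandedness)
        n_used = 0
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not _is_unique(read, mapq_min):
                continue
            chrom = read.reference_name
            if chrom not in sizes:
                raise CoverageError(f"alignment on unknown chromosome {chrom!r}")
            arr = track.arrays[(chrom, fragment_strand(read, strandedness))]
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in _ALIGNED_OPS:
                    arr[pos:pos + length] += 1.0
                    pos += length
                elif op in _REF_SKIP_OPS:
                    pos += length
            n_used += 1
    if n_used == 0:
        log.warning("%s: zero retained reads; background will be 0", alignment_path)
    return track


def background_value(total_signal: float, genome_size: float, stranded: bool) -> BackgroundEstimate:
    """The background-noise formula on explicit sizes.

    Mean depth per strand-aware position: total coverage divided by genome
    size, or by twice the genome size for stranded data (3 vs 6 billion
    nucleotides in the human case).
    """
    if genome_size == 0:
        raise CoverageError("genome size is zero")
    denominator = float(genome_size) * (2.0 if stranded else 1.0)
    return BackgroundEstimate(value=total_signal / denominator, denominator=denominator)


def compute_background(track: CoverageTrack) -> BackgroundEstimate:
    """Total signal divided by (strand-aware) genome size."""
    total = track.total_signal
    if total == 0.0:
        log.warning("coverage track is empty; background noise = 0")
    return background_value(total, track.genome_size, track.stranded)


def region_mean_coverage(
    track: CoverageTrack, chrom: str, start: int, end: int, strand: str = "."
) -> float:
    """Arithmetic mean depth over [start, end) on one strand."""
    if start >= end:
        raise CoverageError(f"empty interval [{start}, {end})")
    size = track.chrom_sizes.get(chrom)
    if size is None:
        raise CoverageError(f"unknown chromosome {chrom!r}")
    if start < 0 or end > size:
        raise CoverageError(
            f"interval [{start}, {end}) outside {chrom} (length {size}); clip first"
        )
    return float(track.array(chrom, strand)[start:end].mean())


def count_body_fragments(
    bam_path, chrom: str, start: int, end: int, strand: str,
    strandedness: str = "fr-firststrand", mapq_min: int = 30,
) -> int:
    """Unique fragments overlapping [start, end) in an indexed BAM.

    Optional expression estimate alongside the body mean depth; requires
    random access, so it is only available for indexed BAM input.
    """
    names = set()
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(chrom, start, end):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not _is_unique(read, mapq_min):
                continue
            if strandedness != "unstranded" and fragment_strand(read, strandedness) != strand:
                continue
            names.add(read.query_name)
    return len(names)


# ---------------------------------------------------------------------------
# Coverage track import/export (bedGraph and BigWig)

_STRAND_SUFFIX = {"+": ".plus", "-": ".minus", ".": ""}


def _iter_runs(arr: np.ndarray) -> Iterator[Tuple[int, int, float]]:
    """Yield (start, end, value) runs of constant non-zero value."""
    if arr.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    for start, end in zip(starts, ends):
        value = float(arr[start])
        if value != 0.0:
            yield int(start), int(end), value


def _fmt_value(value: float) -> str:
    return str(int(value)) if value == int(value) else repr(value)


def export_coverage(track: CoverageTrack, prefix, fmt: str = "bedgraph") -> List[str]:
    """Write the track to bedGraph or BigWig files plus a chrom-sizes file.

    Stranded tracks are written as two files with ``.plus`` / ``.minus``
    suffixes.  Returns the list of coverage file paths written.
    """
    if fmt not in ("bedgraph", "bigwig"):
        raise CoverageError(f"unknown coverage format {fmt!r}")
    prefix = str(prefix)
    chroms = list(track.chrom_sizes)
    paths = []
    for strand in track.strands:
        ext = ".bedgraph" if fmt == "bedgraph" else ".bw"
        path = prefix + _STRAND_SUFFIX[strand] + ext
        if fmt == "bedgraph":
            with open(path, "w") as out:
                for chrom in chroms:
                    for start, end, value in _iter_runs(track.arrays[(chrom, strand)]):
                        out.write(f"{chrom}\t{start}\t{end}\t{_fmt_value(value)}\n")
        else:
            import pyBigWig

            bw = pyBigWig.open(path, "w")
            bw.addHeader([(c, track.chrom_sizes[c]) for c in chroms])
            for chrom in chroms:
                runs = list(_iter_runs(track.arrays[(chrom, strand)]))
                if runs:
                    bw.addEntries(
                        [chrom] * len(runs),
                        [r[0] for r in runs],
                        ends=[r[1] for r in runs],
                        values=[r[2] for r in runs],
                    )
            bw.close()
        paths.append(path)
    with open(prefix + ".chrom.sizes", "w") as out:
        for chrom in chroms:
            out.write(f"{chrom}\t{track.chrom_sizes[chrom]}\n")
    return paths


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.split()
            if len(fields) >= 2:
                sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise CoverageError(f"{path}: no chromosome sizes")
    return sizes


def _load_into(track: CoverageTrack, strand: str, path: str) -> None:
    if path.endswith((".bw", ".bigwig")):
        import pyBigWig

        bw = pyBigWig.open(path)
        for chrom in track.chrom_sizes:
            if chrom not in bw.chroms():
                continue
            if bw.chroms(chrom) != track.chrom_sizes[chrom]:
                raise CoverageError(
                    f"{path}: size of {chrom} disagrees with chrom sizes"
                )
            intervals = bw.intervals(chrom) or ()
            arr = track.arrays[(chrom, strand)]
            for start, end, value in intervals:
                if value < 0:
                    raise CoverageError(f"{path}: negative coverage on {chrom}")
                arr[start:end] = value
        bw.close()
    else:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                fields = line.split()
                if not fields or fields[0].startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if value < 0:
                    raise CoverageError(f"{path} line {lineno}: negative coverage")
                size = track.chrom_sizes.get(chrom)
                if size is None or end > size:
                    raise CoverageError(
                        f"{path} line {lineno}: interval outside chrom sizes"
                    )
                track.arrays[(chrom, strand)][start:end] = value


def import_coverage(
    prefix, chrom_sizes: Optional[Dict[str, int]] = None,
    strandedness: str = "fr-firststrand",
) -> CoverageTrack:
    """Rebuild a CoverageTrack from files written by :func:`export_coverage`.

    ``prefix`` is the path prefix used at export time; stranded tracks
    require both the ``.plus`` and ``.minus`` files.  ``chrom_sizes`` falls
    back to the ``<prefix>.chrom.sizes`` companion file.
    """
    prefix = str(prefix)
    if chrom_sizes is None:
        sizes_path = Path(prefix + ".chrom.sizes")
        if not sizes_path.exists():
            raise CoverageError(f"chrom sizes required: {sizes_path} not found")
        chrom_sizes = read_chrom_sizes(sizes_path)
    track = CoverageTrack(chrom_sizes, strandedness)
    for strand in track.strands:
        candidates = [
            prefix + _STRAND_SUFFIX[strand] + ext
            for ext in (".bedgraph", ".bw", ".bigwig")
        ]
        found = [p for p in candidates if Path(p).exists()]
        if not found:
            name = {"+": "plus", "-": "minus", ".": "unstranded"}[strand]
            raise CoverageError(
                f"missing coverage file for the {name} strand (tried {candidates})"
            )
        _load_into(track, strand, found[0])
    return track
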