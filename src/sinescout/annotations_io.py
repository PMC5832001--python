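"""I/O for SINE annotations, consensus libraries, genome sequences and reports.

All coordinates are 0-based half-open inside the package.  GTF input
(1-based, inclusive) is converted on ingest; BED output is written natively
0-based.  Strandless annotations are excluded rather than defaulted, because
the flanking-region geometry is strand-dependent and a guessed strand would
silently corrupt verdicts.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

log = logging.getLogger(__name__)

REPORT_VERSION = "sinescout-report/1"

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_DNA_ALPHABET = set("ACGTN")


class AnnotationError(ValueError):
    """Raised for unusable annotation or sequence inputs."""


@dataclass(frozen=True)
class SineAnnotation:
    """One annotated repeat interval, 0-based half-open, stranded."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    subfamily: str
    source_line: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.locus_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.locus_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _family_from_subfamily(subfamily: str) -> str:
    """Heuristic family name when the GTF carries no family_id attribute."""
    up = subfamily.upper()
    if up.startswith("ALU"):
        return "Alu"
    if up.startswith("MIR"):
        return "MIR"
    return subfamily


def load_sine_annotations(gtf_path) -> List[SineAnnotation]:
    """Read SINE annotations from a 9-column GTF file.

    The locus identifier is taken from the ``gene_id`` attribute, with
    ``transcript_id`` as fallback.  Records with strand ``.`` are excluded
    with a warning; malformed lines are skipped with their line number
    logged; zero usable records is fatal.  The returned list is sorted by
    (chrom, start).
    """
    gtf_path = Path(gtf_path)
    annotations: List[SineAnnotation] = []
    seen_ids: set = set()
    with open(gtf_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                log.warning("%s line %d: fewer than 9 columns, skipped", gtf_path, lineno)
                continue
            chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                log.warning("%s line %d: non-integer coordinates, skipped", gtf_path, lineno)
                continue
            if strand not in ("+", "-"):
                log.warning(
                    "%s line %d: strand %r is not usable for a strand-dependent "
                    "filter; record excluded", gtf_path, lineno, strand,
                )
                continue
            attr_map = dict(_ATTR_RE.findall(attrs))
            locus_id = attr_map.get("gene_id") or attr_map.get("transcript_id")
            if not locus_id:
                log.warning("%s line %d: no gene_id/transcript_id, skipped", gtf_path, lineno)
                continue
            if locus_id in seen_ids:
                raise AnnotationError(
                    f"{gtf_path} line {lineno}: duplicate locus_id {locus_id!r}"
                )
            start0 = start1 - 1
            if not (0 <= start0 < end1):
                log.warning("%s line %d: empty/negative interval, skipped", gtf_path, lineno)
                continue
            subfamily = attr_map.get("subfamily") or locus_id
            family = attr_map.get("family_id") or _family_from_subfamily(subfamily)
            seen_ids.add(locus_id)
            annotations.append(
                SineAnnotation(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start0,
                    end=end1,
                    strand=strand,
                    family=family,
                    subfamily=subfamily,
                    source_line=lineno,
                )
            )
    if not annotations:
        raise AnnotationError(f"{gtf_path}: no usable annotation records")
    annotations.sort(key=lambda a: (a.chrom, a.start, a.end, a.locus_id))
    return annotations


class ConsensusLibrary:
    """Family/subfamily consensus sequences with subfamily→family fallback.

    Resolution order for an annotation: exact subfamily key, exact family
    key, then the longest library key that is a prefix of the subfamily or
    family name (so ``AluYa5`` resolves to an ``Alu`` entry).
    """

    def __init__(self, entries: Dict[str, str]):
        clean: Dict[str, str] = {}
        for name, seq in entries.items():
            seq = seq.upper()
            if not seq:
                raise AnnotationError(f"consensus {name!r}: empty sequence")
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise AnnotationError(
                    f"consensus {name!r}: non-DNA characters {sorted(bad)}"
                )
            clean[name] = seq
        self.entries = clean

    @classmethod
    def from_fasta(cls, fasta_path) -> "ConsensusLibrary":
        entries: Dict[str, str] = {}
        for record in SeqIO.parse(str(fasta_path), "fasta"):
            if record.id in entries:
                raise AnnotationError(f"{fasta_path}: duplicate header {record.id!r}")
            entries[record.id] = str(record.seq)
        if not entries:
            raise AnnotationError(f"{fasta_path}: empty consensus FASTA")
        return cls(entries)

    def resolve(self, subfamily: str, family: str = "") -> Optional[Tuple[str, str]]:
        """Return (library key, sequence) for a subfamily/family, or None."""
        for name in (subfamily, family):
            if name and name in self.entries:
                return name, self.entries[name]
        best = ""
        for key in self.entries:
            for name in (subfamily, family):
                if name and name.startswith(key) and len(key) > len(best):
                    best = key
        if best:
            return best, self.entries[best]
        return None


class GenomeSequence:
    """In-memory genome: chrom → uppercase DNA string."""

    def __init__(self, seqs: Dict[str, str]):
        self.seqs = {chrom: seq.upper() for chrom, seq in seqs.items()}

    @classmethod
    def from_fasta(cls, fasta_path) -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        if not seqs:
            raise AnnotationError(f"{fasta_path}: empty genome FASTA")
        return cls(seqs)

    @property
    def lengths(self) -> Dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]


# ---------------------------------------------------------------------------
# Report writers

REPORT_COLUMNS = [
    "locus_id", "chrom", "start", "end", "strand", "subfamily", "family",
    "verdict", "over_background", "flank_pass", "fail_reasons",
    "background", "body_start", "body_end", "body_fallback", "clipped",
    "body_cov", "left_cov", "right_cov", "out_cov", "expression",
    "terminator_found", "terminator_offset",
]


def _fmt(value) -> str:
    if value is None:
        return "-"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_locus_report(calls: Sequence, tsv_path, bed_path=None) -> None:
    """Write the per-locus TSV report and a BED6 of PASS loci.

    The BED uses the inferred central-body interval; the score column is the
    body mean coverage rounded and capped to [0, 1000].
    """
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as tsv:
        tsv.write(f"# {REPORT_VERSION}\n")
        tsv.write("\t".join(REPORT_COLUMNS) + "\n")
        for call in calls:
            tsv.write("\t".join(_fmt(v) for v in call.report_row()) + "\n")
    if bed_path is None:
        return
    with open(bed_path, "w") as bed:
        for call in calls:
            if call.verdict != "PASS":
                continue
            body = call.body
            score = int(min(1000, max(0, round(call.coverages.body))))
            bed.write(
                f"{body.chrom}\t{body.start}\t{body.end}\t"
                f"{call.annotation.locus_id}\t{score}\t{body.strand}\n"
            )
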