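"""Synthetic benchmark: genomes, SINE layouts, read alignments and metrics.

The generator emulates the benchmark conditions of the pipeline's published
evaluation: a genome carrying (a) intergenic, autonomously expressed Pol III
SINE loci whose transcripts run from the element 5' end to a poly(dT)
planted downstream of the body, (b) passenger SINEs embedded in expressed
host transcripts, (c) silent SINE copies, and (d) truncated SINE fragments,
with host introns expressed at low level to provide the background noise
signal.  Stranded 76-nt paired-end read alignments are written directly as
SAM (alignment coordinates are known by construction, so no aligner is in
the loop), together with a ground-truth table and a precision/recall
evaluator.

Every planted SINE copy is substitution-mutated (default 5%/base) so that
loci are distinguishable, standing in for the genomic divergence that makes
real SINE loci uniquely mappable; a configurable fraction of decoy
multimapper pairs (NH=2) is added and must be ignored downstream.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .annotations_io import SineAnnotation
from .body_mapping import revcomp

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Benchmark design parameters.

    Counts and the read model follow the published benchmark design (331
    genuine Pol III SINEs, 76-nt stranded paired-end reads); expression
    levels are expressed as folds over ``background_unit``, the nominal
    per-base depth scale of the simulation.  The realized background (total
    signal / strand-aware genome size) emerges from the whole layout and is
    typically below one background_unit.
    """

    seed: int = 42
    n_chroms: int = 4
    chrom_len: int = 5_000_000
    n_true_pol3: int = 331
    n_passenger: int = 300
    n_silent: int = 300
    n_fragment: int = 100
    n_hosts: int = 100
    host_span: Tuple[int, int] = (20_000, 40_000)
    host_exon_fraction: float = 0.3
    host_exons: Tuple[int, int] = (4, 8)
    background_unit: float = 10.0
    pol3_fold_median: float = 8.0
    pol3_fold_sigma: float = 1.0
    host_fold_range: Tuple[float, float] = (5.0, 50.0)
    intron_fold_range: Tuple[float, float] = (0.5, 2.0)
    sub_rate: float = 0.05
    terminator_offset_range: Tuple[int, int] = (20, 180)
    terminator_run_range: Tuple[int, int] = (4, 6)
    fragment_trunc_range: Tuple[float, float] = (0.3, 0.7)
    passenger_segments: Tuple[str, ...] = ("exon", "intron")
    read_len: int = 76
    fragment_len_mean: float = 180.0
    fragment_len_sd: float = 40.0
    decoy_multimapper_frac: float = 0.05
    strandedness: str = "fr-firststrand"
    placement_margin: int = 1500
    passenger_margin: int = 600

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory for reproducibility")
        if self.read_len < 20:
            raise SimulationError("read_len must be >= 20")
        for name in ("n_true_pol3", "n_passenger", "n_silent", "n_fragment"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Transcript:
    """An expressed unit: genomic exon blocks at a target mean depth."""

    name: str
    chrom: str
    strand: str
    blocks: Tuple[Tuple[int, int], ...]
    depth: float

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class TruthRecord:
    locus_id: str
    label: str  # pol3_true | passenger | silent | fragment
    chrom: str
    start: int
    end: int
    strand: str
    fold: float
    terminator_offset: Optional[int]


@dataclass
class SyntheticDataset:
    config: SimConfig
    consensus: Dict[str, str]
    genome: Dict[str, str]
    annotations: List[SineAnnotation]
    truth: List[TruthRecord]
    transcripts: List[Transcript]

    def write(self, out_dir) -> Dict[str, str]:
        """Write genome.fa, sines.gtf, consensus.fa and truth.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(out_dir / "genome.fa"),
            "gtf": str(out_dir / "sines.gtf"),
            "consensus": str(out_dir / "consensus.fa"),
            "truth": str(out_dir / "truth.tsv"),
        }
        with open(paths["genome"], "w") as fa:
            for chrom, seq in self.genome.items():
                fa.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fa.write(seq[i:i + 80] + "\n")
        with open(paths["consensus"], "w") as fa:
            for name, seq in self.consensus.items():
                fa.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fa.write(seq[i:i + 80] + "\n")
        with open(paths["gtf"], "w") as gtf:
            for ann in self.annotations:
                attrs = (
                    f'gene_id "{ann.locus_id}"; transcript_id "{ann.locus_id}"; '
                    f'family_id "{ann.family}"; subfamily "{ann.subfamily}";'
                )
                gtf.write(
                    f"{ann.chrom}\tsinesim\texon\t{ann.start + 1}\t{ann.end}\t.\t"
                    f"{ann.strand}\t.\t{attrs}\n"
                )
        write_truth_table(self.truth, paths["truth"])
        return paths


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as out:
        out.write("locus_id\tclass\tchrom\tstart\tend\tstrand\tfold\tterminator_offset\n")
        for rec in truth:
            term = rec.terminator_offset if rec.terminator_offset is not None else "-"
            out.write(
                f"{rec.locus_id}\t{rec.label}\t{rec.chrom}\t{rec.start}\t{rec.end}\t"
                f"{rec.strand}\t{rec.fold:.6g}\t{term}\n"
            )


def read_truth_table(path) -> List[TruthRecord]:
    records: List[TruthRecord] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("locus_id"):
            raise SimulationError(f"{path}: not a truth table")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    locus_id=f[0], label=f[1], chrom=f[2],
                    start=int(f[3]), end=int(f[4]), strand=f[5],
                    fold=float(f[6]),
                    terminator_offset=None if f[7] == "-" else int(f[7]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Sequence helpers

def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[_random_codes(rng, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    mask = rng.random(codes.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
    return _BASES[codes].tobytes().decode()


def _break_runs(seq: str, base: str, max_run: int, replacement: str) -> str:
    """Cap homopolymer runs of ``base`` at ``max_run`` by substitution."""
    out = list(seq)
    run = 0
    for i, ch in enumerate(out):
        if ch == base:
            run += 1
            if run > max_run:
                out[i] = replacement
                run = 0
        else:
            run = 0
    return "".join(out)


def _build_consensus(rng: np.random.Generator) -> Dict[str, str]:
    """Alu-like 300-nt dimer with A-rich linker; MIR-like 260-nt element.

    Internal Pol III promoter boxes are planted in the left monomer / tRNA
    head for structural plausibility; they are not used by the pipeline.
    """
    a_box = "TGGCTCACGCCTGTAAT"
    b_box = "GTTCGAGAC"
    left = _random_seq(rng, 130)
    left = left[:6] + a_box + left[6 + len(a_box):70] + b_box + left[70 + len(b_box):]
    linker = "AAAAATACAAAAAA"
    right = _random_seq(rng, 144)
    tail = "A" * 12
    alu = (left + linker + right + tail)[:300]
    head = _random_seq(rng, 70)
    head = head[:5] + a_box + head[5 + len(a_box):50] + b_box + head[50 + len(b_box):]
    core = _random_seq(rng, 15)
    line3 = _random_seq(rng, 175)
    mir = (head + core + line3)[:260]
    # no internal sense-strand terminator: Pol III must read through the body
    return {
        "AluSyn": _break_runs(alu, "T", 3, "G"),
        "MIRSyn": _break_runs(mir, "T", 3, "G"),
    }


# ---------------------------------------------------------------------------
# Dataset construction

@dataclass
class _Segment:
    chrom: str
    start: int
    end: int
    depth: float
    strand: str
    kind: str  # exon | intron
    occupied: IntervalTree = field(default_factory=IntervalTree)


def _place(
    rng: np.random.Generator,
    trees: Dict[str, IntervalTree],
    chroms: List[str],
    chrom_len: int,
    span: int,
    margin: int,
    tries: int = 500,
) -> Tuple[str, int]:
    for _ in range(tries):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = chrom_len - span - margin
        if limit <= margin:
            continue
        pos = int(rng.integers(margin, limit))
        if not trees[chrom].overlap(pos - margin, pos + span + margin):
            trees[chrom].addi(pos, pos + span)
            return chrom, pos
    raise SimulationError(
        f"could not place a feature of span {span} after {tries} tries; "
        "enlarge chrom_len or reduce feature counts"
    )


def make_synthetic_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a deterministic genome + annotation + truth + transcript layout."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    consensus = _build_consensus(rng)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_codes = {c: _random_codes(rng, cfg.chrom_len) for c in chroms}
    genome_ba = {c: bytearray(_BASES[codes].tobytes()) for c, codes in genome_codes.items()}
    del genome_codes
    trees = {c: IntervalTree() for c in chroms}
    b0 = cfg.background_unit

    annotations: List[SineAnnotation] = []
    truth: List[TruthRecord] = []
    transcripts: List[Transcript] = []
    segments: List[_Segment] = []

    # --- host Pol II genes: expressed exons, low-level introns -------------
    for h in range(cfg.n_hosts):
        n_ex = int(rng.integers(cfg.host_exons[0], cfg.host_exons[1] + 1))
        span_target = int(rng.integers(cfg.host_span[0], cfg.host_span[1]))
        exon_total = int(span_target * cfg.host_exon_fraction)
        ew = rng.uniform(0.5, 1.5, n_ex)
        exon_lens = np.maximum((ew / ew.sum() * exon_total).astype(int), 200)
        intron_total = span_target - int(exon_lens.sum())
        n_int = max(n_ex - 1, 1)
        iw = rng.uniform(0.5, 1.5, n_int)
        intron_lens = np.maximum((iw / iw.sum() * intron_total).astype(int), 400)
        span = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        exon_depth = float(rng.uniform(*cfg.host_fold_range) * b0)
        intron_depths = rng.uniform(*cfg.intron_fold_range, size=n_int) * b0
        chrom, pos = _place(rng, trees, chroms, cfg.chrom_len, span, cfg.placement_margin)
        cursor = pos
        exon_blocks: List[Tuple[int, int]] = []
        for k in range(n_ex):
            e_start, e_end = cursor, cursor + int(exon_lens[k])
            exon_blocks.append((e_start, e_end))
            segments.append(_Segment(chrom, e_start, e_end, exon_depth, strand, "exon"))
            cursor = e_end
            if k < n_ex - 1:
                i_start, i_end = cursor, cursor + int(intron_lens[k])
                depth_i = float(intron_depths[k])
                segments.append(_Segment(chrom, i_start, i_end, depth_i, strand, "intron"))
                transcripts.append(
                    Transcript(f"host{h}_intron{k}", chrom, strand, ((i_start, i_end),), depth_i)
                )
                cursor = i_end
        transcripts.append(
            Transcript(f"host{h}_mRNA", chrom, strand, tuple(exon_blocks), exon_depth)
        )

    families = list(consensus)

    def planted_copy(rng) -> Tuple[str, str, str]:
        name = families[int(rng.integers(0, len(families)))]
        fam = "Alu" if name.startswith("Alu") else "MIR"
        return name, fam, consensus[name]

    # --- genuine Pol III loci: intergenic, terminator planted downstream ---
    for i in range(cfg.n_true_pol3):
        sub, fam, cons = planted_copy(rng)
        body = _mutate(rng, cons, cfg.sub_rate)
        blen = len(body)
        offset = int(rng.integers(cfg.terminator_offset_range[0],
                                  cfg.terminator_offset_range[1] + 1))
        run = int(rng.integers(cfg.terminator_run_range[0],
                               cfg.terminator_run_range[1] + 1))
        fold = float(rng.lognormal(math.log(cfg.pol3_fold_median), cfg.pol3_fold_sigma))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        span = blen + offset + run
        chrom, pos = _place(rng, trees, chroms, cfg.chrom_len, span, cfg.placement_margin)
        ba = genome_ba[chrom]
        if strand == "+":
            bs, be = pos, pos + blen
            ba[bs:be] = body.encode()
            tail = _break_runs(ba[be:be + offset].decode(), "T", 3, "G")
            ba[be:be + offset] = tail.encode()
            ba[be + offset:be + offset + run] = b"T" * run
            if offset > 0:
                ba[be + offset - 1:be + offset] = b"C"
            ba[be + offset + run:be + offset + run + 1] = b"C"
            tx_blocks = ((bs, be + offset + run),)
        else:
            bs, be = pos + offset + run, pos + offset + run + blen
            ba[bs:be] = revcomp(body).encode()
            tail = _break_runs(ba[bs - offset:bs].decode(), "A", 3, "G")
            ba[bs - offset:bs] = tail.encode()
            ba[bs - offset - run:bs - offset] = b"A" * run
            if offset > 0:
                ba[bs - offset:bs - offset + 1] = b"C"
            ba[bs - offset - run - 1:bs - offset - run] = b"C"
            tx_blocks = ((bs - offset - run, be),)
        locus_id = f"pol3_{i:04d}"
        annotations.append(
            SineAnnotation(locus_id, chrom, bs, be, strand, fam, sub)
        )
        truth.append(
            TruthRecord(locus_id, "pol3_true", chrom, bs, be, strand, fold, offset)
        )
        transcripts.append(Transcript(locus_id, chrom, strand, tx_blocks, fold * b0))

    # --- silent full-length copies ----------------------------------------
    for i in range(cfg.n_silent):
        sub, fam, cons = planted_copy(rng)
        body = _mutate(rng, cons, cfg.sub_rate)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        chrom, pos = _place(rng, trees, chroms, cfg.chrom_len, len(body), cfg.placement_margin)
        seq = body if strand == "+" else revcomp(body)
        genome_ba[chrom][pos:pos + len(body)] = seq.encode()
        locus_id = f"silent_{i:04d}"
        annotations.append(
            SineAnnotation(locus_id, chrom, pos, pos + len(body), strand, fam, sub)
        )
        truth.append(
            TruthRecord(locus_id, "silent", chrom, pos, pos + len(body), strand, 0.0, None)
        )

    # --- truncated fragments ----------------------------------------------
    for i in range(cfg.n_fragment):
        sub, fam, cons = planted_copy(rng)
        frac = float(rng.uniform(*cfg.fragment_trunc_range))
        keep = max(30, int(len(cons) * frac))
        if rng.integers(0, 2) == 0:
            kept = cons[len(cons) - keep:]  # 5'-truncated: 3' portion remains
        else:
            kept = cons[:keep]  # 3'-truncated: 5' portion remains
        body = _mutate(rng, kept, cfg.sub_rate)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        chrom, pos = _place(rng, trees, chroms, cfg.chrom_len, len(body), cfg.placement_margin)
        seq = body if strand == "+" else revcomp(body)
        genome_ba[chrom][pos:pos + len(body)] = seq.encode()
        locus_id = f"frag_{i:04d}"
        annotations.append(
            SineAnnotation(locus_id, chrom, pos, pos + len(body), strand, fam, sub)
        )
        truth.append(
            TruthRecord(locus_id, "fragment", chrom, pos, pos + len(body), strand, 0.0, None)
        )

    # --- passenger SINEs inside expressed host segments --------------------
    margin = cfg.passenger_margin
    body_len_max = max(len(s) for s in consensus.values())
    candidates = [
        s for s in segments
        if s.kind in cfg.passenger_segments
        and (s.end - s.start) >= body_len_max + 2 * margin
    ]
    if cfg.n_passenger > 0 and not candidates:
        raise SimulationError("no host segment is large enough for a passenger SINE")
    for i in range(cfg.n_passenger):
        sub, fam, cons = planted_copy(rng)
        body = _mutate(rng, cons, cfg.sub_rate)
        blen = len(body)
        placed = False
        for _ in range(300):
            seg = candidates[int(rng.integers(0, len(candidates)))]
            lo, hi = seg.start + margin, seg.end - margin - blen
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if seg.occupied.overlap(pos - margin, pos + blen + margin):
                continue
            seg.occupied.addi(pos, pos + blen)
            placed = True
            break
        if not placed:
            raise SimulationError(
                "could not place a passenger SINE; enlarge hosts or reduce n_passenger"
            )
        strand = seg.strand  # sense passenger of the host transcript
        seq = body if strand == "+" else revcomp(body)
        genome_ba[seg.chrom][pos:pos + blen] = seq.encode()
        locus_id = f"passenger_{i:04d}"
        annotations.append(
            SineAnnotation(locus_id, seg.chrom, pos, pos + blen, strand, fam, sub)
        )
        truth.append(
            TruthRecord(
                locus_id, "passenger", seg.chrom, pos, pos + blen, strand,
                seg.depth / b0, None,
            )
        )

    annotations.sort(key=lambda a: (a.chrom, a.start, a.end, a.locus_id))
    truth.sort(key=lambda r: (r.chrom, r.start, r.locus_id))
    genome = {c: ba.decode() for c, ba in genome_ba.items()}
    log.info(
        "synthetic dataset: %d chroms x %d nt, %d annotations, %d transcripts",
        cfg.n_chroms, cfg.chrom_len, len(annotations), len(transcripts),
    )
    return SyntheticDataset(
        config=cfg, consensus=consensus, genome=genome,
        annotations=annotations, truth=truth, transcripts=transcripts,
    )


# ---------------------------------------------------------------------------
# Read simulator

def _transcript_blocks(tx: Transcript) -> List[Tuple[int, int, int, int]]:
    """(t_start, t_end, g_start, g_end) blocks in transcript order."""
    blocks = list(tx.blocks) if tx.strand == "+" else list(reversed(tx.blocks))
    out = []
    t = 0
    for gs, ge in blocks:
        length = ge - gs
        out.append((t, t + length, gs, ge))
        t += length
    return out


def _project(tblocks, strand: str, a: int, b: int) -> List[Tuple[int, int]]:
    """Project transcript window [a, b) to ascending genomic blocks."""
    out = []
    for t0, t1, gs, ge in tblocks:
        lo, hi = max(a, t0), min(b, t1)
        if lo < hi:
            if strand == "+":
                out.append((gs + (lo - t0), gs + (hi - t0)))
            else:
                out.append((ge - (hi - t0), ge - (lo - t0)))
    out.sort()
    return out


def _cigar(blocks: List[Tuple[int, int]]) -> str:
    parts = []
    prev_end = None
    for gs, ge in blocks:
        if prev_end is not None and gs > prev_end:
            parts.append(f"{gs - prev_end}N")
        parts.append(f"{ge - gs}M")
        prev_end = ge
    return "".join(parts)


def simulate_read_alignments(
    dataset: SyntheticDataset, out_sam, seed: Optional[int] = None
) -> Dict[str, int]:
    """Sample stranded paired-end fragments and write a coordinate-sorted SAM.

    Per expressed transcript of depth d and length L, Poisson(d*L/(2*read_len))
    fragments are placed uniformly; each pair contributes exactly
    2*read_len aligned bases, so the expected pileup mean equals d.  Mates
    carry proper flags, spliced CIGARs across host introns, and NH:i:1;
    decoy multimapper pairs carry NH:i:2 and low MAPQ and are generated from
    an independent random stream so that toggling them never perturbs the
    genuine fragments.
    """
    cfg = dataset.config
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 9001])
    rl = cfg.read_len
    read2_sense = cfg.strandedness != "fr-secondstrand"
    chroms = list(dataset.genome)
    records: Dict[str, List[Tuple[int, str]]] = {c: [] for c in chroms}
    n_pairs = 0

    def emit_pair(qname, chrom, strand, blocks_a, blocks_b, mapq, nh):
        genome_seq = dataset.genome[chrom]
        rows = []
        pos_a, pos_b = blocks_a[0][0], blocks_b[0][0]
        end_a, end_b = blocks_a[-1][1], blocks_b[-1][1]
        span_start = min(pos_a, pos_b)
        span_end = max(end_a, end_b)
        for which, blocks in (("A", blocks_a), ("B", blocks_b)):
            sense = which == "A"
            reverse = (strand == "-") if sense else (strand == "+")
            is_read2 = read2_sense == sense
            flag = 0x1 | 0x2 | (0x10 if reverse else 0) | (0x20 if not reverse else 0)
            flag |= 0x80 if is_read2 else 0x40
            pos = blocks[0][0]
            pnext = blocks_b[0][0] if which == "A" else blocks_a[0][0]
            tlen = span_end - span_start
            if pos > pnext or (pos == pnext and which == "B"):
                tlen = -tlen
            seq = "".join(genome_seq[gs:ge] for gs, ge in blocks)
            rows.append(
                (
                    pos,
                    f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{_cigar(blocks)}\t="
                    f"\t{pnext + 1}\t{tlen}\t{seq}\t{'I' * len(seq)}\tNH:i:{nh}",
                )
            )
        records[chrom].extend(rows)

    for tx in dataset.transcripts:
        L = tx.length
        if L < rl:
            continue
        n = int(rng.poisson(tx.depth * L / (2.0 * rl)))
        if n == 0:
            continue
        flens = np.rint(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, n))
        flens = np.clip(flens, rl, L).astype(np.int64)
        starts = np.floor(rng.random(n) * (L - flens + 1)).astype(np.int64)
        tblocks = _transcript_blocks(tx)
        for k in range(n):
            s, fl = int(starts[k]), int(flens[k])
            blocks_5p = _project(tblocks, tx.strand, s, s + rl)
            blocks_3p = _project(tblocks, tx.strand, s + fl - rl, s + fl)
            qname = f"sim_{tx.name}_{k}"
            emit_pair(qname, tx.chrom, tx.strand, blocks_5p, blocks_3p, 60, 1)
            n_pairs += 1

    rng_decoy = np.random.default_rng([base_seed, 9002])
    n_decoys = int(round(cfg.decoy_multimapper_frac * n_pairs))
    for k in range(n_decoys):
        chrom = chroms[int(rng_decoy.integers(0, len(chroms)))]
        clen = len(dataset.genome[chrom])
        fl = int(np.clip(round(rng_decoy.normal(cfg.fragment_len_mean, cfg.fragment_len_sd)),
                         rl, min(2 * rl + 200, clen)))
        pos = int(rng_decoy.integers(0, clen - fl))
        strand = "+" if rng_decoy.integers(0, 2) == 0 else "-"
        blocks_a = [(pos, pos + rl)] if strand == "+" else [(pos + fl - rl, pos + fl)]
        blocks_b = [(pos + fl - rl, pos + fl)] if strand == "+" else [(pos, pos + rl)]
        emit_pair(f"decoy_{k}", chrom, strand, blocks_a, blocks_b, 3, 2)

    out_sam = Path(out_sam)
    with open(out_sam, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in chroms:
            sam.write(f"@SQ\tSN:{chrom}\tLN:{len(dataset.genome[chrom])}\n")
        sam.write("@PG\tID:sinesim\tPN:sinesim\n")
        for chrom in chroms:
            rows = records[chrom]
            rows.sort()
            for _pos, line in rows:
                sam.write(line + "\n")
    stats = {
        "n_pairs": n_pairs,
        "n_decoy_pairs": n_decoys,
        "aligned_bases": 2 * rl * n_pairs,
    }
    log.info("simulated %d read pairs (+%d decoy pairs) -> %s",
             n_pairs, n_decoys, out_sam)
    return stats


# ---------------------------------------------------------------------------
# Precision/recall evaluation

@dataclass(frozen=True)
class Metrics:
    found: int
    true_positive: int
    false_positive: int
    false_negative: int
    precision: Optional[float]
    recall: float

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "true_positive": self.true_positive,
            "false_positive": self.false_positive,
            "false_negative": self.false_negative,
            "precision": self.precision,
            "recall": self.recall,
        }


def evaluate_ids(called_ids: Sequence[str], truth: Sequence[TruthRecord]) -> Metrics:
    """Score a set of called locus ids against the truth table."""
    pol3 = {r.locus_id for r in truth if r.label == "pol3_true"}
    called = set(called_ids)
    tp = len(called & pol3)
    fp = len(called) - tp
    fn = len(pol3 - called)
    found = tp + fp
    return Metrics(
        found=found,
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        precision=(tp / found) if found else None,
        recall=(tp / len(pol3)) if pol3 else 0.0,
    )


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate(pass_bed, truth_table) -> Metrics:
    """Score a PASS BED file against a truth table.

    Calls are matched by locus_id (BED name column); a call whose id is not
    in the truth table falls back to >= 50% reciprocal overlap with a truth
    interval, and counts as a false positive (with a warning) if nothing
    matches.
    """
    truth = (
        truth_table
        if isinstance(truth_table, (list, tuple))
        else read_truth_table(truth_table)
    )
    by_id = {r.locus_id: r for r in truth}
    by_chrom: Dict[str, List[TruthRecord]] = {}
    for rec in truth:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    called_ids: List[str] = []
    with open(pass_bed) as bed:
        for line in bed:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name in by_id:
                called_ids.append(name)
                continue
            hit = None
            for rec in by_chrom.get(chrom, ()):
                if _reciprocal_overlap((start, end), (rec.start, rec.end)) >= 0.5:
                    hit = rec
                    break
            if hit is not None:
                called_ids.append(hit.locus_id)
            else:
                log.warning("call %s matches no truth locus; counted false positive", name)
                called_ids.append(f"__unmatched__{name}")
    return evaluate_ids(called_ids, truth)
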