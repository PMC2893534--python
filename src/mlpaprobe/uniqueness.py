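"""Sequence uniqueness and variation testing against a local genome.

The uniqueness test requires each hybridizing half to occur exactly once in
the genome, and the two halves to be adjacent and in consistent orientation
at one locus — a probe whose halves hit multiple loci would report the sum
of copy numbers of all of them. Matching is exact full-length (seed k-mer
lookup, then verification against the genome string, both strands);
mismatch-tolerant homology search is a documented non-goal.

The variation test drops candidates whose hybridizing footprint overlaps a
known variant: a polymorphism under a half-probe can abolish ligation in
some samples and mimic a copy-number change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .seq_core import ProbeCandidate, VariantInterval, read_genome, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_K = 15


@dataclass(frozen=True)
class Hit:
    """Exact occurrence of a sequence in the genome (forward coordinates)."""

    chrom: str
    pos: int  # 0-based start on the forward strand
    strand: str  # '+' or '-'


@dataclass
class GenomeIndex:
    """k-mer seed index of a genome FASTA; lookups cover both strands."""

    genome_id: str
    k: int
    seqs: dict[str, str]
    seed_table: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


@dataclass
class VariantOverlap:
    """A variant intersecting a candidate footprint, with local placement."""

    variant: VariantInterval
    hybrid_start: int  # offset within LHS+RHS (clipped to the footprint)
    hybrid_end: int
    half: str  # "LHS", "RHS" or "LHS/RHS" when spanning the nick


@dataclass
class UniquenessReport:
    lhs_hits: int
    rhs_hits: int
    unique: bool
    locus: tuple[str, int, str] | None = None  # (chrom, hybrid start, strand)
    variant_overlaps: list[VariantOverlap] = field(default_factory=list)


def build_index(genome: str | Path | dict[str, str], k: int = DEFAULT_K) -> GenomeIndex:
    """Index every k-mer of the genome (forward positions; both strands are
    covered at lookup time via the reverse complement). N-containing k-mers
    are skipped. Deterministic for a given FASTA."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if isinstance(genome, (str, Path)):
        genome_id = str(genome)
        seqs = read_genome(genome)
    else:
        genome_id = "in-memory"
        seqs = {c: s.upper() for c, s in genome.items()}
    table: dict[str, list[tuple[str, int]]] = {}
    indexed = 0
    for chrom, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append((chrom, i))
            indexed += 1
    if indexed == 0:
        log.warning("no k-mers indexed (k=%d longer than every sequence?)", k)
    return GenomeIndex(genome_id=genome_id, k=k, seqs=seqs, seed_table=table)


def count_occurrences(idx: GenomeIndex, seq: str) -> list[Hit]:
    """All exact full-length occurrences of ``seq`` on either strand,
    seed-and-verify. Requires len(seq) >= k."""
    if len(seq) < idx.k:
        raise ValueError(f"query shorter than seed length k={idx.k}")
    hits = []
    for chrom, pos in idx.seed_table.get(seq[: idx.k], []):
        if idx.seqs[chrom][pos : pos + len(seq)] == seq:
            hits.append(Hit(chrom, pos, "+"))
    rc = reverse_complement(seq)
    for chrom, pos in idx.seed_table.get(rc[: idx.k], []):
        if idx.seqs[chrom][pos : pos + len(rc)] == rc:
            hits.append(Hit(chrom, pos, "-"))
    return sorted(hits, key=lambda h: (h.chrom, h.pos, h.strand))


def uniqueness_test(cand: ProbeCandidate, idx: GenomeIndex) -> UniquenessReport:
    """Unique iff each half occurs exactly once and the two single hits are
    colinear (adjacent, same strand, LHS upstream of RHS in probe sense)."""
    lhs_hits = count_occurrences(idx, cand.lhs)
    rhs_hits = count_occurrences(idx, cand.rhs)
    report = UniquenessReport(
        lhs_hits=len(lhs_hits), rhs_hits=len(rhs_hits), unique=False
    )
    if len(lhs_hits) == 1 and len(rhs_hits) == 1:
        hl, hr = lhs_hits[0], rhs_hits[0]
        if hl.chrom == hr.chrom and hl.strand == hr.strand:
            if hl.strand == "+" and hr.pos == hl.pos + len(cand.lhs):
                report.unique = True
                report.locus = (hl.chrom, hl.pos, "+")
            elif hl.strand == "-" and hl.pos == hr.pos + len(cand.rhs):
                # reverse strand: genome holds revcomp(RHS) then revcomp(LHS)
                report.unique = True
                report.locus = (hr.chrom, hr.pos, "-")
    return report


def variation_test(
    cand: ProbeCandidate,
    variants: list[VariantInterval],
    locus: tuple[str, int, str],
) -> list[VariantOverlap]:
    """All variant intervals intersecting the hybridizing footprint.

    ``locus`` is the (chrom, genomic start, strand) placement from the
    uniqueness test. Intervals are half-open; a variant ending exactly at
    the footprint start (or starting at its end) does not overlap. Offsets
    are reported in hybrid coordinates (0 = outer 5' end of the LHS).
    """
    if locus is None:
        raise ValueError("variation_test requires a uniquely placed candidate")
    chrom, start, strand = locus
    length = len(cand.lhs) + len(cand.rhs)
    end = start + length
    out = []
    for v in variants:
        if v.chrom != chrom or v.end <= start or v.start >= end:
            continue
        g_lo, g_hi = max(v.start, start), min(v.end, end)
        if strand == "+":
            h_lo, h_hi = g_lo - start, g_hi - start
        else:
            h_lo, h_hi = end - g_hi, end - g_lo
        nick = len(cand.lhs)
        if h_hi <= nick:
            half = "LHS"
        elif h_lo >= nick:
            half = "RHS"
        else:
            half = "LHS/RHS"
        out.append(VariantOverlap(variant=v, hybrid_start=h_lo, hybrid_end=h_hi, half=half))
    return sorted(out, key=lambda o: o.hybrid_start)
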