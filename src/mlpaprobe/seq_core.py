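"""Sequence primitives, FASTA/VCF/BED input, candidate enumeration, fixtures.

An MLPA probe set consists of two half-probes that hybridize side by side on
a target: the left hybridizing sequence (LHS) and the right hybridizing
sequence (RHS), meeting at the ligation site (the nick sealed by ligase).
This module cuts every admissible (LHS, RHS) pair out of a target sequence
and handles the plain-text formats the rest of the pipeline consumes.

Coordinates are 0-based half-open internally; VCF input (1-based) is
converted on read, and report writers print 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_DNA = set("ACGTN")
_IUPAC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


@dataclass(frozen=True)
class TargetRecord:
    """One input target sequence (uppercase DNA over A/C/G/T/N)."""

    id: str
    sequence: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"target {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"target {self.id!r}: non-ACGTN characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProbeCandidate:
    """An (LHS, RHS) pair cut from a target.

    ``ligation_pos`` is the 0-based offset of the first RHS base within the
    target, i.e. the nick sits between ``ligation_pos - 1`` and
    ``ligation_pos``.
    """

    target_id: str
    ligation_pos: int
    lhs: str
    rhs: str

    def __post_init__(self) -> None:
        if not self.lhs or not self.rhs:
            raise ValueError("lhs and rhs must be non-empty")
        if "N" in self.lhs or "N" in self.rhs:
            raise ValueError("hybridizing sequences may not contain N")

    @property
    def hybrid(self) -> str:
        """The contiguous probe-target hybrid LHS+RHS."""
        return self.lhs + self.rhs

    @property
    def start(self) -> int:
        """0-based start of the hybrid footprint within the target."""
        return self.ligation_pos - len(self.lhs)


@dataclass(frozen=True)
class VariantInterval:
    """A known variant as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    kind: str = "SNP"  # SNP | indel | other

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("variant interval must satisfy start < end")
        if self.kind == "SNP" and self.end - self.start != 1:
            raise ValueError("SNP intervals must have length 1")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC degeneracy support."""
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[TargetRecord]:
    """Read target sequences from a FASTA file.

    Sequences are uppercased and U is mapped to T. IUPAC ambiguity codes
    other than N are rejected with the offending record named; downstream
    candidate windows skip N.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-ACGTN "
                f"characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(TargetRecord(id=rec.id, sequence=seq, source=str(path)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a {name: sequence} dict (uppercased)."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def read_variants(path: str | Path) -> list[VariantInterval]:
    """Read variant intervals from VCF (via cyvcf2) or 3-column BED.

    VCF records are classified: single-base REF with all single-base ALTs
    is a SNP; length-changing alleles are indels; everything else "other".
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                start, end = int(start), int(end)
                kind = "SNP" if end - start == 1 else "other"
                out.append(VariantInterval(chrom, start, end, kind))
        return out
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        alts = v.ALT or []
        if len(v.REF) == 1 and alts and all(len(a) == 1 for a in alts):
            kind = "SNP"
        elif any(len(a) != len(v.REF) for a in alts):
            kind = "indel"
        else:
            kind = "other"
        out.append(VariantInterval(v.CHROM, v.start, v.start + len(v.REF), kind))
    return out


def enumerate_candidates(
    target: TargetRecord,
    lhs_len_range: tuple[int, int],
    rhs_len_range: tuple[int, int],
) -> list[ProbeCandidate]:
    """Enumerate every (ligation position, LHS length, RHS length) combination.

    Windows must fit inside the target and contain no N. Order is
    deterministic: ascending ligation position, then LHS length, then RHS
    length — fixed so that ranking ties are reproducible.
    """
    a_min, a_max = lhs_len_range
    b_min, b_max = rhs_len_range
    if a_min <= 0 or b_min <= 0 or a_min > a_max or b_min > b_max:
        raise ValueError("length ranges must be positive and ordered")
    seq = target.sequence
    if len(seq) < a_min + b_min:
        log.warning(
            "target %s shorter than minimum hybrid length %d; no candidates",
            target.id, a_min + b_min,
        )
        return []
    # next_n[i] = index of the first N at or after i (len(seq) if none)
    next_n = [len(seq)] * (len(seq) + 1)
    for i in range(len(seq) - 1, -1, -1):
        next_n[i] = i if seq[i] == "N" else next_n[i + 1]
    out = []
    for lig in range(a_min, len(seq) - b_min + 1):
        for a in range(a_min, min(a_max, lig) + 1):
            if next_n[lig - a] < lig:
                continue
            for b in range(b_min, min(b_max, len(seq) - lig) + 1):
                if next_n[lig] < lig + b:
                    continue
                out.append(
                    ProbeCandidate(
                        target_id=target.id,
                        ligation_pos=lig,
                        lhs=seq[lig - a : lig],
                        rhs=seq[lig : lig + b],
                    )
                )
    return out


def random_dna(rng: random.Random, length: int, cpg_free: bool = False) -> str:
    """Uniform random DNA; with ``cpg_free`` no CG dinucleotide is emitted."""
    bases = "ACGT"
    out = []
    for _ in range(length):
        choices = bases
        if cpg_free and out and out[-1] == "C":
            choices = "ACT"
        out.append(rng.choice(choices))
    return "".join(out)


@dataclass
class FixtureSet:
    """Paths and ground truth produced by :func:`make_fixtures`."""

    targets_fasta: Path
    genome_fasta: Path
    variants_vcf: Path
    target_loci: dict[str, int] = field(default_factory=dict)
    variant_positions: list[int] = field(default_factory=list)


def make_fixtures(
    seed: int,
    n_targets: int,
    genome_len: int,
    n_variants: int,
    out_dir: str | Path,
    target_len: int = 120,
) -> FixtureSet:
    """Write a toy genome, targets cut from it, and a VCF of planted SNPs.

    Targets are exact substrings of the toy genome so uniqueness tests have
    known answers; variant positions are recorded in the returned object.
    Output is byte-identical for identical arguments.
    """
    if n_variants > genome_len:
        raise ValueError("n_variants exceeds genome length")
    if genome_len < target_len:
        raise ValueError("genome shorter than target length")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = random_dna(rng, genome_len)
    loci = {}
    targets = []
    for i in range(n_targets):
        start = rng.randrange(0, genome_len - target_len + 1)
        tid = f"target_{i + 1}"
        loci[tid] = start
        targets.append((tid, genome[start : start + target_len]))
    positions = sorted(rng.sample(range(genome_len), n_variants))

    targets_fa = out_dir / "targets.fa"
    with open(targets_fa, "w") as fh:
        for tid, seq in targets:
            fh.write(f">{tid}\n{seq}\n")
    genome_fa = out_dir / "genome.fa"
    with open(genome_fa, "w") as fh:
        fh.write(f">toy_chr1\n")
        for i in range(0, genome_len, 70):
            fh.write(genome[i : i + 70] + "\n")
    vcf = out_dir / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=toy_chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos in positions:
            ref = genome[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fh.write(f"toy_chr1\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    return FixtureSet(
        targets_fasta=targets_fa,
        genome_fasta=genome_fa,
        variants_vcf=vcf,
        target_loci=loci,
        variant_positions=positions,
    )


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write (header, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
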