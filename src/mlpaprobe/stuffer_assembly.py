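"""Oligo assembly, stuffer generation/verification, amplicon planning.

The left probe oligo (LPO) is the universal left PCR primer followed by the
LHS; the right probe oligo (RPO) is the RHS, an optional stuffer (or bead
tag), and the binding site for the right PCR primer. In electrophoresis
mode every probe in a multiplex must yield a distinct amplicon length, so
stuffers of graded lengths are inserted; in bead-coupled mode an address
tag replaces the stuffer.

Stuffers must not interfere with the assay. A stuffer record is verified
against four criteria, each applied to the stuffer+primer union sequences:
(1) free of secondary structure (hairpin ΔG above a floor); (2) no
significant homology to any supplied target genome (operationalized as no
exact k-mer match — stricter than an alignment-based cutoff, and safe);
(3) no recognition site for any methylation-sensitive enzyme in the table;
(4) no cross-interaction (heterodimer ΔG above a floor) with any peer
stuffer's unions. The packaged generator rejection-samples CpG-free,
GC-balanced sequences until all four criteria pass, so a verified set can
be reproduced from its seed; externally sourced stuffers can be imported
from TSV and re-verified with the same code.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .msmlpa import RestrictionEnzyme, find_sites
from .seq_core import ProbeCandidate, random_dna
from .thermo import ThermoConfig, dimer_dg, gc_fraction, hairpin_dg
from .uniqueness import GenomeIndex

# Universal MLPA PCR primer pair used by the commercial MRC-Holland kits;
# config-supplied default, overridable per run.
DEFAULT_PRIMERS = (
    "GGGTTCCCTAAGGGTTGGA",  # left primer, 5' end of the LPO
    "TCTAGATTGGATCTTGCTGGCAC",  # right-primer binding site, 3' end of the RPO
)

DEFAULT_HAIRPIN_FLOOR = -3.0  # kcal/mol, criterion 1
DEFAULT_CROSS_FLOOR = -8.0  # kcal/mol, criterion 4


@dataclass(frozen=True)
class PrimerPair:
    left_primer: str = DEFAULT_PRIMERS[0]
    right_primer_binding: str = DEFAULT_PRIMERS[1]

    def __post_init__(self) -> None:
        if not self.left_primer or not self.right_primer_binding:
            raise ValueError("both primer sequences must be non-empty")


@dataclass
class CriterionResult:
    passed: bool
    metric: float | None = None
    detail: str = ""


@dataclass
class StufferRecord:
    id: str
    sequence: str
    verification: dict[int, CriterionResult] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def verified(self) -> bool:
        return bool(self.verification) and all(
            c.passed for c in self.verification.values()
        )


@dataclass
class ProbeOligos:
    """Assembled LPO/RPO with recoverable segment boundaries."""

    lpo: str
    rpo: str
    segments: dict[str, str]  # left_primer, lhs, rhs, insert, right_primer_binding
    junction_base: str  # target base immediately after the left primer

    @property
    def amplicon_len(self) -> int:
        return len(self.lpo) + len(self.rpo)


def assemble_oligos(
    cand: ProbeCandidate,
    primers: PrimerPair = PrimerPair(),
    stuffer: StufferRecord | None = None,
    mode: str = "electrophoresis",
    tag: str | None = None,
) -> ProbeOligos:
    """Build LPO = left_primer + LHS and RPO = RHS + insert + right binding.

    Electrophoresis mode inserts the stuffer (None gives the shortest
    amplicon); bead mode requires an address tag. The junction base (first
    LHS base, i.e. the target base immediately following the left primer)
    is recorded for the adenosine score adjustment.
    """
    if mode == "electrophoresis":
        insert = stuffer.sequence if stuffer is not None else ""
    elif mode == "bead":
        if tag is None:
            raise ValueError("bead mode requires a tag sequence")
        insert = tag
    else:
        raise ValueError(f"unknown mode {mode!r}")
    segments = {
        "left_primer": primers.left_primer,
        "lhs": cand.lhs,
        "rhs": cand.rhs,
        "insert": insert,
        "right_primer_binding": primers.right_primer_binding,
    }
    return ProbeOligos(
        lpo=primers.left_primer + cand.lhs,
        rpo=cand.rhs + insert + primers.right_primer_binding,
        segments=segments,
        junction_base=cand.lhs[0],
    )


def _unions(stuffer_seq: str, primers: PrimerPair) -> list[str]:
    return [
        primers.left_primer + stuffer_seq,
        stuffer_seq + primers.right_primer_binding,
    ]


def verify_stuffer(
    stuffer: StufferRecord,
    primers: PrimerPair,
    genomes: list[GenomeIndex],
    enzymes: list[RestrictionEnzyme],
    peers: list[StufferRecord],
    thermo_cfg: ThermoConfig = ThermoConfig(),
    hairpin_floor: float = DEFAULT_HAIRPIN_FLOOR,
    cross_floor: float = DEFAULT_CROSS_FLOOR,
) -> dict[int, CriterionResult]:
    """Run the four stuffer criteria; results are stored on the record.

    With no genomes supplied, criterion 2 is reported as passed with the
    detail "not evaluated". Failures are results, never exceptions.
    """
    unions = _unions(stuffer.sequence, primers)
    report: dict[int, CriterionResult] = {}

    dgs = [hairpin_dg(u, thermo_cfg) for u in unions]
    worst = min((d for d in dgs if d is not None), default=None)
    report[1] = CriterionResult(
        passed=worst is None or worst >= hairpin_floor,
        metric=worst,
        detail="hairpin ΔG of primer+stuffer unions",
    )

    if not genomes:
        report[2] = CriterionResult(passed=True, metric=None, detail="not evaluated")
    else:
        hit_detail = ""
        n_hits = 0
        for idx in genomes:
            for u in unions:
                for i in range(len(u) - idx.k + 1):
                    kmer = u[i : i + idx.k]
                    from .seq_core import reverse_complement

                    if kmer in idx.seed_table or reverse_complement(kmer) in idx.seed_table:
                        n_hits += 1
                        hit_detail = f"k-mer match at union offset {i} ({idx.genome_id})"
        report[2] = CriterionResult(
            passed=n_hits == 0, metric=float(n_hits), detail=hit_detail or "no genome k-mer match"
        )

    bad_enzymes = sorted(
        {
            e.name
            for e in enzymes
            if e.methylation_sensitive
            for u in unions
            if find_sites(u, e)
        }
    )
    report[3] = CriterionResult(
        passed=not bad_enzymes,
        metric=float(len(bad_enzymes)),
        detail=", ".join(bad_enzymes) if bad_enzymes else "no restriction site",
    )

    worst_cross = None
    worst_peer = ""
    for peer in peers:
        if peer.id == stuffer.id:
            continue
        for u in unions:
            for pu in _unions(peer.sequence, primers):
                dg = dimer_dg(u, pu, thermo_cfg)
                if dg is not None and (worst_cross is None or dg < worst_cross):
                    worst_cross = dg
                    worst_peer = peer.id
    report[4] = CriterionResult(
        passed=worst_cross is None or worst_cross >= cross_floor,
        metric=worst_cross,
        detail=f"worst cross-dimer vs {worst_peer}" if worst_peer else "no peers",
    )

    stuffer.verification = report
    return report


class StufferGenerationError(RuntimeError):
    pass


def generate_stuffer_set(
    seed: int,
    lengths: list[int],
    primers: PrimerPair = PrimerPair(),
    genomes: list[GenomeIndex] | None = None,
    enzymes: list[RestrictionEnzyme] | None = None,
    thermo_cfg: ThermoConfig = ThermoConfig(),
    hairpin_floor: float = DEFAULT_HAIRPIN_FLOOR,
    cross_floor: float = DEFAULT_CROSS_FLOOR,
    max_attempts: int = 5000,
) -> list[StufferRecord]:
    """Rejection-sample a verified stuffer set, deterministic for a seed.

    Candidates are CpG-free (no methylation-sensitive site can form inside
    them) with GC fraction in [0.4, 0.6], and each must verify against all
    previously accepted members before joining the set.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("stuffer lengths must be positive")
    from .msmlpa import load_enzyme_table

    genomes = genomes or []
    enzymes = enzymes if enzymes is not None else load_enzyme_table()
    rng = random.Random(seed)
    accepted: list[StufferRecord] = []
    for n, length in enumerate(lengths, start=1):
        fail_counts = {1: 0, 2: 0, 3: 0, 4: 0}
        for attempt in range(max_attempts):
            seq = random_dna(rng, length, cpg_free=True)
            if not (0.4 <= gc_fraction(seq) <= 0.6):
                continue
            rec = StufferRecord(id=f"stuffer_{n:02d}_len{length}", sequence=seq)
            report = verify_stuffer(
                rec, primers, genomes, enzymes, accepted, thermo_cfg,
                hairpin_floor, cross_floor,
            )
            if all(c.passed for c in report.values()):
                accepted.append(rec)
                break
            for k, c in report.items():
                if not c.passed:
                    fail_counts[k] += 1
        else:
            raise StufferGenerationError(
                f"no admissible stuffer of length {length} in {max_attempts} "
                f"attempts; failures per criterion: {fail_counts}"
            )
    return accepted


def plan_amplicon_lengths(
    n_probes: int,
    min_len: int,
    max_len: int,
    spacing: int,
    fixed_len: int = 0,
) -> list[tuple[int, int]]:
    """Evenly spaced target amplicon lengths and required stuffer lengths.

    Returns (amplicon length, stuffer length) per probe, where stuffer
    length = amplicon − ``fixed_len`` (primers + hybridizing sequences).
    """
    if n_probes < 1 or spacing < 1:
        raise ValueError("need n_probes >= 1 and spacing >= 1")
    if min_len + (n_probes - 1) * spacing > max_len:
        raise ValueError(
            f"cannot fit {n_probes} amplicons spaced {spacing} nt in "
            f"[{min_len}, {max_len}]"
        )
    plan = []
    for i in range(n_probes):
        amp = min_len + i * spacing
        stuffer_len = amp - fixed_len
        if stuffer_len < 0:
            raise ValueError(
                f"amplicon {amp} nt shorter than fixed parts ({fixed_len} nt)"
            )
        plan.append((amp, stuffer_len))
    return plan
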