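"""End-to-end probe design: enumerate → screen → score → uniqueness →
variation → rank → assemble, with an optional MS-MLPA filter view.

The workflow is two processes: (1) the physical-chemical property test of
hybridizing sequences and oligos with composite scoring, and (2) the
sequence uniqueness and variation test against a local genome. Candidates
with a final score of 0 never reach process 2. For MS-MLPA a third,
restriction-enzyme filtering process is applied on top of the genomic
result, as a filtered view that preserves the score order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .msmlpa import RestrictionEnzyme, apply_ms_view, get_enzyme, load_enzyme_table
from .screening import ScoreBreakdown, ScreenConfig, physchem_test, score_candidate
from .seq_core import (
    ProbeCandidate,
    TargetRecord,
    enumerate_candidates,
    read_fasta,
    read_variants,
)
from .stuffer_assembly import PrimerPair, ProbeOligos, StufferRecord, assemble_oligos
from .thermo import ThermoConfig
from .uniqueness import (
    GenomeIndex,
    VariantOverlap,
    build_index,
    uniqueness_test,
    variation_test,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "electrophoresis"
    genome: str | Path | None = None
    variants: str | Path | None = None
    enzyme: str | None = None  # enables the MS-MLPA view
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    primers: PrimerPair = field(default_factory=PrimerPair)
    seed: int = 1
    k: int = 15
    output_dir: Path | None = None


@dataclass
class ProbeSetResult:
    """One designed probe set: candidate, score, oligos, test outcomes."""

    candidate: ProbeCandidate
    breakdown: ScoreBreakdown
    oligos: ProbeOligos
    locus: tuple[str, int, str] | None = None
    variant_overlaps: list[VariantOverlap] = field(default_factory=list)
    ms_verdict: object | None = None


@dataclass
class FailedCandidate:
    """A rejected candidate with the workflow step at which it failed."""

    candidate: ProbeCandidate
    step: str  # physchem | score | uniqueness | variation
    reasons: list[str] = field(default_factory=list)


@dataclass
class TargetResult:
    target: TargetRecord
    ranked: list[ProbeSetResult] = field(default_factory=list)
    ms_view: list[ProbeSetResult] | None = None
    failed: list[FailedCandidate] = field(default_factory=list)


def design_target(
    target: TargetRecord,
    run: RunConfig,
    index: GenomeIndex | None,
    variants,
    enzyme: RestrictionEnzyme | None,
    stuffers: list[StufferRecord] | None = None,
) -> TargetResult:
    """Design probe sets for one target; see module docstring for stages."""
    result = TargetResult(target=target)
    cands = enumerate_candidates(
        target, run.screen.lhs_len_range, run.screen.rhs_len_range
    )
    log.info("%s: %d candidate windows", target.id, len(cands))

    scored = []
    for cand in cands:
        ok, reasons = physchem_test(cand, run.screen, run.thermo)
        if not ok:
            result.failed.append(FailedCandidate(cand, "physchem", reasons))
            continue
        b = score_candidate(cand, run.screen, run.thermo)
        if b.final == 0:
            result.failed.append(
                FailedCandidate(cand, "score", ["final score 0"])
            )
            continue
        scored.append((cand, b))
    log.info("%s: %d candidates passed physical-chemical screening",
             target.id, len(scored))

    survivors = []
    for cand, b in scored:
        locus = None
        overlaps: list[VariantOverlap] = []
        if index is not None:
            rep = uniqueness_test(cand, index)
            if not rep.unique:
                result.failed.append(
                    FailedCandidate(
                        cand, "uniqueness",
                        [f"LHS hits={rep.lhs_hits}, RHS hits={rep.rhs_hits}"],
                    )
                )
                continue
            locus = rep.locus
            if variants:
                overlaps = variation_test(cand, variants, locus)
                if enzyme is None and overlaps:
                    result.failed.append(
                        FailedCandidate(
                            cand, "variation",
                            [f"{len(overlaps)} variant(s) in footprint"],
                        )
                    )
                    continue
        survivors.append((cand, b, locus, overlaps))

    from .screening import rank_candidates

    order = rank_candidates([(c, b) for c, b, _, _ in survivors])
    by_id = {id(c): (locus, ov) for c, _, locus, ov in survivors}
    stuffer_iter = iter(stuffers or [])
    for cand, b in order:
        locus, overlaps = by_id[id(cand)]
        stuffer = next(stuffer_iter, None) if run.mode == "electrophoresis" else None
        oligos = assemble_oligos(cand, run.primers, stuffer, mode="electrophoresis")
        result.ranked.append(
            ProbeSetResult(
                candidate=cand, breakdown=b, oligos=oligos,
                locus=locus, variant_overlaps=overlaps,
            )
        )

    if enzyme is not None:
        result.ms_view = apply_ms_view(result.ranked, enzyme)
        log.info("%s: %d of %d probe sets pass the MS-MLPA filter",
                 target.id, len(result.ms_view), len(result.ranked))
    return result


def design(run: RunConfig, targets: str | Path | list[TargetRecord]) -> list[TargetResult]:
    """Design probe sets for all targets under one configuration."""
    if isinstance(targets, (str, Path)):
        targets = read_fasta(targets)
    index = build_index(run.genome, k=run.k) if run.genome is not None else None
    variants = read_variants(run.variants) if run.variants is not None else []
    enzyme = None
    if run.enzyme is not None:
        enzyme = get_enzyme(run.enzyme, load_enzyme_table())
    results = []
    for target in targets:
        res = design_target(target, run, index, variants, enzyme)
        if not res.ranked:
            log.warning("%s: no probe set passed all tests", target.id)
        results.append(res)
    return results


def verify_probes(
    rows: list[dict],
    thermo_cfg: ThermoConfig = ThermoConfig(),
) -> list[dict]:
    """Standalone physical-chemical verification of user-supplied probes.

    Each row supplies either an LHS/RHS pair or an LPO/RPO pair (keys are
    case-insensitive). Reports Tm, GC, hairpin ΔG, self-dimer ΔG per
    sequence and the cross-dimer ΔG of the pair. Deliberately performs no
    uniqueness or variation testing — manually designed probes (e.g. for
    SNP genotyping, where the variant sits at the 3' end of the LPO) target
    loci where those tests do not apply. Malformed rows are reported
    row-level; remaining rows are still processed.
    """
    from .thermo import dimer_dg, gc_fraction, hairpin_dg, melting_temperature

    out = []
    for i, row in enumerate(rows):
        lowered = {k.lower(): v for k, v in row.items()}
        pair = None
        for a, b in (("lhs", "rhs"), ("lpo", "rpo")):
            if lowered.get(a) and lowered.get(b):
                pair = (a, b)
                break
        rec: dict = {"row": i + 1, "id": lowered.get("id", f"probe_{i + 1}")}
        if pair is None:
            rec["error"] = "row must provide lhs+rhs or lpo+rpo columns"
            out.append(rec)
            continue
        try:
            seqs = {name: str(lowered[name]).upper() for name in pair}
            for name, seq in seqs.items():
                rec[f"tm_{name}"] = melting_temperature(seq, thermo_cfg)
                rec[f"gc_{name}"] = gc_fraction(seq)
                rec[f"dg_hairpin_{name}"] = hairpin_dg(seq, thermo_cfg)
                rec[f"dg_self_dimer_{name}"] = dimer_dg(seq, seq, thermo_cfg)
            a, b = pair
            rec["dg_cross_dimer"] = dimer_dg(seqs[a], seqs[b], thermo_cfg)
        except ValueError as exc:
            rec["error"] = str(exc)
        out.append(rec)
    return out
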