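"""Physical-chemical screening and the composite probe-set score.

A candidate passes screening when both halves clear the user-specified
minimum Tm, sit inside the GC window, and neither assembled oligo folds or
self-dimerizes below the configured ΔG floors. Surviving candidates get a
composite score in [0, 1] built from four sub-scores (Tm, ΔG, GC content,
ligation site), with 1 the best. Probes in which the target base
immediately following the left PCR primer is an adenosine amplify with
2-3-fold lower signal, so their final score is multiplied by 0.5 — they are
down-weighted, never rejected. Candidates with final score 0 are excluded
from downstream (uniqueness/variation) testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .seq_core import ProbeCandidate
from .thermo import ThermoConfig, dimer_dg, gc_fraction, hairpin_dg, melting_temperature

DEFAULT_LIG_TABLE = {"G": 1.0, "A": 1.0, "T": 0.75, "C": 0.5}


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds and score-map shape.

    tm_min is the user-specified minimum hybridizing-sequence Tm; the Tm
    sub-score rises linearly from 0 at tm_min to 1 at tm_opt and stays at 1
    above it unless tm_max is set (then it descends to 0 at tm_max). The GC
    sub-score is a tent peaking at the midpoint of [gc_min, gc_max]. ΔG
    floors are kcal/mol, more negative = more stable structure = worse.
    """

    tm_min: float = 55.0
    tm_opt: float | None = None  # default tm_min + 5
    tm_max: float | None = None  # None = no upper Tm penalty
    gc_min: float = 0.35
    gc_max: float = 0.65
    dg_hairpin_floor: float = -3.0
    dg_dimer_floor: float = -8.0
    lhs_len_range: tuple[int, int] = (21, 30)
    rhs_len_range: tuple[int, int] = (21, 30)
    platform: str = "electrophoresis"  # electrophoresis | bead
    composite: str = "product"  # product | min | mean
    lig_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIG_TABLE)
    )

    def __post_init__(self) -> None:
        if self.resolved_tm_opt < self.tm_min:
            raise ValueError("tm_opt must be >= tm_min")
        if self.tm_max is not None and self.tm_max < self.resolved_tm_opt:
            raise ValueError("tm_max must be >= tm_opt")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.dg_hairpin_floor > 0 or self.dg_dimer_floor > 0:
            raise ValueError("ΔG floors must be <= 0")
        if self.platform not in ("electrophoresis", "bead"):
            raise ValueError("platform must be electrophoresis or bead")
        if self.composite not in ("product", "min", "mean"):
            raise ValueError("composite must be product, min or mean")

    @property
    def resolved_tm_opt(self) -> float:
        return self.tm_min + 5.0 if self.tm_opt is None else self.tm_opt

    @property
    def gc_opt(self) -> float:
        return 0.5 * (self.gc_min + self.gc_max)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lhs_len_range", "rhs_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScoreBreakdown:
    """Per-criterion sub-scores in [0, 1] plus the composite final score."""

    s_tm: float
    s_dg: float
    s_gc: float
    s_lig: float
    adenosine_adjusted: bool = False
    composite: float = 0.0  # unadjusted composite of the four sub-scores
    final: float = 0.0
    metrics: dict = field(default_factory=dict)


def _tent(x: float, lo: float, peak: float, hi: float | None) -> float:
    """Piecewise-linear map: 0 at lo, 1 at peak, 0 at hi (1 beyond if hi None)."""
    if x <= lo:
        return 0.0
    if x <= peak or peak == lo:
        return min(1.0, (x - lo) / (peak - lo)) if peak > lo else 1.0
    if hi is None:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - peak)


def _dg_score(dg: float | None, floor: float) -> float:
    """1 at ΔG = 0 (or no structure), linearly down to 0 at the floor."""
    if dg is None or dg >= 0:
        return 1.0
    if dg <= floor:
        return 0.0
    return 1.0 - dg / floor


def physchem_test(
    cand: ProbeCandidate,
    cfg: ScreenConfig,
    thermo_cfg: ThermoConfig = ThermoConfig(),
    lpo: str | None = None,
    rpo: str | None = None,
) -> tuple[bool, list[str]]:
    """Hard pass/fail physical-chemical test with named failure reasons.

    Structure (hairpin/self-dimer) floors are checked on the assembled
    oligos when ``lpo``/``rpo`` are given, otherwise on the bare halves.
    Failure is a result, not an error.
    """
    reasons = []
    halves = {"LHS": cand.lhs, "RHS": cand.rhs}
    for name, seq in halves.items():
        if melting_temperature(seq, thermo_cfg) < cfg.tm_min:
            reasons.append(f"Tm({name}) below minimum {cfg.tm_min:g} °C")
        gc = gc_fraction(seq)
        if not (cfg.gc_min <= gc <= cfg.gc_max):
            reasons.append(
                f"GC({name}) = {gc:.2f} outside [{cfg.gc_min:g}, {cfg.gc_max:g}]"
            )
    oligos = {"LPO": lpo, "RPO": rpo} if (lpo or rpo) else halves
    for name, seq in oligos.items():
        if seq is None:
            continue
        dg_h = hairpin_dg(seq, thermo_cfg)
        if dg_h is not None and dg_h < cfg.dg_hairpin_floor:
            reasons.append(f"hairpin({name}) ΔG {dg_h:.2f} below floor")
        dg_s = dimer_dg(seq, seq, thermo_cfg)
        if dg_s is not None and dg_s < cfg.dg_dimer_floor:
            reasons.append(f"self-dimer({name}) ΔG {dg_s:.2f} below floor")
    return (not reasons, reasons)


def component_scores(
    cand: ProbeCandidate,
    cfg: ScreenConfig,
    thermo_cfg: ThermoConfig = ThermoConfig(),
) -> ScoreBreakdown:
    """Sub-scores for a candidate that passed :func:`physchem_test`.

    Each half is mapped through the Tm and GC tents and the worse (lower)
    half governs; the ΔG sub-score takes the worst structure over hairpins
    and self-dimers of both halves; the ligation-site sub-score looks up
    the 5' base of the RHS (the base 3' of the nick).
    """
    ok, reasons = physchem_test(cand, cfg, thermo_cfg)
    if not ok:
        raise ValueError(f"component_scores on failed candidate: {reasons}")
    tm_l = melting_temperature(cand.lhs, thermo_cfg)
    tm_r = melting_temperature(cand.rhs, thermo_cfg)
    gc_l, gc_r = gc_fraction(cand.lhs), gc_fraction(cand.rhs)
    s_tm = min(
        _tent(tm_l, cfg.tm_min, cfg.resolved_tm_opt, cfg.tm_max),
        _tent(tm_r, cfg.tm_min, cfg.resolved_tm_opt, cfg.tm_max),
    )
    s_gc = min(
        _tent(gc_l, cfg.gc_min, cfg.gc_opt, cfg.gc_max),
        _tent(gc_r, cfg.gc_min, cfg.gc_opt, cfg.gc_max),
    )
    dg_scores = []
    for seq in (cand.lhs, cand.rhs):
        dg_scores.append(_dg_score(hairpin_dg(seq, thermo_cfg), cfg.dg_hairpin_floor))
        dg_scores.append(_dg_score(dimer_dg(seq, seq, thermo_cfg), cfg.dg_dimer_floor))
    s_dg = min(dg_scores)
    s_lig = cfg.lig_table.get(cand.rhs[0], 0.5)
    return ScoreBreakdown(
        s_tm=s_tm,
        s_dg=s_dg,
        s_gc=s_gc,
        s_lig=s_lig,
        metrics={
            "tm_lhs": tm_l,
            "tm_rhs": tm_r,
            "gc_lhs": gc_l,
            "gc_rhs": gc_r,
        },
    )


def final_score(
    b: ScoreBreakdown,
    lpo_junction_base: str,
    composite: str = "product",
) -> float:
    """Fill in the composite and the adenosine-adjusted final score.

    ``lpo_junction_base`` is the target-derived base immediately following
    the left PCR primer in the LPO (the first base of the LHS). If it is A
    the final score is halved; adenosine never rejects a probe set on its
    own. A zero final score excludes the candidate from further tests.
    """
    subs = (b.s_tm, b.s_dg, b.s_gc, b.s_lig)
    for s in subs:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"sub-score {s} outside [0, 1]")
    if composite == "product":
        comp = subs[0] * subs[1] * subs[2] * subs[3]
    elif composite == "min":
        comp = min(subs)
    elif composite == "mean":
        comp = sum(subs) / 4.0
    else:
        raise ValueError(f"unknown composite rule {composite!r}")
    b.composite = comp
    b.adenosine_adjusted = lpo_junction_base == "A"
    b.final = 0.5 * comp if b.adenosine_adjusted else comp
    return b.final


def score_candidate(
    cand: ProbeCandidate,
    cfg: ScreenConfig,
    thermo_cfg: ThermoConfig = ThermoConfig(),
) -> ScoreBreakdown:
    """Convenience: component scores + final score in one call."""
    b = component_scores(cand, cfg, thermo_cfg)
    final_score(b, cand.lhs[0], cfg.composite)
    return b


def rank_candidates(
    scored: list[tuple[ProbeCandidate, ScoreBreakdown]],
) -> list[tuple[ProbeCandidate, ScoreBreakdown]]:
    """Descending final score; ties by ascending ligation position, then
    ascending total hybrid length. Stable and deterministic."""
    return sorted(
        scored,
        key=lambda cb: (
            -cb[1].final,
            cb[0].ligation_pos,
            len(cb[0].lhs) + len(cb[0].rhs),
        ),
    )
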