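"""Physical-chemical calculators for probe oligos.

Nearest-neighbor (NN) melting temperature, GC fraction, and free-energy
heuristics for hairpins and oligo-oligo dimers. The NN parameter set is the
unified DNA/DNA table shipped as ``data/nn_params.tsv`` so alternates can be
swapped in; the monovalent-salt correction is logarithmic
(16.6 * log10[Na+]).

The hairpin model is deliberately restricted to perfect ungapped stems
(>= 3 bp) closing loops of >= 3 nt: it under-predicts structures with
internal loops or bulges, but every prediction is checkable by exhaustive
enumeration at desk scale. Dimers are scored as the best ungapped
complementary alignment between the two strands in antiparallel register,
including duplex initiation terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

_R = 1.987  # gas constant, cal/(mol*K)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _load_nn() -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
    pairs: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    text = resources.files("mlpaprobe.data").joinpath("nn_params.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pair\t"):
            continue
        key, dh, ds = line.split("\t")
        if key.startswith("init_"):
            init[key] = (float(dh), float(ds))
        else:
            pairs[key] = (float(dh), float(ds))
    return pairs, init


def _load_loops() -> list[tuple[int, float]]:
    text = resources.files("mlpaprobe.data").joinpath("hairpin_loops.tsv").read_text()
    table = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("size\t"):
            continue
        size, dg = line.split("\t")
        table.append((int(size), float(dg)))
    return sorted(table)


NN_PAIRS, NN_INIT = _load_nn()
LOOP_TABLE = _load_loops()


@dataclass(frozen=True)
class ThermoConfig:
    """Solution conditions for Tm and ΔG evaluation.

    na_conc: monovalent cation concentration (molar), default 0.05 M.
    oligo_conc: total strand concentration (molar), default 2.5e-7 M.
    temperature: °C at which ΔG values are evaluated, default 37 °C.
    """

    na_conc: float = 0.05
    oligo_conc: float = 2.5e-7
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.na_conc <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= -273.15:
            raise ValueError("temperature below absolute zero")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class ThermoResult:
    """Bundle of Tm and structure ΔG metrics for one oligo."""

    tm: float
    dg_hairpin: float | None
    dg_self_dimer: float | None
    dg_cross_dimer: float | None = None


def _check_acgt(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters {sorted(bad)}")


def gc_fraction(seq: str) -> float:
    """(G + C) / length, in [0, 1]."""
    _check_acgt(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def _nn_sums(seq: str) -> tuple[float, float]:
    """Total ΔH (kcal/mol) and ΔS (cal/mol·K) of a duplex of seq, with init."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        idh, ids = NN_INIT[key]
        dh += idh
        ds += ids
    for i in range(len(seq) - 1):
        pdh, pds = NN_PAIRS[seq[i : i + 2]]
        dh += pdh
        ds += pds
    return dh, ds


def melting_temperature(seq: str, cfg: ThermoConfig = ThermoConfig()) -> float:
    """Nearest-neighbor duplex Tm in °C.

    Tm = 1000·ΔH / (ΔS + R·ln(CT/4)) − 273.15 + 16.6·log10[Na+],
    with ΔH/ΔS summed over NN stacks plus initiation terms. Sequences
    shorter than 8 nt are refused (the NN model is unreliable there).
    """
    _check_acgt(seq)
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt: NN Tm unreliable")
    dh, ds = _nn_sums(seq)
    tm_1m = (dh * 1000.0) / (ds + _R * math.log(cfg.oligo_conc / 4.0)) - 273.15
    return tm_1m + 16.6 * math.log10(cfg.na_conc)


def stack_dg(dinuc: str, cfg: ThermoConfig = ThermoConfig()) -> float:
    """ΔG of one NN stack at the configured temperature (kcal/mol)."""
    dh, ds = NN_PAIRS[dinuc]
    return dh - cfg.kelvin * ds / 1000.0


def _init_dg(base: str, cfg: ThermoConfig) -> float:
    key = "init_A/T" if base in "AT" else "init_G/C"
    dh, ds = NN_INIT[key]
    return dh - cfg.kelvin * ds / 1000.0


def loop_penalty(size: int) -> float:
    """Hairpin loop initiation ΔG37 (kcal/mol) for a loop of ``size`` nt."""
    if size < 3:
        raise ValueError("hairpin loops smaller than 3 nt are disallowed")
    table = LOOP_TABLE
    for (s0, g0), (s1, g1) in zip(table, table[1:]):
        if s0 <= size <= s1:
            if size == s0:
                return g0
            return g0 + (g1 - g0) * (size - s0) / (s1 - s0)
    s_max, g_max = table[-1]
    return g_max + 1.75 * (_R / 1000.0) * 310.15 * math.log(size / s_max)


MIN_STEM = 3
MIN_LOOP = 3


def hairpin_dg(seq: str, cfg: ThermoConfig = ThermoConfig()) -> float | None:
    """Most stable (minimum) hairpin ΔG, or None if nothing stable exists.

    Scans every perfect ungapped stem of >= MIN_STEM base pairs closing a
    loop of >= MIN_LOOP nt; ΔG = sum of stem stack terms + loop penalty.
    Returns None when no configuration reaches ΔG < 0.
    """
    _check_acgt(seq)
    n = len(seq)
    best: float | None = None
    for i in range(n):
        for j in range(i + 2 * MIN_STEM + MIN_LOOP - 1, n):
            # extend stem inward from the (i, j) closing pair
            s = 0
            stack_sum = 0.0
            while (
                i + s < j - s
                and _COMP[seq[i + s]] == seq[j - s]
            ):
                s += 1
                loop = j - i - 2 * s + 1
                if s >= MIN_STEM and loop >= MIN_LOOP:
                    dg = stack_sum + loop_penalty(loop)
                    if best is None or dg < best:
                        best = dg
                if i + s < j - s and _COMP[seq[i + s]] == seq[j - s]:
                    stack_sum += stack_dg(seq[i + s - 1 : i + s + 1], cfg)
    if best is not None and best < 0:
        return best
    return None


def dimer_dg(a: str, b: str, cfg: ThermoConfig = ThermoConfig()) -> float | None:
    """Best ungapped duplex ΔG between a and b, or None if none is stable.

    Every run of >= 3 consecutive complementary pairs in antiparallel
    register is scored as a duplex (stacks + initiation terms); the most
    negative value is returned, None when nothing reaches ΔG < 0.
    Symmetric: dimer_dg(a, b) == dimer_dg(b, a).
    """
    _check_acgt(a, "a")
    _check_acgt(b, "b")
    rc = "".join(_COMP[c] for c in reversed(b))
    n, m = len(a), len(rc)
    best: float | None = None
    # diagonals of the a-vs-rc match matrix; equal chars = complementary pair
    for d in range(-(m - 1), n):
        i = max(0, d)
        j = i - d
        while i < n and j < m:
            if a[i] == rc[j]:
                run_start = i
                while i < n and j < m and a[i] == rc[j]:
                    i += 1
                    j += 1
                run_len = i - run_start
                if run_len >= 3:
                    # all sub-runs of length >= 3 of this maximal run
                    for s in range(run_start, i - 2):
                        for e in range(s + 3, i + 1):
                            sub = a[s:e]
                            dg = _init_dg(sub[0], cfg) + _init_dg(sub[-1], cfg)
                            for t in range(len(sub) - 1):
                                dg += stack_dg(sub[t : t + 2], cfg)
                            if best is None or dg < best:
                                best = dg
            else:
                i += 1
                j += 1
    if best is not None and best < 0:
        return best
    return None


def oligo_profile(
    seq: str, cfg: ThermoConfig = ThermoConfig(), partner: str | None = None
) -> ThermoResult:
    """Tm, hairpin ΔG, self-dimer ΔG (and cross-dimer ΔG if partner given)."""
    return ThermoResult(
        tm=melting_temperature(seq, cfg),
        dg_hairpin=hairpin_dg(seq, cfg),
        dg_self_dimer=dimer_dg(seq, seq, cfg),
        dg_cross_dimer=None if partner is None else dimer_dg(seq, partner, cfg),
    )
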