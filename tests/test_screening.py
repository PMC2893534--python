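import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import STRUCTURELESS_20, make_candidate, random_seq
from mlpaprobe import (
    ScoreBreakdown,
    ScreenConfig,
    component_scores,
    final_score,
    melting_temperature,
    physchem_test,
    rank_candidates,
    score_candidate,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def vacuous_config() -> ScreenConfig:
    return ScreenConfig(
        tm_min=-500.0, tm_opt=-499.0, gc_min=0.0, gc_max=1.0,
        dg_hairpin_floor=-1e9, dg_dimer_floor=-1e9,
    )


class TestPhyschemTest:
    def test_vacuous_thresholds_pass_everything(self, rng):
        cfg = vacuous_config()
        for _ in range(20):
            cand = make_candidate(random_seq(rng, 25), random_seq(rng, 25))
            ok, reasons = physchem_test(cand, cfg)
            assert ok and reasons == []

    def test_impossible_thresholds_pass_nothing(self, rng):
        cfg = ScreenConfig(tm_min=500.0, tm_opt=501.0)
        for _ in range(20):
            cand = make_candidate(random_seq(rng, 25), random_seq(rng, 25))
            ok, _ = physchem_test(cand, cfg)
            assert not ok

    def test_at_rich_halves_fail_on_tm(self):
        # NN Tm of the all-AT 20-mer is ~19.7 °C, far below a 60 °C minimum
        cand = make_candidate("ATATATATATATATATATAT", "ATATATATATATATATATAT")
        cfg = ScreenConfig(tm_min=60.0, gc_min=0.0, gc_max=1.0)
        ok, reasons = physchem_test(cand, cfg)
        assert not ok
        assert any("Tm(LHS)" in r for r in reasons)
        assert any("Tm(RHS)" in r for r in reasons)

    def test_multiple_violations_all_reported(self):
        # all-AT: fails both the Tm minimum and the GC window
        cand = make_candidate("ATATATATATATATATATAT", STRUCTURELESS_20)
        cfg = ScreenConfig(tm_min=60.0, gc_min=0.35, gc_max=0.65)
        ok, reasons = physchem_test(cand, cfg)
        assert not ok
        assert any("Tm(LHS)" in r for r in reasons)
        assert any("GC(LHS)" in r for r in reasons)


class TestComponentScores:
    def test_peak_candidate_scores_one_everywhere(self, lenient_screen):
        # G/T-only halves: GC = 0.5 (the tent peak), Tm above tm_opt on the
        # plateau, no foldable structure, RHS starts with the top ligation base
        cand = make_candidate(STRUCTURELESS_20, STRUCTURELESS_20)
        b = component_scores(cand, lenient_screen)
        assert (b.s_tm, b.s_dg, b.s_gc, b.s_lig) == (1.0, 1.0, 1.0, 1.0)

    def test_gc_at_window_edge_scores_zero(self):
        cfg = ScreenConfig(tm_min=40.0, tm_opt=45.0, gc_min=0.5, gc_max=0.9)
        cand = make_candidate(STRUCTURELESS_20, STRUCTURELESS_20)
        b = component_scores(cand, cfg)
        assert b.s_gc == 0.0

    def test_rejects_failed_candidate(self):
        cand = make_candidate("ATATATATATATATATATAT", "ATATATATATATATATATAT")
        cfg = ScreenConfig(tm_min=60.0)
        with pytest.raises(ValueError):
            component_scores(cand, cfg)

    def test_matches_independent_tent_reimplementation(self, rng, lenient_screen):
        """Second-implementation oracle for the piecewise-linear maps."""
        cfg = lenient_screen

        def tent(x, lo, peak, hi):
            if x <= lo or (hi is not None and x >= hi):
                return 0.0
            if x <= peak:
                return (x - lo) / (peak - lo)
            return 1.0 if hi is None else (hi - x) / (hi - peak)

        checked = 0
        for _ in range(50):
            cand = make_candidate(random_seq(rng, 22), random_seq(rng, 22))
            ok, _ = physchem_test(cand, cfg)
            if not ok:
                continue
            b = component_scores(cand, cfg)
            tms = [melting_temperature(s) for s in (cand.lhs, cand.rhs)]
            gcs = [
                (s.count("G") + s.count("C")) / len(s)
                for s in (cand.lhs, cand.rhs)
            ]
            want_tm = min(
                tent(t, cfg.tm_min, cfg.resolved_tm_opt, cfg.tm_max) for t in tms
            )
            want_gc = min(
                tent(g, cfg.gc_min, (cfg.gc_min + cfg.gc_max) / 2, cfg.gc_max)
                for g in gcs
            )
            assert b.s_tm == pytest.approx(want_tm, abs=1e-12)
            assert b.s_gc == pytest.approx(want_gc, abs=1e-12)
            assert b.s_lig == {"G": 1.0, "A": 1.0, "T": 0.75, "C": 0.5}[cand.rhs[0]]
            checked += 1
        assert checked >= 10


class TestFinalScore:
    def test_perfect_scores_with_g_junction(self):
        b = ScoreBreakdown(s_tm=1, s_dg=1, s_gc=1, s_lig=1)
        assert final_score(b, "G") == 1.0
        assert not b.adenosine_adjusted

    def test_adenosine_junction_halves_score(self):
        b = ScoreBreakdown(s_tm=1, s_dg=1, s_gc=1, s_lig=1)
        assert final_score(b, "A") == 0.5
        assert b.adenosine_adjusted

    def test_zero_subscore_is_fatal(self):
        b = ScoreBreakdown(s_tm=1, s_dg=0, s_gc=1, s_lig=1)
        assert final_score(b, "G") == 0.0

    def test_out_of_range_subscore_rejected(self):
        b = ScoreBreakdown(s_tm=1.2, s_dg=1, s_gc=1, s_lig=1)
        with pytest.raises(ValueError):
            final_score(b, "G")

    @given(unit, unit, unit, unit, st.sampled_from("ACGT"))
    def test_final_always_in_unit_interval(self, s1, s2, s3, s4, base):
        for rule in ("product", "min", "mean"):
            b = ScoreBreakdown(s_tm=s1, s_dg=s2, s_gc=s3, s_lig=s4)
            f = final_score(b, base, composite=rule)
            assert 0.0 <= f <= 1.0

    @given(unit, unit, unit, unit)
    def test_adenosine_ratio_exactly_half(self, s1, s2, s3, s4):
        b1 = ScoreBreakdown(s_tm=s1, s_dg=s2, s_gc=s3, s_lig=s4)
        b2 = ScoreBreakdown(s_tm=s1, s_dg=s2, s_gc=s3, s_lig=s4)
        fa = final_score(b1, "A")
        fg = final_score(b2, "G")
        assert fa == 0.5 * fg


class TestRanking:
    def test_descending_by_score(self, rng):
        cands = [
            make_candidate(random_seq(rng, 20), random_seq(rng, 20))
            for _ in range(3)
        ]
        scored = []
        for cand, f in zip(cands, (0.2, 0.9, 0.5)):
            b = ScoreBreakdown(s_tm=1, s_dg=1, s_gc=1, s_lig=1, final=f)
            scored.append((cand, b))
        ranked = rank_candidates(scored)
        assert [b.final for _, b in ranked] == [0.9, 0.5, 0.2]

    def test_ties_broken_by_ligation_position(self, rng):
        seq = random_seq(rng, 60)
        cands = [
            make_candidate(seq[p - 20 : p], seq[p : p + 20])
            for p in (40, 25, 30)
        ]
        scored = [
            (
                c.__class__(c.target_id, p, c.lhs, c.rhs),
                ScoreBreakdown(s_tm=1, s_dg=1, s_gc=1, s_lig=1, final=0.7),
            )
            for c, p in zip(cands, (40, 25, 30))
        ]
        ranked = rank_candidates(scored)
        assert [c.ligation_pos for c, _ in ranked] == [25, 30, 40]

    def test_ranking_is_permutation(self, rng):
        scored = []
        for i in range(15):
            c = make_candidate(random_seq(rng, 20), random_seq(rng, 20), f"t{i}")
            scored.append(
                (c, ScoreBreakdown(s_tm=1, s_dg=1, s_gc=1, s_lig=1, final=i / 15))
            )
        ranked = rank_candidates(scored)
        assert sorted(id(c) for c, _ in ranked) == sorted(id(c) for c, _ in scored)


class TestScreenConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "tm_min: 52\ntm_opt: 58\ngc_min: 0.3\ngc_max: 0.7\n"
            "lhs_len_range: [22, 28]\n"
        )
        cfg = ScreenConfig.from_yaml(p)
        assert cfg.tm_min == 52 and cfg.lhs_len_range == (22, 28)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("tm_minimum: 52\n")
        with pytest.raises(ValueError, match="unknown"):
            ScreenConfig.from_yaml(p)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(gc_min=0.7, gc_max=0.3)
        with pytest.raises(ValueError):
            ScreenConfig(tm_min=60, tm_opt=55)
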