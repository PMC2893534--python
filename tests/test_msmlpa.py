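import pytest

from conftest import make_candidate, random_seq
from mlpaprobe import (
    PrimerPair,
    RestrictionEnzyme,
    VariantInterval,
    assemble_oligos,
    find_sites,
    get_enzyme,
    load_enzyme_table,
    ms_filter,
    reverse_complement,
    validate_enzyme_table,
)
from mlpaprobe.msmlpa import IUPAC_EXPAND, EnzymeTableError, apply_ms_view
from mlpaprobe.uniqueness import VariantOverlap

HHAI = RestrictionEnzyme("HhaI", "GCGC", 3, 1, True)
ACII = RestrictionEnzyme("AciI", "CCGC", 1, 3, True)


def enz(recognition, name="E", ms=True):
    return RestrictionEnzyme(name, recognition, 1, len(recognition) - 1, ms)


class TestEnzymeTable:
    def test_packaged_table_is_valid(self):
        table = load_enzyme_table()
        assert {e.name for e in table} >= {"HhaI", "HpaII", "AciI"}
        assert all(e.methylation_sensitive for e in table)

    def test_single_cpg_accepted(self):
        validate_enzyme_table([enz("GCGC")])  # one CG, at offset 1

    def test_multiple_cpg_rejected(self):
        with pytest.raises(EnzymeTableError, match="multiple CpG"):
            validate_enzyme_table([enz("CGCG")])  # CG at offsets 0 and 2

    def test_ms_without_cpg_rejected(self):
        with pytest.raises(EnzymeTableError, match="no CpG"):
            validate_enzyme_table([enz("GGCC")])

    def test_cut_offset_outside_site_rejected(self):
        bad = RestrictionEnzyme("E", "GCGC", 7, 1, True)
        with pytest.raises(EnzymeTableError, match="cut offset"):
            validate_enzyme_table([bad])

    def test_duplicate_names_rejected(self):
        with pytest.raises(EnzymeTableError, match="duplicate"):
            validate_enzyme_table([enz("GCGC"), enz("ACGT")])

    def test_unknown_enzyme_lookup(self):
        with pytest.raises(KeyError):
            get_enzyme("NoSuchEnzyme")


def naive_sites(seq, enzyme):
    """O(n*m) IUPAC scan oracle over both strands."""
    hits = []
    patterns = [(enzyme.recognition, "+")]
    rc = reverse_complement(enzyme.recognition)
    if rc != enzyme.recognition:
        patterns.append((rc, "-"))
    for pat, strand in patterns:
        m = len(pat)
        for i in range(len(seq) - m + 1):
            if all(seq[i + j] in IUPAC_EXPAND[pat[j]] for j in range(m)):
                hits.append((i, strand))
    return sorted(hits)


class TestFindSites:
    def test_single_site(self):
        (hit,) = find_sites("AAGCGCAA", HHAI)
        assert hit.position == 2 and hit.strand == "+"

    def test_no_site(self):
        assert find_sites("AAAAAA", HHAI) == []

    def test_overlapping_sites_all_reported(self):
        hits = find_sites("GCGCGC", HHAI)
        assert [h.position for h in hits] == [0, 2]

    def test_nonpalindromic_scans_both_strands(self):
        # AciI CCGC: the bottom strand carries the site where the top reads GCGG
        hits = find_sites("AAGCGGAA", ACII)
        assert [(h.position, h.strand) for h in hits] == [(2, "-")]

    def test_palindromic_site_reported_once(self):
        hits = find_sites("AGCGCA", HHAI)
        assert len(hits) == 1

    def test_degenerate_recognition(self):
        e = enz("RCGY")  # R=A/G, Y=C/T
        hits = find_sites("AAACGTAA", e)
        assert any(h.position == 2 for h in hits)

    def test_matches_naive_scan_oracle(self, rng):
        enzymes = [HHAI, ACII, enz("RCGY"), get_enzyme("ClaI")]
        for _ in range(40):
            seq = random_seq(rng, rng.randint(20, 300))
            for e in enzymes:
                got = [(h.position, h.strand) for h in find_sites(seq, e)]
                assert got == naive_sites(seq, e)


def build_ms_candidate(site_offset, lhs_len=25, rhs_len=25, site="GCGC"):
    """A/T background hybrid with a single recognition site planted at
    ``site_offset`` (hybrid coordinates)."""
    hybrid = "ATTA" * ((lhs_len + rhs_len) // 4 + 1)
    hybrid = hybrid[: lhs_len + rhs_len]
    hybrid = hybrid[:site_offset] + site + hybrid[site_offset + len(site) :]
    return make_candidate(hybrid[:lhs_len], hybrid[lhs_len:])


def oligos_for(cand, stuffer_seq=""):
    from mlpaprobe import StufferRecord

    stuffer = StufferRecord("s", stuffer_seq) if stuffer_seq else None
    return assemble_oligos(cand, PrimerPair(), stuffer)


class TestMsFilter:
    def test_clean_single_site_passes(self):
        cand = build_ms_candidate(10)
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [])
        assert verdict.passed
        assert verdict.rule_results == {1: True, 2: True, 3: True, 4: True}
        assert verdict.site.position == 10

    def test_two_sites_fail_rule_1(self):
        cand = build_ms_candidate(8)
        hybrid = cand.hybrid[:30] + "GCGC" + cand.hybrid[34:]
        cand2 = make_candidate(hybrid[:25], hybrid[25:])
        verdict = ms_filter(cand2, oligos_for(cand2), HHAI, [])
        assert not verdict.passed
        assert verdict.rule_results[1] is False

    def test_zero_sites_fail_rule_1(self):
        cand = make_candidate("AT" * 12, "TA" * 12)
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [])
        assert verdict.rule_results[1] is False

    def test_three_nt_flank_fails_rule_3(self):
        cand = build_ms_candidate(3)
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [])
        assert verdict.rule_results[3] is False

    def test_stuffer_junction_site_fails_rule_2(self):
        cand = build_ms_candidate(10)
        # RHS ends ...TA; a stuffer starting GCGC... adds a new RPO site
        verdict = ms_filter(cand, oligos_for(cand, "GCGCTTTT"), HHAI, [])
        assert verdict.rule_results[2] is False
        assert verdict.rule_results[1] is True

    def test_snp_inside_site_fails_rule_4(self):
        cand = build_ms_candidate(10)
        ov = VariantOverlap(
            variant=VariantInterval("c", 0, 1, "SNP"), hybrid_start=11,
            hybrid_end=12, half="LHS",
        )
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [ov])
        assert verdict.rule_results[4] is False

    def test_snp_outside_site_passes_rule_4(self):
        cand = build_ms_candidate(10)
        ov = VariantOverlap(
            variant=VariantInterval("c", 0, 1, "SNP"), hybrid_start=20,
            hybrid_end=21, half="LHS",
        )
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [ov])
        assert verdict.rule_results[4] is True

    def test_indels_ignored_by_default(self):
        cand = build_ms_candidate(10)
        ov = VariantOverlap(
            variant=VariantInterval("c", 0, 3, "indel"), hybrid_start=11,
            hybrid_end=13, half="LHS",
        )
        assert ms_filter(cand, oligos_for(cand), HHAI, [ov]).rule_results[4]
        assert not ms_filter(
            cand, oligos_for(cand), HHAI, [ov], include_indels=True
        ).rule_results[4]

    def test_junction_spanning_site_counts_once(self):
        cand = build_ms_candidate(23)  # GCGC spans positions 23-26, nick at 25
        verdict = ms_filter(cand, oligos_for(cand), HHAI, [])
        assert verdict.rule_results[1] is True
        # the split site appears in neither oligo, so no extra-site failure
        assert verdict.rule_results[2] is True
        assert verdict.passed

    def test_non_ms_enzyme_is_input_error(self):
        cand = build_ms_candidate(10)
        not_ms = RestrictionEnzyme("EcoRI", "GAATTC", 1, 5, False)
        with pytest.raises(ValueError, match="not methylation-sensitive"):
            ms_filter(cand, oligos_for(cand), not_ms, [])

    def test_sweep_pass_boundary_at_four_nt_flank(self):
        """Sliding one site across the hybrid passes exactly where both
        flanks are >= 4 nt."""
        L = 50
        for offset in range(0, L - 4 + 1):
            cand = build_ms_candidate(offset)
            verdict = ms_filter(cand, oligos_for(cand), HHAI, [])
            expect = offset >= 4 and (L - offset - 4) >= 4
            assert verdict.passed == expect, f"offset {offset}"


class TestApplyMsView:
    def _rows(self, offsets):
        import types

        rows = []
        for off in offsets:
            cand = build_ms_candidate(off)
            rows.append(
                types.SimpleNamespace(
                    candidate=cand,
                    oligos=oligos_for(cand),
                    variant_overlaps=[],
                    ms_verdict=None,
                )
            )
        return rows

    def test_survivors_are_order_preserving_subset(self):
        rows = self._rows([10, 2, 15, 44, 20])  # 2 and 44 violate rule 3
        survivors = apply_ms_view(rows, HHAI)
        assert [r.candidate for r in survivors] == [
            rows[0].candidate, rows[2].candidate, rows[4].candidate
        ]
        assert all(r.ms_verdict.passed for r in survivors)

    def test_enzyme_without_sites_gives_empty_view(self):
        rows = self._rows([10, 20])
        survivors = apply_ms_view(rows, get_enzyme("ClaI"))
        assert survivors == []
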