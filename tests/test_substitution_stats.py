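"""Concordant-site detection, composition profiles and the bias tests."""
import math

from hypothesis import given, settings, strategies as st

import numpy as np
import pytest
from scipy import stats

from protshift import (
    SpeciesPartition,
    SubstitutionSite,
    accumulate_matrix,
    detect_concordant_sites,
    exact_binomial_pvalue,
    global_composition,
    global_usage_chi2,
    pool_sites,
    site_composition,
)
from protshift.substitution_stats import CompositionProfile, normal_proportion_pvalue

from protshift import test_directional_imbalance as imbalance_test
from protshift import test_usage_bias as usage_bias_test
from _oracles import brute_force_sites, direct_binomial_two_sided
from conftest import make_alignment, random_alignment


def six_species_alignment(ref1, ref2, fg):
    """One column per character position; fg is a 4-tuple of row strings."""
    rows = [("ref1", "r1", ref1), ("ref2", "r2", ref2)]
    rows += [(f"fg{i + 1}", f"t{i + 1}", s) for i, s in enumerate(fg)]
    return make_alignment(rows)


class TestDetectConcordantSites:
    def test_concordant_replacement_yields_site(self, partition):
        aln = six_species_alignment("L", "L", ("M", "M", "M", "M"))
        sites = detect_concordant_sites(aln, partition)
        assert [(s.column, s.ref_residue, s.fg_residue) for s in sites] == [(1, "L", "M")]

    def test_identical_column_yields_nothing(self, partition):
        aln = six_species_alignment("L", "L", ("L", "L", "L", "L"))
        assert detect_concordant_sites(aln, partition) == []

    def test_gap_or_x_disqualifies(self, partition):
        for bad in "-X":
            aln = six_species_alignment("L", "L", ("M", "M", "M", bad))
            assert detect_concordant_sites(aln, partition) == []

    def test_discordant_foreground_yields_nothing(self, partition):
        aln = six_species_alignment("L", "L", ("M", "M", "M", "I"))
        assert detect_concordant_sites(aln, partition) == []

    def test_discordant_references_yield_nothing(self, partition):
        aln = six_species_alignment("L", "K", ("M", "M", "M", "M"))
        assert detect_concordant_sites(aln, partition) == []

    def test_missing_species_is_error_naming_it(self, partition):
        aln = make_alignment(
            [("ref1", "r", "L"), ("ref2", "r", "L"), ("fg1", "t", "M"), ("fg2", "t", "M"),
             ("fg3", "t", "M")]
        )
        with pytest.raises(ValueError, match="fg4"):
            detect_concordant_sites(aln, partition)

    def test_permissive_mode_scores_present_species(self, partition):
        aln = make_alignment(
            [("ref1", "r", "L"), ("ref2", "r", "L"), ("fg1", "t", "M"), ("fg2", "t", "M")]
        )
        sites = detect_concordant_sites(aln, partition, require_all_foreground=False)
        assert [(s.ref_residue, s.fg_residue) for s in sites] == [("L", "M")]
        # a gap demotes the species to absent; one remaining fg species < 2
        aln2 = make_alignment(
            [("ref1", "r", "L"), ("ref2", "r", "L"), ("fg1", "t", "M"), ("fg2", "t", "-")]
        )
        assert detect_concordant_sites(aln2, partition, require_all_foreground=False) == []

    def test_column_map_reports_original_coordinates(self, partition):
        aln = six_species_alignment("KL", "KL", ("KM", "KM", "KM", "KM"))
        sites = detect_concordant_sites(aln, partition, column_map=[4, 9])
        assert [s.column for s in sites] == [10]  # local col 2 -> original 1-based 10

    def test_matches_bruteforce_on_random_alignments(self, rng, partition):
        species = ["ref1", "ref2", "fg1", "fg2", "fg3", "fg4"]
        for i in range(50):
            aln = random_alignment(rng, species, int(rng.integers(5, 80)), group_id=f"r{i}")
            got = [(s.group_id, s.column, s.ref_residue, s.fg_residue)
                   for s in detect_concordant_sites(aln, partition)]
            assert got == brute_force_sites(aln, partition)


class TestMatrixAndComposition:
    def test_empty_sites_zero_matrix(self):
        m = accumulate_matrix([])
        assert m.total == 0
        assert (m.counts.to_numpy() == 0).all()

    def test_directed_counts(self):
        sites = [SubstitutionSite("g", i + 1, "L", "M") for i in range(3)]
        sites.append(SubstitutionSite("g", 9, "M", "L"))
        m = accumulate_matrix(sites)
        assert m.counts.loc["L", "M"] == 3 and m.counts.loc["M", "L"] == 1
        assert m.total == 4
        assert np.diag(m.counts.to_numpy()).sum() == 0
        assert m.percentages().loc["L", "M"] == pytest.approx(75.0)

    def test_site_composition_and_conservation(self):
        sites = [SubstitutionSite("g", 1, "L", "M"), SubstitutionSite("g", 2, "L", "S")]
        ref, fg = site_composition(sites)
        assert ref.freqs["L"] == 1.0
        assert fg.freqs["M"] == 0.5 and fg.freqs["S"] == 0.5
        m = accumulate_matrix(sites)
        assert ref.total == fg.total == m.total == len(sites)

    def test_empty_profile_flagged(self):
        ref, fg = site_composition([])
        assert ref.total == 0
        assert ref.freqs.isna().all()

    def test_global_composition_counts_non_gap_residues(self):
        aln = make_alignment([("sp", "s", "MMLK"), ("other", "o", "MMMM")])
        prof = global_composition([aln], "sp")
        assert prof.freqs["M"] == 0.5 and prof.freqs["L"] == 0.25 and prof.freqs["K"] == 0.25
        gapped = make_alignment([("sp", "s", "M--K")])
        assert global_composition([gapped], "sp").total == 2

    def test_global_composition_missing_species_error(self):
        aln = make_alignment([("sp", "s", "MK")])
        with pytest.raises(ValueError, match="absent"):
            global_composition([aln], "ghost")

    def test_pool_sites_concatenates_and_checks_duplicates(self):
        a = [SubstitutionSite("g1", 1, "L", "M"), SubstitutionSite("g1", 5, "A", "S")]
        b = [SubstitutionSite("g2", 1, "K", "R")] * 1 + [
            SubstitutionSite("g2", 2, "K", "R"), SubstitutionSite("g2", 3, "K", "R")
        ]
        pooled = pool_sites([a, b])
        assert len(pooled) == 5 and pooled[:2] == a
        with pytest.raises(ValueError, match="duplicate"):
            pool_sites([a, a])

    def test_invalid_site_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionSite("g", 1, "L", "L")
        with pytest.raises(ValueError):
            SubstitutionSite("g", 1, "-", "M")


def profile(**counts):
    import pandas as pd

    from protshift.alphabet import AMINO_ACIDS

    s = pd.Series(0, index=list(AMINO_ACIDS))
    for aa, c in counts.items():
        s[aa] = c
    return CompositionProfile(s)


class TestUsageBias:
    def test_identical_profiles_null(self):
        p = profile(M=100, L=900)
        results = usage_bias_test(p, p)
        assert all(r.chi2 == 0.0 and r.p_raw == 1.0 and not r.significant for r in results)

    def test_matches_hand_computed_2x2_statistic(self):
        # independent oracle: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)
        ref = profile(M=100, L=9900)
        fg = profile(M=400, L=9600)
        r = next(x for x in usage_bias_test(ref, fg) if x.residue == "M")
        a, b, c, d = 100, 9900, 400, 9600
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert r.chi2 == pytest.approx(expected, rel=1e-12)
        assert r.p_raw == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)
        assert r.p_bonferroni == pytest.approx(min(1.0, 20 * r.p_raw))
        assert r.favored_in_foreground is True

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            usage_bias_test(profile(), profile(M=1))

    def test_direction_reported(self):
        ref = profile(P=300, A=700)
        fg = profile(P=100, A=900)
        by_res = {r.residue: r for r in usage_bias_test(ref, fg)}
        assert by_res["P"].favored_in_foreground is False
        assert by_res["A"].favored_in_foreground is True
        assert by_res["W"].favored_in_foreground is None

    def test_global_chi2_secondary_screen(self):
        ref = profile(M=100, L=900)
        fg = profile(M=200, L=800)
        chi2, p, dof = global_usage_chi2(ref, fg)
        assert dof == 1  # only two observed categories remain
        assert chi2 > 0 and 0 < p < 1


class TestExactBinomial:
    def test_symmetric_counts_give_p_one(self):
        assert exact_binomial_pvalue(10, 20) == pytest.approx(1.0)

    def test_80_20_matches_direct_summation(self):
        p = exact_binomial_pvalue(80, 100)
        assert p == pytest.approx(direct_binomial_two_sided(80, 100), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 7, 33, 150])
    def test_agrees_with_scipy_binomtest(self, n):
        for k in range(n + 1):
            ours = exact_binomial_pvalue(k, n)
            ref = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_pvalue(5, 4)
        assert exact_binomial_pvalue(0, 0) == 1.0

    def test_normal_approximation_variant(self):
        p = normal_proportion_pvalue(80, 100)
        z = (80 - 50) / math.sqrt(25)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)


def matrix_with(counts):
    sites = []
    i = 0
    for (src, dst), n in counts.items():
        for _ in range(n):
            sites.append(SubstitutionSite(f"g{i}", 1, src, dst))
            i += 1
    return accumulate_matrix(sites)


class TestDirectionalImbalance:
    def test_balanced_pair(self):
        results = imbalance_test(matrix_with({("L", "M"): 10, ("M", "L"): 10}))
        (r,) = results
        assert r.log2_ratio == 0.0 and r.p_raw == pytest.approx(1.0)

    def test_80_20_pair(self):
        (r,) = imbalance_test(matrix_with({("L", "M"): 80, ("M", "L"): 20}))
        assert r.log2_ratio == pytest.approx(2.0)
        assert r.p_raw == pytest.approx(direct_binomial_two_sided(80, 100), abs=1e-12)

    def test_one_direction_unobserved_has_valid_p_but_nan_ratio(self):
        (r,) = imbalance_test(matrix_with({("L", "M"): 12}))
        assert math.isnan(r.log2_ratio)
        assert r.p_raw == pytest.approx(direct_binomial_two_sided(12, 12), abs=1e-12)

    def test_zero_total_pairs_omitted(self):
        results = imbalance_test(matrix_with({("L", "M"): 3}))
        assert len(results) == 1  # the other 189 pairs are grey / omitted

    def test_bh_adjustment_matches_hand_computation(self):
        m = matrix_with({("L", "M"): 30, ("M", "L"): 2, ("A", "S"): 6, ("S", "A"): 5,
                         ("K", "R"): 9, ("R", "K"): 1})
        results = imbalance_test(m)
        ps = sorted(r.p_raw for r in results)
        n = len(ps)
        # step-up BH by hand
        adj = [p * n / (i + 1) for i, p in enumerate(ps)]
        for i in range(n - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        got = sorted(r.q_bh for r in results)
        assert got == pytest.approx([min(1.0, a) for a in adj], rel=1e-12)

    def test_normal_method_option(self):
        (r,) = imbalance_test(
            matrix_with({("L", "M"): 80, ("M", "L"): 20}), method="normal"
        )
        assert r.p_raw == pytest.approx(normal_proportion_pvalue(80, 100))


class TestRoleSwap:
    def test_swapping_roles_transposes_and_negates(self, rng, partition):
        species = ["ref1", "ref2", "fg1", "fg2", "fg3", "fg4"]
        swapped = partition.swapped()
        for i in range(5):
            aln = random_alignment(rng, species, 60, group_id=f"r{i}")
            m_fwd = accumulate_matrix(detect_concordant_sites(aln, partition))
            m_rev = accumulate_matrix(detect_concordant_sites(aln, swapped))
            assert m_rev.counts.equals(m_fwd.counts.T)
            fwd = {(r.residue_a, r.residue_b): r for r in imbalance_test(m_fwd)}
            rev = {(r.residue_a, r.residue_b): r for r in imbalance_test(m_rev)}
            assert set(fwd) == set(rev)
            for key, rf in fwd.items():
                rr = rev[key]
                assert rr.p_raw == pytest.approx(rf.p_raw, abs=1e-14)
                if not math.isnan(rf.log2_ratio):
                    assert rr.log2_ratio == pytest.approx(-rf.log2_ratio)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 300).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
def test_exact_binomial_symmetry_and_range_property(nk):
    """p(k, n) = p(n-k, n), always in (0, 1], for arbitrary counts."""
    n, k = nk
    p = exact_binomial_pvalue(k, n)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(exact_binomial_pvalue(n - k, n), rel=1e-9)
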