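"""p-distance semantics, the 0.34 %/Myr clock, consensus, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervkit.dating import (
    AgeEstimate,
    MethodUnavailableError,
    NoComparableSitesError,
    age_from_pair,
    build_consensus,
    estimate_age,
    estimate_age_from_ltrs,
    p_distance,
    summarize_ages,
)
from ervkit.simulate import plant_divergence

aligned_pair = st.integers(1, 40).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="ACGTN-", min_size=n, max_size=n),
        st.text(alphabet="ACGTN-", min_size=n, max_size=n)))


class TestPDistance:
    def test_simple_mismatch(self):
        assert p_distance("ACGT", "ACGA") == (0.25, 4)

    def test_pairwise_deletion(self):
        assert p_distance("AC-T", "ACGT") == (0.0, 3)

    def test_cpg_masking_hand_count(self):
        # CG at positions 3-4 of the first sequence masks that column pair
        assert p_distance("TTCGTT", "TTTATT", mask_cpg=True) == (0.0, 4)
        D, sites = p_distance("TTCGTT", "TTTATT", mask_cpg=False)
        assert (pytest.approx(D), sites) == (2 / 6, 6)

    def test_no_comparable_sites_is_explicit_error(self):
        with pytest.raises(NoComparableSitesError):
            p_distance("--", "AC")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")

    @given(aligned_pair)
    @settings(max_examples=80, deadline=None)
    def test_symmetry_range_and_mask_monotonicity(self, pair):
        a, b = pair
        try:
            d1, s1 = p_distance(a, b)
        except NoComparableSitesError:
            return
        d2, s2 = p_distance(b, a)
        assert (d1, s1) == (d2, s2)
        assert 0.0 <= d1 <= 1.0
        try:
            _, s_masked = p_distance(a, b, mask_cpg=True)
        except NoComparableSitesError:
            return
        assert s_masked <= s1


class TestClockFormula:
    def test_ltr_pair_is_halved(self):
        est = AgeEstimate.from_divergence("ltr_vs_ltr", 0.034, 968)
        assert est.T == pytest.approx((3.4 / 0.34) / 2) == 5.0

    def test_consensus_methods_not_halved(self):
        est = AgeEstimate.from_divergence("gag_vs_consensus", 0.034, 2000)
        assert est.T == pytest.approx(10.0)

    def test_identical_ltrs_date_to_zero(self):
        est = age_from_pair("ACGTAT" * 50, "ACGTAT" * 50, "ltr_vs_ltr")
        assert est.T == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            age_from_pair("ACGT", "ACGT", "carbon_dating")


class TestClosedLoopWithPlanter:
    def test_planted_age_recovered_within_site_quantum(self, model):
        quantum = 100 / (2 * 0.34 * len(model.ltr_seq)) + 1e-9  # ~0.152 Myr
        for T in (2.0, 10.0, 25.0):
            l5, l3, _ = plant_divergence(model.ltr_seq, model.internal_seq,
                                         T, seed=int(T * 10))
            est = estimate_age_from_ltrs(l5, l3, band=50)
            assert est.T == pytest.approx(T, abs=quantum + 1e-6), T

    def test_mean_bias_within_two_percent(self, model):
        # calibration over ages drawn uniformly from the activity window
        rng = np.random.default_rng(17)
        rel = []
        for _ in range(120):
            T = float(rng.uniform(1, 35))
            l5, l3, _ = plant_divergence(
                model.ltr_seq, model.internal_seq, T,
                seed=int(rng.integers(2 ** 31)))
            est = estimate_age_from_ltrs(l5, l3, band=60)
            rel.append((est.T - T) / T)
        assert abs(float(np.mean(rel))) <= 0.02

    def test_ltr_vs_consensus_agrees_with_ltr_pair(self, model):
        # disjoint-site planting keeps the multi-locus consensus at the
        # ancestral state, so both estimators see the same divergence
        pairs = [plant_divergence(model.ltr_seq, model.internal_seq, 12.0,
                                  seed=s)[:2] for s in range(8)]
        cols = [ltr for pair in pairs for ltr in pair]
        cons = build_consensus(cols, model.ltr_seq)
        assert cons == model.ltr_seq
        l5, l3 = pairs[0]
        pair_T = age_from_pair(l5, l3, "ltr_vs_ltr").T
        cons_T = np.mean([age_from_pair(l5, cons, "ltr_vs_consensus").T,
                          age_from_pair(l3, cons, "ltr_vs_consensus").T])
        quantum = 100 / (0.34 * len(model.ltr_seq))
        assert abs(pair_T - cons_T) <= quantum


class TestEstimateAgeOnProjections:
    def test_solo_ltr_cannot_use_ltr_pair(self, model):
        from ervkit.align import project_locus
        from ervkit.simulate import make_locus
        solo = make_locus(model, solo_ltr=True, T=5, seed=4)
        proj = project_locus(solo.seq, model.provirus_seq, band=None)
        with pytest.raises(MethodUnavailableError):
            estimate_age(proj, model, "ltr_vs_ltr")

    def test_full_locus_ltr_pair_via_projection(self, projections, model):
        est = estimate_age(projections["macaque_v1"], model, "ltr_vs_ltr")
        assert est.T == pytest.approx(10.0, abs=0.3)


class TestConsensus:
    def test_identical_members(self):
        assert build_consensus(["ACGT", "ACGT"]) == "ACGT"

    def test_plurality(self):
        assert build_consensus(["AAAA", "AAAC", "CAAC"])[0] == "A"

    def test_tie_broken_toward_reference(self):
        assert build_consensus(["A", "C"], reference="C") == "C"
        assert build_consensus(["A", "C"], reference="A") == "A"

    def test_majority_gap_column_emitted_as_gap(self):
        assert build_consensus(["A-", "--", "A-"])[1] == "-"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestSummaries:
    def test_odd_median(self):
        (s,) = summarize_ages({"c": [1.0, 2.0, 3.0]})
        assert s.median == 2.0 and s.n == 3

    def test_single_estimate(self):
        (s,) = summarize_ages({"c": [7.5]})
        assert s.median == s.q1 == s.q3 == 7.5

    def test_empty_category_omitted(self):
        assert summarize_ages({"c": []}) == []
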