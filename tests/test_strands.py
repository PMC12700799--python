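"""Guide/passenger rule, 5'-end thermodynamics, loading model, switch detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirswitch.core import CountMatrix, Genotype
from mirswitch.quantify import normalize
from mirswitch.simulate import (
    SimulationParams,
    hairpin_latents,
    planted_switch_set,
    simulate_expression,
)
from mirswitch.strands import (
    AsymmetryScores,
    LoadingParams,
    SubstrateForm,
    call_strands,
    classify_strands,
    delta_g_first3,
    detect_strand_switch,
    predict_loading,
    score_duplex,
    strand_score,
)


class TestClassifyStrands:
    @pytest.mark.parametrize(
        "c5, c3, guide",
        [
            (800, 200, "5p"),  # 80% and >100 reads
            (90, 20, "none"),  # fraction ok but 90 <= 100
            (150, 150, "none"),  # 50/50
            (200, 800, "3p"),
            (101, 0, "5p"),  # boundary: fraction 1.0, reads just over 100
            (100, 0, "none"),  # reads exactly 100: exclusive boundary
            (70, 30, "none"),  # fraction exactly 0.70: exclusive boundary
        ],
    )
    def test_rule_examples(self, c5, c3, guide):
        assert classify_strands(c5, c3).guide_arm == guide

    def test_zero_expression_flagged(self):
        call = classify_strands(0, 0, "h")
        assert call.guide_arm == "none" and call.zero_expression

    def test_matches_brute_force_on_integer_grid(self):
        """Oracle equivalence: direct transcription of the printed rule over
        a coarse grid of count pairs."""
        for c5 in range(0, 301, 7):
            for c3 in range(0, 301, 7):
                if c5 + c3 == 0:
                    expected = "none"
                elif c5 / (c5 + c3) > 0.70 and c5 > 100:
                    expected = "5p"
                elif c3 / (c5 + c3) > 0.70 and c3 > 100:
                    expected = "3p"
                else:
                    expected = "none"
                assert classify_strands(c5, c3).guide_arm == expected, (c5, c3)

    def test_fractions_complementary(self):
        call = classify_strands(60, 140)
        assert np.isclose(call.fraction_5p, 0.3)


class TestDeltaG3:
    def test_frozen_nearest_neighbor_values(self):
        """Hand-computed stack sums from the standard Watson-Crick table.

        Strand 5'-UGA..., partner pairing A,C,U antiparallel: stacks
        (U.A,G.C) = UG/AC = -2.11 and (G.C,A.U) = GA/CU = -2.35.
        """
        strand = "UGAGGUA"
        partner = "UCA" + "GGGG"  # partner[2]=A pairs U, [1]=C pairs G, [0]=U pairs A
        pairing = {0: 2, 1: 1, 2: 0}
        res = delta_g_first3(strand, partner, pairing)
        assert res.value == pytest.approx(-2.11 + -2.35)
        assert not res.any_unpaired

    def test_gc_stacks_more_stable_than_au(self):
        gc = delta_g_first3("GCGAAAA", "AACGC", {0: 4, 1: 3, 2: 2})  # G.C,C.G,G.C
        au = delta_g_first3("AUAAAAA", "AAUAU", {0: 4, 1: 3, 2: 2})  # A.U,U.A,A.U
        assert gc.value < au.value < 0

    def test_unpaired_first_three_is_zero_and_flagged(self):
        res = delta_g_first3("AAAGGG", "CCCCCC", {})
        assert res.value == 0.0 and res.any_unpaired

    def test_non_watson_crick_position_breaks_stack(self):
        # middle position G across G: only flagged, no stack spans it
        res = delta_g_first3("AGAGGG", "AGUAU", {0: 4, 1: 3, 2: 2})
        assert res.value == 0.0
        assert res.paired == (True, False, True)

    def test_non_rna_rejected(self):
        with pytest.raises(ValueError, match="RNA"):
            delta_g_first3("ACGT", "ACGU", {})


class TestStrandScore:
    def test_stated_default_arithmetic(self):
        assert strand_score("U", -2.0) == pytest.approx(1 + 0.25 * -2.0)
        assert strand_score("G", 0.0) == 0.0

    def test_nt5_swap_changes_score_by_weight_difference(self):
        dg = -1.7
        assert strand_score("U", dg) - strand_score("G", dg) == pytest.approx(1.0)


class TestPredictLoading:
    def _scores(self, s5, s3):
        return AsymmetryScores("h", "A", "A", 0.0, 0.0, s5, s3)

    def test_nick5p_blocks_5p_strand_exactly(self):
        for s5 in (-3.0, 0.0, 5.0):
            out = predict_loading(SubstrateForm.NICK_5P, self._scores(s5, 0.2))
            assert out.p_load_5p == 0.0
            assert out.blocked_5p

    def test_nick3p_blocks_3p_strand_exactly(self):
        for s3 in (-3.0, 0.0, 5.0):
            out = predict_loading(SubstrateForm.NICK_3P, self._scores(0.2, s3))
            assert out.p_load_3p == 0.0

    def test_duplex_logistic_limits(self):
        hi = predict_loading(SubstrateForm.DUPLEX, self._scores(50.0, -50.0))
        assert hi.p_load_5p == pytest.approx(1.0) and hi.p_load_3p == pytest.approx(0.0)

    def test_duplex_single_ago_budget(self):
        out = predict_loading(SubstrateForm.DUPLEX, self._scores(0.3, 0.1))
        assert out.p_load_5p + out.p_load_3p <= 1.0 + 1e-12

    def test_nick5p_3p_loading_invariant_to_5p_score(self):
        """The key mechanistic claim: with the 5p strand trapped on the loop,
        3p loading depends on the 3p score alone."""
        ref = predict_loading(SubstrateForm.NICK_5P, self._scores(0.0, 0.4))
        for s5 in np.linspace(-5, 5, 11):
            out = predict_loading(SubstrateForm.NICK_5P, self._scores(s5, 0.4))
            assert out.p_load_3p == ref.p_load_3p

    @given(
        s5=st.floats(-3, 3), s3=st.floats(-3, 3), bump=st.floats(0.01, 2.0),
        form=st.sampled_from(list(SubstrateForm)),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_own_score(self, s5, s3, bump, form):
        base = predict_loading(form, self._scores(s5, s3))
        up5 = predict_loading(form, self._scores(s5 + bump, s3))
        up3 = predict_loading(form, self._scores(s5, s3 + bump))
        assert up5.p_load_5p >= base.p_load_5p - 1e-12
        assert up3.p_load_3p >= base.p_load_3p - 1e-12

    @given(s5=st.floats(-3, 3), s3=st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_arm_swap_antisymmetry(self, s5, s3):
        """Swapping arm labels negates the score difference and swaps the
        duplex loading probabilities exactly."""
        fwd = self._scores(s5, s3)
        rev = self._scores(s3, s5)
        assert fwd.delta == -rev.delta
        a = predict_loading(SubstrateForm.DUPLEX, fwd)
        b = predict_loading(SubstrateForm.DUPLEX, rev)
        assert a.p_load_5p == pytest.approx(b.p_load_3p)
        assert a.p_load_3p == pytest.approx(b.p_load_5p)

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            LoadingParams(tau=0.0)


class TestScoreDuplex:
    def test_scores_finite_over_catalog(self, catalog200):
        for h in catalog200[:50]:
            sc = score_duplex(h)
            assert np.isfinite(sc.s5p) and np.isfinite(sc.s3p)
            assert sc.dg3_5p <= 0 and sc.dg3_3p <= 0


@pytest.fixture(scope="module")
def hm_run(catalog200, params2, latents200):
    gt_wt, tot_wt, _ = simulate_expression(catalog200, Genotype.WT, params2, 6, latents200)
    gt_hm, tot_hm, _ = simulate_expression(catalog200, Genotype.HM, params2, 6, latents200)
    total = CountMatrix(
        pd.concat([tot_wt.data, tot_hm.data], axis=1),
        {**tot_wt.samples, **tot_hm.samples},
    )
    norm = normalize(total, "spike_in")
    wt = norm.sample_ids(genotype=Genotype.WT)
    hm = norm.sample_ids(genotype=Genotype.HM)
    calls = call_strands(norm, [h.hairpin_id for h in catalog200], wt)
    return gt_wt, gt_hm, norm, wt, hm, calls


class TestDetectStrandSwitch:
    def test_recovers_planted_switch_set(self, hm_run):
        gt_wt, gt_hm, norm, wt, hm, calls = hm_run
        planted = planted_switch_set(gt_wt, gt_hm)
        table = detect_strand_switch(calls, norm, wt, hm)
        flagged = set(table.index[table["switched"]])
        tp = len(flagged & planted)
        f1 = 2 * tp / (2 * tp + len(flagged - planted) + len(planted - flagged))
        assert f1 >= 0.9

    def test_no_guide_3p_flagged(self, hm_run):
        *_, calls = hm_run
        gt_wt, gt_hm, norm, wt, hm, calls = hm_run
        table = detect_strand_switch(calls, norm, wt, hm)
        assert not ((table["strand_class"] == "guide") & table["switched"]).any()

    def test_wt_self_split_yields_no_switches(self, catalog200, latents200):
        params = SimulationParams(seed=5)
        gt, total, _ = simulate_expression(catalog200, Genotype.WT, params, 12, latents200)
        norm = normalize(total, "spike_in")
        cols = list(norm.data.columns)
        calls = call_strands(norm, [h.hairpin_id for h in catalog200], cols[:6])
        table = detect_strand_switch(calls, norm, cols[:6], cols[6:])
        assert int(table["switched"].sum()) == 0

    def test_requires_replicates(self, hm_run):
        gt_wt, gt_hm, norm, wt, hm, calls = hm_run
        with pytest.raises(ValueError, match="replicates"):
            detect_strand_switch(calls, norm, wt[:1], hm)
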