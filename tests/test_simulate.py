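"""Synthetic-data generator: catalog structure, expression model, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirswitch._nn import WC_COMPLEMENT, is_watson_crick
from mirswitch.core import Genotype
from mirswitch.simulate import (
    SimulationParams,
    expected_abundances,
    expected_log2fc,
    generate_catalog,
    generate_target_map,
    generate_utrs,
    hairpin_latents,
    reads_from_counts,
    simulate_clash_reads,
    simulate_expression,
    simulate_transcriptome,
)


class TestGenerateCatalog:
    def test_single_hairpin_satisfies_invariants(self):
        (h,) = generate_catalog(1, seed=7)
        assert 18 <= len(h.arm5p) <= 25 and len(h.loop) >= 4

    def test_arms_near_reverse_complement_with_overhangs(self, catalog200):
        for h in catalog200:
            paired = sum(
                is_watson_crick(h.arm5p_seq[i], h.arm3p_seq[j]) for i, j in h.duplex_pairs
            )
            assert paired / len(h.duplex_pairs) >= 0.8
            # 2-nt 3' overhang on both strands: the register leaves the last
            # two nucleotides of each arm unpaired
            paired_5p = {i for i, _ in h.duplex_pairs}
            paired_3p = {j for _, j in h.duplex_pairs}
            assert len(h.arm5p) - 1 not in paired_5p and len(h.arm5p) - 2 not in paired_5p
            assert len(h.arm3p) - 1 not in paired_3p and len(h.arm3p) - 2 not in paired_3p

    def test_five_prime_nucleotides_uniform(self, catalog200):
        for arm in ("arm5p_seq", "arm3p_seq"):
            counts = pd.Series([getattr(h, arm)[0] for h in catalog200]).value_counts()
            chi2 = sps.chisquare([counts.get(b, 0) for b in "ACGU"])
            assert chi2.pvalue > 0.01

    def test_deterministic(self):
        assert generate_catalog(10, seed=3) == generate_catalog(10, seed=3)


class TestExpectedAbundances:
    def test_hm_without_residual_cleavage_has_zero_free_5p(self, catalog200):
        params = SimulationParams(seed=2, epsilon=0.0)
        strands, _ = expected_abundances(catalog200, Genotype.HM, params)
        assert (strands.loc[strands["arm"] == "5p", "abundance"] == 0).all()
        assert (strands.loc[strands["arm"] == "5pLoop", "abundance"] > 0).any()

    def test_hetko_equals_wt(self, catalog200, params2):
        wt, _ = expected_abundances(catalog200, Genotype.WT, params2)
        het, _ = expected_abundances(catalog200, Genotype.HetKO, params2)
        pd.testing.assert_frame_equal(wt, het)

    def test_mass_conservation_up_to_decay(self, catalog200, params2, latents200):
        for geno in Genotype:
            strands, _ = expected_abundances(catalog200, geno, params2, latents200)
            per_hairpin = strands.groupby("hairpin_id")["abundance"].sum()
            cap = latents200["lam"] * (params2.rho + 1.0)
            assert (per_hairpin <= cap.loc[per_hairpin.index] + 1e-9).all()

    def test_neutral_stability_limit_hm_3p_equals_wt_3p(self, catalog200):
        params = SimulationParams(seed=2, rho=1.0, delta=1.0)
        wt, _ = expected_abundances(catalog200, Genotype.WT, params)
        hm, _ = expected_abundances(catalog200, Genotype.HM, params)
        m = wt["arm"] == "3p"
        assert np.allclose(wt.loc[m, "abundance"], hm.loc[m, "abundance"])

    def test_hm_3p_abundance_monotone_in_3p_score(self, catalog200, params2, latents200):
        """Raising a passenger 3p strand's score never lowers its expected HM level."""
        hm, scores = expected_abundances(catalog200, Genotype.HM, params2, latents200)
        ab3 = hm.loc[hm["arm"] == "3p"]
        # same hairpin, perturbed score: recompute via the loading law directly
        lp = params2.loading
        s3 = scores["s3p"].to_numpy()
        lam = latents200["lam"].to_numpy()
        for bump in (0.2, 1.0):
            p_lo = 1 / (1 + np.exp(-(s3 - lp.s0) / lp.tau))
            p_hi = 1 / (1 + np.exp(-(s3 + bump - lp.s0) / lp.tau))
            ab_lo = lam * (p_lo * params2.rho + (1 - p_lo) * params2.delta)
            ab_hi = lam * (p_hi * params2.rho + (1 - p_hi) * params2.delta)
            assert (ab_hi >= ab_lo - 1e-12).all()

    def test_unknown_genotype_rejected(self, catalog200, params2):
        with pytest.raises(ValueError, match="genotype"):
            expected_abundances(catalog200, "mutant", params2)


class TestSimulateExpression:
    def test_nb_moments(self):
        """Sample mean of replicate NB draws sits within 3 SE of the NB mean."""
        cat = generate_catalog(1, seed=5)
        params = SimulationParams(seed=5, phi=0.1, lib_sigma=0.0, n_hairpins=1)
        gt, total, _ = simulate_expression(cat, Genotype.WT, params, n_replicates=500)
        species = gt.strands.index[gt.strands["expected_counts"] > 100][0]
        m = gt.strands.loc[species, "expected_counts"]
        draws = total.data.loc[species].to_numpy()
        se = np.sqrt((m + params.phi * m**2) / len(draws))
        assert abs(draws.mean() - m) < 3 * se

    def test_deterministic(self, catalog200, params2, latents200):
        a = simulate_expression(catalog200, Genotype.HM, params2, 3, latents200)
        b = simulate_expression(catalog200, Genotype.HM, params2, 3, latents200)
        pd.testing.assert_frame_equal(a[1].data, b[1].data)
        pd.testing.assert_frame_equal(a[2].data, b[2].data)

    def test_spike_ins_recorded_for_total_libraries(self, catalog200, params2, latents200):
        _, total, ip = simulate_expression(catalog200, Genotype.WT, params2, 2, latents200)
        assert all(m.spike_in_sum > 0 for m in total.samples.values())
        assert all(not m.spike_in_counts for m in ip.samples.values())

    def test_ip_counts_track_loaded_abundance_only(self, catalog200, params2, latents200):
        gt, _, ip = simulate_expression(catalog200, Genotype.HM, params2, 6, latents200)
        loop = gt.strands["arm"] == "5pLoop"
        assert ip.data.loc[loop.index[loop]].to_numpy().sum() == 0


class TestTranscriptome:
    def _truths(self, catalog200, params, latents200):
        out = {}
        for g in (Genotype.WT, Genotype.HM):
            out[g], _, _ = simulate_expression(catalog200, g, params, 2, latents200)
        return out

    def test_zero_repression_means_identical_expectations(self, catalog200, latents200):
        params = SimulationParams(seed=2, repression_strength=0.0, noise=False)
        truths = self._truths(catalog200, params, latents200)
        tm = generate_target_map(catalog200, params)
        gene_truth, counts = simulate_transcriptome(truths, tm, params, 2)
        assert np.allclose(gene_truth["repression_WT"], 1.0)
        assert np.allclose(gene_truth["repression_HM"], 1.0)

    def test_repression_direction_follows_loaded_abundance(self, catalog200, latents200):
        """Genes targeted only by a lost 5p guide go up in HM; genes targeted only
        by a strand-switched passenger 3p go down."""
        params = SimulationParams(seed=2, noise=False)
        truths = self._truths(catalog200, params, latents200)
        wt, hm = truths[Genotype.WT], truths[Genotype.HM]
        up5 = (wt.strands["loaded"] - hm.strands["loaded"]).idxmax()  # a lost 5p guide
        gain3 = (hm.strands["loaded"] - wt.strands["loaded"]).idxmax()  # a switched 3p
        tm = pd.DataFrame(
            {
                "mirna_id": [up5, gain3],
                "gene_id": ["g00001", "g00002"],
                "context_score": [-0.5, -0.5],
                "affinity": [0.5, 0.5],
            }
        )
        gene_truth, _ = simulate_transcriptome(truths, tm, params, 2)
        fc = np.log2(gene_truth["repression_HM"] / gene_truth["repression_WT"])
        assert fc["g00001"] > 0 and fc["g00002"] < 0

    def test_negative_affinity_rejected(self, catalog200, params2, latents200):
        truths = self._truths(catalog200, params2, latents200)
        tm = pd.DataFrame(
            {"mirna_id": ["x-5p"], "gene_id": ["g00001"], "context_score": [0.1], "affinity": [-0.1]}
        )
        with pytest.raises(ValueError, match="affinity"):
            simulate_transcriptome(truths, tm, params2, 2)


@pytest.fixture(scope="module")
def clash_setup(catalog200, params2, latents200):
    gt, _, _ = simulate_expression(catalog200, Genotype.HM, params2, 2, latents200)
    tm = generate_target_map(catalog200, params2)
    utrs, sites = generate_utrs(tm, catalog200, params2)
    return gt, tm, utrs, sites


class TestClashReads:
    @pytest.fixture()
    def setup(self, clash_setup):
        return clash_setup

    def test_pure_background_emits_no_hybrids(self, catalog200, setup):
        gt, tm, utrs, sites = setup
        _, truth = simulate_clash_reads(
            gt, catalog200, tm, utrs, sites, 500, seed=2, background_fraction=1.0
        )
        assert truth["is_background"].all()

    def test_deterministic(self, catalog200, setup):
        gt, tm, utrs, sites = setup
        a = simulate_clash_reads(gt, catalog200, tm, utrs, sites, 1000, seed=9)
        b = simulate_clash_reads(gt, catalog200, tm, utrs, sites, 1000, seed=9)
        assert a[0] == b[0]

    def test_hybrid_arm_ratio_matches_loaded_abundance(self, catalog200, setup):
        """5p:3p chimera ratio tracks the generator's loaded-abundance weighting."""
        gt, tm, utrs, sites = setup
        _, truth = simulate_clash_reads(
            gt, catalog200, tm, utrs, sites, 50000, seed=2, background_fraction=0.0
        )
        w = tm["affinity"].to_numpy() * gt.strands["loaded"].reindex(
            tm["mirna_id"]
        ).fillna(0).to_numpy()
        planted_3p = w[tm["mirna_id"].str.endswith("-3p")].sum() / w.sum()
        observed_3p = truth["mirna_id"].str.endswith("-3p").mean()
        assert abs(observed_3p - planted_3p) < 0.03

    def test_planted_sites_present_in_utrs(self, catalog200, setup):
        gt, tm, utrs, sites = setup
        mature = {
            f"{h.hairpin_id}-{arm}": h.mature_seq(arm)
            for h in catalog200
            for arm in ("5p", "3p")
        }
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for (mirna, gene), pos in list(sites.items())[:50]:
            site = "".join(comp[c] for c in reversed(mature[mirna][1:8])) + "A"
            assert utrs[gene][pos : pos + 8] == site

    def test_zero_reads_rejected(self, catalog200, setup):
        gt, tm, utrs, sites = setup
        with pytest.raises(ValueError, match="n_reads"):
            simulate_clash_reads(gt, catalog200, tm, utrs, sites, 0, seed=2)


class TestReadsFromCounts:
    def test_emitted_reads_are_exact_annotated_sequences(self, small_catalog):
        params = SimulationParams(seed=4, depth=5e3, n_hairpins=len(small_catalog))
        lat = hairpin_latents(small_catalog, params)
        _, total, _ = simulate_expression(small_catalog, Genotype.HM, params, 1, lat)
        reads = reads_from_counts(small_catalog, total)
        seqs = {h.arm5p_seq for h in small_catalog}
        seqs |= {h.arm3p_seq for h in small_catalog}
        seqs |= {h.five_p_loop_seq for h in small_catalog}
        seqs |= {h.three_p_loop_seq for h in small_catalog}
        sid = total.data.columns[0]
        assert reads[sid] and all(r in seqs for r in reads[sid])


class TestExpectedLog2fc:
    def test_wt_vs_itself_is_zero(self, catalog200, params2, latents200):
        gt, _, _ = simulate_expression(catalog200, Genotype.WT, params2, 2, latents200)
        assert np.allclose(expected_log2fc(gt, gt), 0.0)
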