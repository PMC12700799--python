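"""Enrichment ratio, Welch differential testing, KS shifts, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirswitch.core import Assay, Genotype
from mirswitch.quantify import normalize
from mirswitch.simulate import SimulationParams, simulate_expression
from mirswitch.stats import ago_enrichment, differential, ks_shift, score_correlation
from tests.conftest import make_matrix


class TestAgoEnrichment:
    def test_ratio_definition(self):
        ip = make_matrix({"i1": {"a-5p": 20}}, assay=Assay.ago_ip)
        inp = make_matrix({"t1": {"a-5p": 10}})
        out = ago_enrichment(ip, inp, pseudocount=0.0)
        assert out.loc["a-5p", "enrichment"] == pytest.approx(2.0)

    def test_pseudocount_limit_flagged_low_evidence(self):
        ip = make_matrix({"i1": {"a-5p": 0}}, assay=Assay.ago_ip)
        inp = make_matrix({"t1": {"a-5p": 0}})
        out = ago_enrichment(ip, inp, pseudocount=1.0)
        assert out.loc["a-5p", "enrichment"] == pytest.approx(1.0)
        assert bool(out.loc["a-5p", "low_evidence"])

    def test_input_floor_excludes_and_lists(self):
        ip = make_matrix({"i1": {"a-5p": 5, "b-3p": 5}}, assay=Assay.ago_ip)
        inp = make_matrix({"t1": {"a-5p": 100, "b-3p": 1}})
        out = ago_enrichment(ip, inp, input_floor=10.0)
        assert "b-3p" not in out.index and out.attrs["excluded"] == ["b-3p"]

    def test_disjoint_indices_rejected(self):
        ip = make_matrix({"i1": {"a-5p": 5}}, assay=Assay.ago_ip)
        inp = make_matrix({"t1": {"z-3p": 5}})
        with pytest.raises(ValueError, match="share no species"):
            ago_enrichment(ip, inp)

    def test_scale_invariance_under_total_mirna_normalization(
        self, catalog200, params2, latents200
    ):
        """Multiplying all IP libraries by a constant leaves E unchanged after
        per-million normalization."""
        _, total, ip = simulate_expression(catalog200, Genotype.HM, params2, 4, latents200)
        inn = normalize(total, "spike_in")
        e1 = ago_enrichment(normalize(ip, "total_mirna"), inn)["enrichment"]
        scaled = ip.copy()
        scaled.data = scaled.data * 7
        e2 = ago_enrichment(normalize(scaled, "total_mirna"), inn)["enrichment"]
        assert np.allclose(e1, e2)


class TestDifferential:
    def test_identical_groups_null(self):
        m = make_matrix({f"s{i}": {"a-5p": 10, "b-3p": 5} for i in range(6)})
        out = differential(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(out["log2fc"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_welch_matches_independent_closed_form(self):
        """Welch's t and p recomputed from the textbook formula."""
        a, b = np.array([10.0, 12.0, 11.0]), np.array([20.0, 22.0, 21.0])
        m = make_matrix({f"s{i}": {"x": v} for i, v in enumerate(list(a) + list(b))})
        out = differential(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy import stats as sps

        p = 2 * sps.t.sf(abs(t), df)
        assert out.loc["x", "t"] == pytest.approx(t)
        assert out.loc["x", "p"] == pytest.approx(p)

    def test_permutation_within_groups_is_invariant(self):
        vals = {"s0": 3, "s1": 9, "s2": 6, "s3": 20, "s4": 25, "s5": 30}
        m = make_matrix({s: {"x": v, "y": v + 1} for s, v in vals.items()})
        out1 = differential(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        out2 = differential(m, ["s2", "s0", "s1"], ["s5", "s3", "s4"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            {
                f"s{i}": {f"g{j}": int(v) for j, v in enumerate(rng.poisson(50, 40))}
                for i in range(6)
            }
        )
        out = differential(m, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
        srt = out.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()

    def test_single_replicate_rejected(self):
        m = make_matrix({"s0": {"x": 1}, "s1": {"x": 2}, "s2": {"x": 3}})
        with pytest.raises(ValueError, match="replicates"):
            differential(m, ["s0"], ["s1", "s2"])


def _exhaustive_perm_p(fg, bg):
    """Independent oracle: exact permutation null of the one-sided D+ statistic."""
    pool = np.concatenate([fg, bg])
    n = len(fg)

    def d_down(f, b):
        return max(np.mean(f <= x) - np.mean(b <= x) for x in pool)

    d_obs = d_down(np.asarray(fg), np.asarray(bg))
    hits = total = 0
    for idx in itertools.combinations(range(len(pool)), n):
        mask = np.zeros(len(pool), bool)
        mask[list(idx)] = True
        hits += d_down(pool[mask], pool[~mask]) >= d_obs - 1e-12
        total += 1
    return hits / total


class TestKsShift:
    def test_identical_samples_null(self):
        r = ks_shift([1, 2, 3], [1, 2, 3], direction="down")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_full_separation_down(self):
        r = ks_shift([1, 2, 3], [10, 11, 12, 13], direction="down")
        assert r.statistic == 1.0

    def test_full_separation_up(self):
        r = ks_shift([10, 11, 12], [1, 2, 3, 4], direction="up")
        assert r.statistic == 1.0

    def test_small_n_exact_mode_matches_exhaustive_permutation_oracle(self):
        fg = [0.1, 0.9, 1.7, 2.4]
        bg = [1.1, 1.6, 2.2, 2.9, 3.4]
        r = ks_shift(fg, bg, direction="down")  # auto -> exact at 4+5
        assert r.method == "exact"
        assert r.p == pytest.approx(_exhaustive_perm_p(fg, bg), abs=1e-12)

    def test_asymptotic_branch_close_to_permutation_null_at_moderate_n(self):
        rng = np.random.default_rng(12)
        fg = rng.normal(-0.5, 1, 50)
        bg = rng.normal(0.0, 1, 50)
        r = ks_shift(fg, bg, direction="down")
        assert r.method == "asymp"
        pool = np.concatenate([fg, bg])
        xs = np.sort(pool)

        def d_down(f, b):
            return np.max(
                np.searchsorted(np.sort(f), xs, side="right") / len(f)
                - np.searchsorted(np.sort(b), xs, side="right") / len(b)
            )

        d_obs = d_down(fg, bg)
        hits = 0
        B = 4000
        for _ in range(B):
            idx = rng.permutation(100)
            hits += d_down(pool[idx[:50]], pool[idx[50:]]) >= d_obs - 1e-12
        assert abs(r.p - hits / B) < 0.02

    def test_direction_is_explicit(self):
        with pytest.raises(ValueError, match="direction"):
            ks_shift([1, 2, 3], [1, 2, 3], direction="sideways")

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match=">= 3"):
            ks_shift([1, 2], [1, 2, 3], direction="up")


class TestScoreCorrelation:
    def test_perfect_linear_relation(self):
        e = pd.Series(np.exp([1.0, 2.0, 3.0, 4.0]), index=list("abcd"))
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = score_correlation(e, s)
        assert out["r2"] == pytest.approx(1.0)

    def test_shuffled_pairing_kills_correlation(self):
        rng = np.random.default_rng(8)
        idx = [f"m{i}" for i in range(100)]
        s = pd.Series(rng.normal(size=100), index=idx)
        e = pd.Series(np.exp(s + rng.normal(scale=0.2, size=100)), index=idx)
        r2s = []
        for _ in range(100):
            shuffled = pd.Series(rng.permutation(s.to_numpy()), index=idx)
            r2s.append(score_correlation(e, shuffled)["r2"])
        assert np.median(r2s) < 0.05

    def test_zero_variance_flagged(self):
        e = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert score_correlation(e, s)["flag"] == "zero_variance"

    def test_minimum_pairs(self):
        e = pd.Series([1.0, 2.0], index=list("ab"))
        s = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match=">= 3"):
            score_correlation(e, s)
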