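"""TMM, qCML dispersion, NB exact test and BH FDR against hand oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st
from scipy.stats import rankdata

from epifidelity import nbstats
from epifidelity.datatypes import TagCountMatrix

from conftest import make_null_matrix


# --- independent TMM oracle (trimmed weighted mean from the definition) ----


def oracle_tmm_factor(obs, ref, lib_obs, lib_ref, trim_m=0.30, trim_a=0.05):
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    var = (1 - o) / o + (1 - r) / r
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm, ra = rankdata(m), rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(m[kept] / var[kept]) / np.sum(1 / var[kept]))


class TestTmm:
    def test_identical_libraries_get_unit_factors(self):
        c = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(nbstats.tmm_factors(c).to_numpy(), [1.0, 1.0])

    def test_pure_depth_difference_absorbed_by_lib_size(self):
        c = pd.DataFrame({"a": [10, 20, 30, 5], "b": [20, 40, 60, 10]})
        np.testing.assert_allclose(nbstats.tmm_factors(c).to_numpy(), [1.0, 1.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.poisson(40, (100, 3)), columns=list("abc"))
        base = nbstats.tmm_factors(c)
        c2 = c.copy()
        c2["b"] = c["b"] * 7
        np.testing.assert_allclose(
            nbstats.tmm_factors(c2).to_numpy(), base.to_numpy(), rtol=1e-12
        )

    def test_matches_hand_oracle_on_inflated_fixture(self):
        """2 of 20 tags inflated 16x in B: factor equals the definitional oracle."""
        rng = np.random.default_rng(3)
        a = rng.integers(50, 200, size=20)
        b = a + rng.integers(0, 7, size=20)  # distinct log-ratios, no rank ties
        b[:2] *= 16
        c = pd.DataFrame({"a": a, "b": b})
        factors = nbstats.tmm_factors(c)
        raw = oracle_tmm_factor(
            b.astype(float), a.astype(float), float(b.sum()), float(a.sum())
        )
        # package factors are geometric-mean anchored
        expected = np.array([1 / np.sqrt(raw), np.sqrt(raw)])
        np.testing.assert_allclose(factors.to_numpy(), expected, atol=1e-9)

    def test_disjoint_library_warns_and_returns_unit(self):
        c = pd.DataFrame({"a": [5, 5, 0, 0], "b": [0, 0, 7, 7]})
        with pytest.warns(UserWarning, match="no positive tags"):
            f = nbstats.tmm_factors(c)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])

    def test_geometric_mean_of_factors_is_one(self):
        rng = np.random.default_rng(8)
        c = pd.DataFrame(rng.poisson(30, (200, 5)))
        f = nbstats.tmm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self):
        m, groups = make_null_matrix(1, n_tags=2000, phi=0.0)
        nbstats.normalize_tmm(m)
        assert nbstats.common_dispersion(m, groups) <= 0.01

    @pytest.mark.parametrize("phi", [0.05, 0.2])
    def test_recovers_planted_dispersion(self, phi):
        ests = []
        for seed in range(4):
            m, groups = make_null_matrix(100 + seed, n_tags=2000, n_per_group=6, phi=phi)
            nbstats.normalize_tmm(m)
            ests.append(nbstats.common_dispersion(m, groups))
        assert np.mean(ests) == pytest.approx(phi, rel=0.15)

    def test_flat_likelihood_returns_lower_bound(self):
        counts = pd.DataFrame([[7, 7, 7, 7]], columns=list("abcd"))
        meta = pd.DataFrame(
            {"variety": "V", "condition": ["field", "field", "in_vitro", "in_vitro"],
             "tissue": "root", "replicate": 1}, index=counts.columns,
        )
        m = TagCountMatrix(counts, meta)
        assert nbstats.common_dispersion(m, meta["condition"]) == nbstats.PHI_MIN

    def test_all_zero_matrix_warns(self):
        counts = pd.DataFrame(np.zeros((3, 4), dtype=int), columns=list("abcd"))
        meta = pd.DataFrame(
            {"variety": "V", "condition": ["field", "field", "in_vitro", "in_vitro"],
             "tissue": "root", "replicate": 1}, index=counts.columns,
        )
        m = TagCountMatrix(counts, meta)
        with pytest.warns(UserWarning, match="all-zero"):
            assert nbstats.common_dispersion(m, meta["condition"]) == nbstats.PHI_MIN


@pytest.fixture(scope="module")
def fitted():
    m, groups = make_null_matrix(9, n_tags=300, n_per_group=6, phi=0.15)
    nbstats.normalize_tmm(m)
    phi_c = nbstats.common_dispersion(m, groups)
    return m, groups, phi_c


class TestTagwiseDispersion:
    def test_infinite_prior_recovers_common(self, fitted):
        m, groups, phi_c = fitted
        tw = nbstats.tagwise_dispersion(m, groups, phi_c, prior_n=1e9)
        assert np.abs(np.log(tw / phi_c)).max() < 1e-3

    def test_zero_prior_matches_grid_search_oracle(self, fitted):
        m, groups, phi_c = fitted
        sub = TagCountMatrix(m.counts.iloc[:10].copy(), m.meta)
        nbstats.normalize_tmm(sub)
        tw = nbstats.tagwise_dispersion(sub, groups, phi_c, prior_n=0.0)
        pseudo, _ = nbstats.equalize_library_sizes(
            sub.counts, sub.effective_lib_size(), groups, phi_c
        )
        z = pseudo.to_numpy()
        grid = np.logspace(-6, 1, 4000)
        from scipy.special import gammaln

        mask1 = np.asarray(groups.loc[sub.counts.columns] == "field")
        for i in range(10):
            ll = np.zeros_like(grid)
            for mask in (mask1, ~mask1):
                zg, n = z[i, mask], int(mask.sum())
                r = 1.0 / grid
                ll += (
                    gammaln(zg[:, None] + r[None, :]).sum(0)
                    + gammaln(n * r) - gammaln(zg.sum() + n * r) - n * gammaln(r)
                )
            mle = grid[np.argmax(ll)]
            assert abs(np.log(tw.iloc[i] / mle)) < 0.02

    def test_shrinkage_monotone_in_prior(self, fitted):
        m, groups, phi_c = fitted
        spreads = [
            np.std(np.log(nbstats.tagwise_dispersion(m, groups, phi_c, prior_n=pn)))
            for pn in (1, 10, 100)
        ]
        assert spreads[0] > spreads[1] > spreads[2]

    def test_rejects_negative_prior(self, fitted):
        m, groups, phi_c = fitted
        with pytest.raises(ValueError, match="prior_n"):
            nbstats.tagwise_dispersion(m, groups, phi_c, prior_n=-1)


# --- independent exact-test oracle -----------------------------------------


def oracle_exact_p(s1, s2, n1, n2, phi):
    """Enumerate the conditional NB convolution directly."""
    t = int(round(s1 + s2))
    if t == 0:
        return 1.0
    y_obs = min(max(int(round(s1)), 0), t)
    mu = t / (n1 + n2)
    y = np.arange(t + 1)
    if phi == 0:
        pr = st.binom.pmf(y, t, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        p1 = st.nbinom.pmf(y, r1, r1 / (r1 + n1 * mu))
        p2 = st.nbinom.pmf(t - y, r2, r2 / (r2 + n2 * mu))
        pr = p1 * p2
        pr = pr / pr.sum()
    return float(pr[pr <= pr[y_obs] * (1 + 1e-12)].sum())


class TestExactTest:
    def test_mode_split_has_p_one(self):
        assert nbstats._exact_nb_pvalue(6, 6, 3, 3, 0.1) == pytest.approx(1.0)

    def test_poisson_limit_equals_binomial(self):
        p = nbstats._exact_nb_pvalue(3, 9, 3, 3, 0.0)
        pr = st.binom.pmf(np.arange(13), 12, 0.5)
        expected = pr[pr <= pr[3] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            t = int(rng.integers(1, 200))
            s1 = int(rng.integers(0, t + 1))
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            phi = float(rng.choice([0.0, 0.05, 0.2, 1.0]))
            ours = nbstats._exact_nb_pvalue(s1, t - s1, n1, n2, phi)
            assert ours == pytest.approx(oracle_exact_p(s1, t - s1, n1, n2, phi), rel=1e-9)

    def test_zero_total_gives_p_one_and_zero_logfc(self):
        counts = pd.DataFrame(
            {"a": [0, 5], "b": [0, 6], "c": [0, 4], "d": [0, 7]},
            index=["empty", "busy"],
        )
        meta = pd.DataFrame(
            {"variety": "V", "condition": ["field", "field", "in_vitro", "in_vitro"],
             "tissue": "root", "replicate": 1}, index=counts.columns,
        )
        m = TagCountMatrix(counts, meta)
        res = nbstats.exact_test(
            m, meta["condition"], pair=("in_vitro", "field"), dispersion=0.1
        )
        assert res.loc["empty", "pvalue"] == 1.0
        assert res.loc["empty", "log2fc"] == 0.0
        assert res.loc["empty", "phase"] == "none"

    def test_symmetric_under_group_swap(self):
        m, groups = make_null_matrix(21, n_tags=50)
        nbstats.normalize_tmm(m)
        a = nbstats.exact_test(m, groups, ("in_vitro", "field"), dispersion=0.2)
        b = nbstats.exact_test(m, groups, ("field", "in_vitro"), dispersion=0.2)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-9)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        swapped = a["phase"].map(
            {"up_in_field": "up_in_field", "up_in_vitro": "up_in_vitro", "none": "none"}
        )
        pd.testing.assert_series_equal(swapped, b["phase"], check_names=False)

    def test_type_one_error_in_binomial_envelope(self):
        m, groups = make_null_matrix(31, n_tags=2000, n_per_group=3, phi=0.2)
        nbstats.normalize_tmm(m)
        phi_c = nbstats.common_dispersion(m, groups)
        res = nbstats.exact_test(m, groups, ("in_vitro", "field"), dispersion=phi_c)
        rate = (res["pvalue"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert rate <= 0.05 + half
        assert rate >= 0.05 - half


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert nbstats.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(nbstats.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            nbstats.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_empty_input(self):
        assert nbstats.bh_fdr([]).size == 0

    def test_preserves_input_order(self):
        p = [0.04, 0.001, 0.9]
        q = nbstats.bh_fdr(p)
        assert q[1] == min(q)
        assert q[2] == max(q)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            nbstats.bh_fdr([0.5, 1.5])
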