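import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from isoniche.competition import (compare_groups, compute_ccd, compute_centroids,
                                  compute_itp, permanova2, summarize_metric)


def centroid_frame(key, species, pts):
    return pd.DataFrame({"key": key, "species": species,
                         "c_d13c": [p[0] for p in pts],
                         "c_d15n": [p[1] for p in pts]})


class TestCCD:
    def test_three_four_five_triangle(self):
        df = centroid_frame(["c"] * 2, ["a", "b"], [(0, 0), (3, 4)])
        out = compute_ccd(df)
        assert np.allclose(out["ccd"], 5.0)

    def test_identical_centroids_give_zero(self):
        df = centroid_frame(["c"] * 2, ["a", "b"], [(1, 2), (1, 2)])
        assert (compute_ccd(df)["ccd"] == 0).all()

    def test_mediterranean_pooled_centroids(self):
        # swordfish vs blue shark and shortfin mako, published regional means
        df = centroid_frame(
            ["med"] * 3, ["swordfish", "blue_shark", "shortfin_mako"],
            [(-18.26, 11.41), (-17.49, 11.29), (-16.69, 13.08)])
        out = compute_ccd(df).set_index("species")
        d_bs = math.hypot(-18.26 + 17.49, 11.41 - 11.29)
        d_mk = math.hypot(-18.26 + 16.69, 11.41 - 13.08)
        assert abs(out.loc["swordfish", "ccd"] - (d_bs + d_mk) / 2) < 1e-12
        assert abs(out.loc["swordfish", "ccd"] - 1.536) < 1e-3

    def test_two_species_case_is_symmetric(self, rng):
        pts = [tuple(rng.normal(size=2)) for _ in range(2)]
        out = compute_ccd(centroid_frame(["k"] * 2, ["a", "b"], pts))
        assert out["ccd"].iloc[0] == out["ccd"].iloc[1]

    def test_single_species_key_skipped(self):
        df = centroid_frame(["k1", "k2", "k2"], ["a", "a", "b"],
                            [(0, 0), (0, 0), (1, 1)])
        out = compute_ccd(df)
        assert set(out["key"]) == {"k2"}

    @given(dx=st.floats(-30, 30), dy=st.floats(-30, 30),
           c=st.floats(0.1, 10))
    def test_translation_invariant_scale_equivariant(self, dx, dy, c):
        pts = [(0.0, 0.0), (1.0, 2.0), (-1.5, 0.5)]
        base = compute_ccd(centroid_frame(["k"] * 3, list("abc"), pts))
        moved = [(x * c + dx, y * c + dy) for x, y in pts]
        out = compute_ccd(centroid_frame(["k"] * 3, list("abc"), moved))
        assert np.allclose(out["ccd"], base["ccd"] * c, rtol=1e-9, atol=1e-9)

    def test_centroids_from_samples(self):
        df = pd.DataFrame({"species": ["a", "a", "b"], "region": ["r"] * 3,
                           "d13c": [0.0, 2.0, 5.0], "d15n": [1.0, 3.0, 7.0]})
        cents = compute_centroids(df)
        a = cents[cents["species"] == "a"].iloc[0]
        assert a["c_d13c"] == 1.0 and a["c_d15n"] == 2.0 and a["n"] == 2


class TestITP:
    def test_zero_abundance_gives_zero(self):
        assert compute_itp(0.0, 5.0) == 0.0

    def test_direct_evaluations(self):
        assert abs(compute_itp(9.0, 2.0) - math.log(10) / 2) < 1e-15
        assert abs(compute_itp(math.e - 1, 1.0) - 1.0) < 1e-12

    def test_vectorized_matches_direct_arithmetic(self):
        rng = np.random.default_rng(0)
        ncpue = rng.uniform(0, 50, 1000)
        area = rng.uniform(0.1, 30, 1000)
        expected = np.array([math.log(v + 1) / a for v, a in zip(ncpue, area)])
        assert np.max(np.abs(compute_itp(ncpue, area) - expected)) < 1e-12

    def test_monotone_in_abundance_and_inverse_in_area(self):
        n = np.linspace(0, 20, 50)
        itp = compute_itp(n, 2.0)
        assert (np.diff(itp) > 0).all()
        assert np.allclose(compute_itp(5.0, 1.0), 2 * compute_itp(5.0, 2.0))

    def test_log_base_configurable(self):
        assert abs(compute_itp(9.0, 1.0, log_base=10) - 1.0) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_itp(-1.0, 1.0)
        with pytest.raises(ValueError):
            compute_itp(1.0, 0.0)


class TestSummarize:
    def test_singleton_group_sd_absent(self):
        df = pd.DataFrame({"species": ["a"], "itp": [0.4]})
        out = summarize_metric(df, "itp")
        assert out["mean"].iloc[0] == 0.4 and np.isnan(out["sd"].iloc[0])

    def test_two_value_arithmetic(self):
        df = pd.DataFrame({"species": ["a", "a"], "itp": [0.0, 2.0]})
        out = summarize_metric(df, "itp")
        assert out["mean"].iloc[0] == 1.0
        assert abs(out["sd"].iloc[0] - math.sqrt(2)) < 1e-12

    def test_matches_brute_force_aggregation(self, rng):
        df = pd.DataFrame({"species": rng.choice(list("abc"), 200),
                           "ccd": rng.gamma(2, 1, 200)})
        out = summarize_metric(df, "ccd").set_index("species")
        for sp in "abc":
            v = df.loc[df["species"] == sp, "ccd"].to_numpy()
            assert abs(out.loc[sp, "mean"] - v.mean()) < 1e-12
            assert abs(out.loc[sp, "sd"] - v.std(ddof=1)) < 1e-12


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        v = np.tile(np.arange(10.0), 2)
        g = np.repeat(["a", "b"], 10)
        res = compare_groups(v, g)
        assert res.p_value > 0.9

    def test_widely_separated_groups_significant(self, rng):
        v = np.r_[rng.normal(0, 1, 30), rng.normal(10, 1, 30)]
        g = np.repeat(["a", "b"], 30)
        res = compare_groups(v, g)
        assert res.p_value < 1e-3
        assert len(res.pairwise) == 1

    def test_tiny_group_forces_nonparametric(self, rng):
        v = np.r_[rng.normal(0, 1, 20), [0.5, 0.6]]
        g = np.array(["a"] * 20 + ["b"] * 2)
        res = compare_groups(v, g)
        assert res.omnibus_test == "kruskal"

    def test_skewed_data_takes_nonparametric_branch(self, rng):
        v = np.r_[rng.lognormal(0, 2, 60), rng.lognormal(0.2, 2, 60)]
        g = np.repeat(["a", "b"], 60)
        res = compare_groups(v, g)
        assert res.omnibus_test == "kruskal"

    def test_type_one_error_calibrated(self):
        # simulated null: rejection rate at alpha=0.05 should be 0.05 +/- 0.02
        rng = np.random.default_rng(99)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            v = rng.normal(size=60)
            g = np.repeat(["a", "b", "c"], 20)
            rej += compare_groups(v, g, pairwise=False).p_value < 0.05
        assert abs(rej / n_rep - 0.05) < 0.02

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])


def _oracle_sequential_f(Y, fa, fb):
    """Independent route: classical sequential ANOVA projections on coordinates."""
    n = len(Y)
    one = np.ones((n, 1))
    Xa = pd.get_dummies(pd.Series(fa)).to_numpy(float)
    Xb = pd.get_dummies(pd.Series(fb)).to_numpy(float)

    def proj(M):
        q, _ = np.linalg.qr(M)
        return q @ q.T

    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc**2).sum()
    Pa = proj(np.hstack([one, Xa]))
    Pab = proj(np.hstack([one, Xa, Xb]))
    ss_a = ((Pa @ Y - Y.mean(axis=0))**2).sum()
    ss_ab = ((Pab @ Y - Y.mean(axis=0))**2).sum()
    ss_b = ss_ab - ss_a
    ss_res = ss_tot - ss_ab
    df_a = np.linalg.matrix_rank(np.hstack([one, Xa])) - 1
    df_b = np.linalg.matrix_rank(np.hstack([one, Xa, Xb])) - 1 - df_a
    df_res = n - 1 - df_a - df_b
    return (ss_a / df_a) / (ss_res / df_res), (ss_b / df_b) / (ss_res / df_res)


class TestPermanova:
    def test_pseudo_f_matches_coordinate_anova(self, rng):
        Y = rng.normal(size=(24, 2))
        fa = rng.choice(["a", "b", "c"], 24)
        fb = rng.choice(["x", "y"], 24)
        res = permanova2(Y, fa, fb, n_perm=99, seed=0)
        f_a, f_b = _oracle_sequential_f(Y, fa, fb)
        assert abs(res.pseudo_f[0] - f_a) < 1e-8
        assert abs(res.pseudo_f[1] - f_b) < 1e-8

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        n = 6
        Y = rng.normal(size=(n, 2))
        fa = np.array(["a", "a", "b", "b", "a", "b"])
        fb = np.array(["x", "y", "x", "y", "y", "x"])
        res = permanova2(Y, fa, fb, exact=True)
        f_a, f_b = _oracle_sequential_f(Y, fa, fb)
        count_a = count_b = total = 0
        for pm in itertools.permutations(range(n)):
            fpa, fpb = _oracle_sequential_f(Y[list(pm)], fa, fb)
            count_a += fpa >= f_a - 1e-12
            count_b += fpb >= f_b - 1e-12
            total += 1
        assert res.p_value[0] == pytest.approx(count_a / total, abs=1e-12)
        assert res.p_value[1] == pytest.approx(count_b / total, abs=1e-12)

    def test_strong_separation_attains_minimal_p(self, rng):
        Y = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(10, 1, (15, 2))])
        sp = np.repeat(["a", "b"], 15)
        reg = np.tile(["r1", "r2", "r3"], 10)
        res = permanova2(Y, sp, reg, n_perm=999, seed=3)
        assert res.p_value[0] == pytest.approx(1 / 1000)

    def test_null_p_values_are_uniform(self):
        # shuffled labels: p should be U(0,1); KS test must not reject
        rng = np.random.default_rng(17)
        pvals = []
        for i in range(400):
            Y = rng.normal(size=(20, 2))
            fa = rng.permutation(np.repeat(["a", "b"], 10))
            fb = rng.permutation(np.tile(["x", "y"], 10))
            res = permanova2(Y, fa, fb, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value[0])
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_level_factor_rejected(self, rng):
        Y = rng.normal(size=(8, 2))
        with pytest.raises(ValueError):
            permanova2(Y, np.repeat("a", 8), np.tile(["x", "y"], 4))
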