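"""Nonparametric test wrappers against enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import valphys as v
from valphys.design import ConfigurationError
from valphys.stats import bh_adjust


def exact_mw_p_twosided(a, b):
    """Full enumeration of the Mann-Whitney null: every assignment of the
    pooled (distinct) values to group A, two-sided p = 2 * min(tail)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_separated_triples(self):
        res = v.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)
        assert res.direction == -1

    def test_identical_multisets(self):
        res = v.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)
        assert res.direction == 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            v.mann_whitney([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 4), (5, 4)])
    def test_exact_path_matches_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            res = v.mann_whitney(a, b)
            assert res.test == "mann-whitney-exact"
            assert res.p == pytest.approx(exact_mw_p_twosided(a, b), abs=1e-12)

    def test_exact_close_to_asymptotic_at_n8(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 17))
            a, b = pooled[:8], pooled[8:]
            exact = v.mann_whitney(a, b).p
            from scipy.stats import mannwhitneyu

            asym = mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - asym) <= 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        p1 = v.mann_whitney(a, b).p
        p2 = v.mann_whitney(np.exp(a), np.exp(b)).p
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestKSNormality:
    def test_normal_data_mostly_accepted(self):
        rng = np.random.default_rng(0)
        accepted = sum(
            v.ks_normality(rng.normal(size=1000)).p > 0.05 for _ in range(20)
        )
        assert accepted >= 18  # standardization makes the test conservative

    def test_exponential_data_rejected(self):
        rng = np.random.default_rng(1)
        rejected = sum(
            v.ks_normality(rng.exponential(size=1000)).p < 0.01 for _ in range(20)
        )
        assert rejected == 20

    def test_small_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            v.ks_normality([1.0, 2.0, 3.0])


class TestZScore:
    def make_table(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame(
            {
                "subject": np.repeat(["S01", "S02"], 20),
                "f1": rng.normal(5, 2, 40),
                "f2": rng.uniform(0, 10, 40),
            }
        )

    def test_global_standardization(self):
        out = v.zscore_features(self.make_table(), ["f1", "f2"])
        for c in ("f1", "f2"):
            assert out[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_per_subject_standardization(self):
        out = v.zscore_features(
            self.make_table(), ["f1"], grouping="per-subject"
        )
        for _, g in out.groupby("subject"):
            assert g["f1"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_constant_column_named(self):
        df = self.make_table()
        df["dead"] = 3.0
        with pytest.raises(ConfigurationError, match="dead"):
            v.zscore_features(df, ["f1", "dead"])


class TestCorrelation:
    def test_identity_feature(self):
        df = pd.DataFrame(
            {"subject": "S01", "valence_rating": np.arange(14.0),
             "f": np.arange(14.0)}
        )
        out = v.feature_valence_correlation(df, ["f"], mode="SI")
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_feature_centred_at_zero(self):
        rng = np.random.default_rng(5)
        rhos = []
        for _ in range(200):
            df = pd.DataFrame(
                {"subject": "S01", "valence_rating": rng.normal(size=14),
                 "f": rng.normal(size=14)}
            )
            rhos.append(
                v.feature_valence_correlation(df, ["f"], mode="SI")["rho"].iloc[0]
            )
        assert abs(np.mean(rhos)) < 0.05
        assert np.all(np.abs(rhos) <= 1.0)

    def test_sign_heterogeneity_cancels_in_si(self):
        # half the subjects respond positively, half negatively: SD sees
        # strong mixed-sign coefficients, SI pools to ~zero
        rng = np.random.default_rng(6)
        frames = []
        for j in range(10):
            rating = rng.uniform(1, 9, 28)
            sign = 1 if j % 2 == 0 else -1
            frames.append(
                pd.DataFrame(
                    {"subject": f"S{j:02d}", "valence_rating": rating,
                     "f": sign * rating + 0.3 * rng.normal(size=28)}
                )
            )
        df = pd.concat(frames, ignore_index=True)
        sd = v.feature_valence_correlation(df, ["f"], mode="SD")
        si = v.feature_valence_correlation(df, ["f"], mode="SI")
        assert (sd["rho"] > 0.8).sum() == 5
        assert (sd["rho"] < -0.8).sum() == 5
        assert abs(si["rho"].iloc[0]) < 0.2

    def test_constant_feature_missing(self):
        df = pd.DataFrame(
            {"subject": "S01", "valence_rating": np.arange(10.0), "f": 1.0}
        )
        out = v.feature_valence_correlation(df, ["f"], mode="SI")
        assert np.isnan(out["rho"].iloc[0])


def test_bh_adjustment_monotone():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    adj = bh_adjust(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj) >= 0)
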