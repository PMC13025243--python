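import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegti import bh_fdr, describe, describe_table, pearson_matrix, render_report
from eegti.exceptions import DomainError, InsufficientDataError
from eegti.stats import correlation_long
from eegti.ti import PairedContrast


def bh_stepup_oracle(p_values, q):
    """Direct evaluation of the step-up definition (independent of the
    implementation path): reject the k smallest p-values where k is the
    largest rank with p_(k) <= q*k/m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestDescribe:
    def test_hand_computed_values(self):
        d = describe([1, 2, 3, 4])
        assert d.mean == 2.5
        assert d.sd == pytest.approx(1.2910, abs=5e-5)
        assert d.median == 2.5
        assert d.n == 4

    def test_constant_vector_flagged_not_thrown(self):
        d = describe([3.0, 3.0, 3.0])
        assert d.sd == 0 and d.degenerate
        assert np.isnan(d.skewness)

    def test_missing_values_excluded(self):
        d = describe([5.0, np.nan, 7.0])
        assert d.n == 2 and d.mean == 6.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            describe([1.0, np.nan])

    def test_matches_naive_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.lognormal(1.0, 0.8, size=rng.integers(5, 60))
            d = describe(x)
            n = len(x)
            mean = x.sum() / n
            sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
            z3 = (((x - mean) / sd) ** 3).sum()
            g1 = n / ((n - 1) * (n - 2)) * z3  # SPSS-adjusted skewness
            z4 = (((x - mean) / sd) ** 4).sum()
            g2 = (
                n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * z4
                - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
            )
            assert d.mean == pytest.approx(mean, rel=1e-12)
            assert d.sd == pytest.approx(sd, rel=1e-12)
            assert d.skewness == pytest.approx(g1, rel=1e-10)
            assert d.excess_kurtosis == pytest.approx(g2, rel=1e-10)

    def test_describe_table_right_skewed_power(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"delta": rng.lognormal(9.0, 0.6, 39)})
        out = describe_table(df)
        assert out.loc[0, "skewness"] > 0  # raw power is right-skewed


class TestBhFdr:
    def test_textbook_vector(self):
        reject, adjusted = bh_fdr([0.001, 0.02, 0.03, 0.04, 0.5], q=0.05)
        assert reject.tolist() == [True, True, True, True, False]
        assert np.all(adjusted[:4] <= 0.05)

    def test_all_ones_keep_everything(self):
        reject, _ = bh_fdr([1.0] * 6)
        assert not reject.any()

    def test_single_test_reduces_to_threshold(self):
        reject, _ = bh_fdr([0.04], q=0.05)
        assert reject.tolist() == [True]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.2])

    def test_flags_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        reject, _ = bh_fdr(p, q=0.1)
        if reject.any():
            assert reject[p <= p[reject].max()].all()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_agrees_with_stepup_oracle_on_arbitrary_vectors(self, p, q):
        reject, adjusted = bh_fdr(p, q=q)
        assert reject.tolist() == bh_stepup_oracle(p, q).tolist()
        assert np.all((adjusted >= np.asarray(p) - 1e-12) & (adjusted <= 1.0))

    def test_agrees_with_stepup_oracle_exhaustively(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 1.0]
        for length in range(1, 5):
            for combo in itertools.combinations_with_replacement(grid, length):
                reject, _ = bh_fdr(list(combo), q=0.05)
                expected = bh_stepup_oracle(combo, q=0.05)
                assert reject.tolist() == expected.tolist(), combo


class TestPearsonMatrix:
    def _df(self, n=60, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=n)})

    def test_self_and_anti_correlation(self):
        rep = pearson_matrix(self._df(), "fam")
        assert rep.r.loc["x", "x"] == 1.0
        assert rep.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_symmetry_and_bounds(self):
        rep = pearson_matrix(self._df(), "fam")
        pd.testing.assert_frame_equal(rep.r, rep.r.T)
        assert (rep.r.abs() <= 1).all().all()

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(12)
        rho, n = 0.6, 500
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        rep = pearson_matrix(pd.DataFrame({"x": x, "y": y}), "fam")
        assert 0.52 <= rep.r.loc["x", "y"] <= 0.67

    def test_pairwise_deletion_counts(self):
        df = self._df(n=39)
        df.loc[5, "z"] = np.nan  # one missing observation
        rep = pearson_matrix(df, "fam")
        assert rep.n.loc["x", "y"] == 39
        assert rep.n.loc["x", "z"] == 38

    def test_sparse_pair_marked_unavailable(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.0, np.nan, np.nan]}
        )
        rep = pearson_matrix(df, "fam")
        assert np.isnan(rep.r.loc["x", "y"])
        assert not rep.fdr_flags.loc["x", "y"]

    def test_joint_permutation_invariance(self):
        df = self._df()
        perm = np.random.default_rng(0).permutation(len(df))
        rep1 = pearson_matrix(df, "fam")
        rep2 = pearson_matrix(df.iloc[perm].reset_index(drop=True), "fam")
        pd.testing.assert_frame_equal(rep1.r, rep2.r)


class TestReporting:
    def test_marker_distinguishes_fdr_from_nominal(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.normal(size=n)
        strong = x + 0.3 * rng.normal(size=n)
        weak = 0.35 * x + rng.normal(size=n)
        rep = pearson_matrix(
            pd.DataFrame({"x": x, "strong": strong, "weak": weak}), "fam"
        )
        long = correlation_long(rep)
        markers = set(long["marker"])
        assert "**fdr" in markers

    def test_render_report_round_trip(self, tmp_path):
        desc = describe_table(pd.DataFrame({"a": np.arange(10.0)}))
        rep = pearson_matrix(self._null_df(), "fam")
        contrast = PairedContrast(n=10, t=2.0, df=9, p=0.07, d=0.63,
                                  d_ci=(0.0, 1.3))
        written = render_report(
            tmp_path, descriptives=desc, correlations=[rep],
            contrast=contrast, metadata={"seed": 0},
        )
        names = {p.name for p in written}
        assert {"descriptives.tsv", "correlations_fam.tsv", "contrast.tsv",
                "run_metadata.json"} <= names
        back = pd.read_csv(tmp_path / "contrast.tsv", sep="\t")
        assert back.loc[0, "t"] == 2.0

    def test_empty_family_omitted_with_notice(self, tmp_path):
        rep = pearson_matrix(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), "solo")
        written = render_report(tmp_path, correlations=[rep])
        assert not (tmp_path / "correlations_solo.tsv").exists()
        meta = (tmp_path / "run_metadata.json").read_text()
        assert "omitted" in meta

    @staticmethod
    def _null_df():
        rng = np.random.default_rng(9)
        return pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
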