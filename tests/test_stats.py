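import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calvaria.phantom import PhantomSpec
from calvaria.stats import (
    RatingsTable,
    icc_absolute_agreement,
    retest_reliability_experiment,
    spearman_holm,
)


def anova_oracle(x: np.ndarray):
    """Two-way ANOVA mean squares by explicit double loops (oracle path)."""
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    ssr = ssc = sst = 0.0
    for i in range(n):
        row_mean = sum(x[i, j] for j in range(k)) / k
        ssr += k * (row_mean - grand) ** 2
    for j in range(k):
        col_mean = sum(x[i, j] for i in range(n)) / n
        ssc += n * (col_mean - grand) ** 2
    for i in range(n):
        for j in range(k):
            sst += (x[i, j] - grand) ** 2
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_columns(self):
        x = np.tile(np.arange(1.0, 11.0)[:, None], (1, 2))
        res = icc_absolute_agreement(RatingsTable(x))
        assert res.icc == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_agreement_destroyed_by_noise(self):
        rng = np.random.default_rng(0)
        subj = rng.normal(size=50)
        x = np.stack([subj, subj + rng.normal(scale=50.0, size=50)], axis=1)
        res = icc_absolute_agreement(RatingsTable(x))
        assert abs(res.icc) < 0.2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        k = int(rng.integers(2, 4))
        x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * rng.uniform(0.5, 3)
        res = icc_absolute_agreement(RatingsTable(x))
        assert res.icc == pytest.approx(anova_oracle(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        n, k = 12, 2
        x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
        res = icc_absolute_agreement(RatingsTable(x))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "y": x.ravel(),
            }
        )
        row = (
            pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
        assert res.p_value == pytest.approx(row["pval"], abs=1e-8)
        assert res.ci_low == pytest.approx(row["CI95"][0], abs=0.01)
        assert res.ci_high == pytest.approx(row["CI95"][1], abs=0.01)

    @given(
        st.integers(min_value=0, max_value=1000),
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.1, max_value=50),
    )
    @settings(max_examples=25, deadline=None)
    def test_location_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 2
        a = icc_absolute_agreement(RatingsTable(x)).icc
        b = icc_absolute_agreement(RatingsTable(x * scale + shift)).icc
        assert a == pytest.approx(b, abs=1e-8)

    def test_zero_between_subject_variance_flagged(self):
        x = np.ones((10, 2))
        res = icc_absolute_agreement(RatingsTable(x))
        assert res.icc == 0.0
        assert "zero_between_subject_variance" in res.flags

    def test_incomplete_rows_dropped(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        x[3, 1] = np.nan
        table = RatingsTable(x)
        assert table.n == 9
        assert table.n_dropped == 1

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            RatingsTable(np.ones((2, 2)))


class TestSpearmanHolm:
    def test_monotone(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 3})
        panel = spearman_holm(df, [("x", "y")])
        assert panel.rho.iloc[0] == pytest.approx(1.0)

    def test_antitone(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        panel = spearman_holm(df, [("x", "y")])
        assert panel.rho.iloc[0] == pytest.approx(-1.0)

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        panel = spearman_holm(df, [("x", "y")])
        assert np.isnan(panel.rho.iloc[0])
        assert "constant_variable" in panel["flags"].iloc[0]

    def test_holm_step_down_arithmetic(self):
        # raw (0.01, 0.02, 0.04) -> holm (0.03, 0.04, 0.04)
        from statsmodels.stats.multitest import multipletests

        _, p_holm, _, _ = multipletests([0.01, 0.02, 0.04], method="holm")
        assert np.allclose(p_holm, [0.03, 0.04, 0.04])

    def test_holm_monotone_and_capped(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        pairs = list(itertools.combinations("abcd", 2))
        panel = spearman_holm(df, pairs)
        assert (panel.p_holm >= panel.p_raw - 1e-12).all()
        assert (panel.p_holm <= 1.0).all()
        order = panel.p_raw.argsort()
        assert (np.diff(panel.p_holm.to_numpy()[order]) >= -1e-12).all()

    def test_exact_permutation_small_n(self):
        # perfect monotone with n=5: exact two-sided p = 2/5! = 1/60
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0], "y": [2.0, 4.0, 5.0, 7.0, 9.0]})
        panel = spearman_holm(df, [("x", "y")])
        assert panel.p_raw.iloc[0] == pytest.approx(2 / 120)

    def test_too_few_pairs_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        panel = spearman_holm(df, [("x", "y")])
        assert "too_few_pairs" in panel["flags"].iloc[0]


@pytest.fixture(scope="module")
def tiny_base():
    return PhantomSpec(
        shape=(64, 64, 64),
        brain_radii=(15.0, 14.0, 13.0),
        noise_sd=0.0,
        open_inferior=True,
    )


class TestRetestExperiment:
    def test_noise_free_perfect_icc(self, tiny_base):
        table = retest_reliability_experiment(
            tiny_base, n_subjects=10, seed=3, corruption_fraction=0.0
        )
        assert (table.icc > 0.999).all()

    def test_determinism(self, tiny_base):
        a = retest_reliability_experiment(
            tiny_base, n_subjects=10, seed=3, corruption_fraction=0.0
        )
        b = retest_reliability_experiment(
            tiny_base, n_subjects=10, seed=3, corruption_fraction=0.0
        )
        pd.testing.assert_frame_equal(a, b)

    def test_protocol_shift_degrades_intensity_icc_only(self, tiny_base):
        # sessions differ only by a global intensity offset: WM-normalized
        # intensity measures lose agreement, thickness measures do not
        table = retest_reliability_experiment(
            tiny_base,
            n_subjects=10,
            seed=3,
            corruption_fraction=0.0,
            protocol_shift_sd=80.0,
        ).set_index("measure")
        assert table.loc["bone_thickness_mm", "icc"] == pytest.approx(1.0)
        assert table.loc["tap_mm", "icc"] == pytest.approx(1.0)
        assert table.loc["proxy_bmd", "icc"] < 0.999

    def test_minimum_subjects(self, tiny_base):
        with pytest.raises(ValueError):
            retest_reliability_experiment(tiny_base, n_subjects=5, seed=1)
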