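import numpy as np
import pytest

from emonet.exceptions import DegenerateSignalError
from emonet.stats import (
    bonferroni,
    chi_square_2x2,
    paired_t,
    pearson_p_from_r,
    pearson_r,
    rm_anova,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        x = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        y = np.array([3.0, 3.8, 4.1, 3.5])
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        res = two_sample_t(x, y, pooled=True)
        assert res.statistic == pytest.approx(t_hand, abs=1e-6)
        assert res.df == (nx + ny - 2,)

    def test_sign_tracks_shift(self):
        x = np.array([1.0, 2.0, 3.0, 2.5])
        assert two_sample_t(x + 1.0, x).statistic > 0
        assert two_sample_t(x - 1.0, x).statistic < 0

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateSignalError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestPairedT:
    def test_zero_difference_variance_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateSignalError):
            paired_t(x, x.copy())

    def test_sixteen_pairs_give_df_15(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=16), rng.normal(size=16)
        assert paired_t(x, y).df == (15.0,)

    def test_matches_hand_computation_with_cohens_d(self):
        x = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        y = np.array([8.0, 11.0, 10.0, 11.0, 9.0, 10.0])
        diff = x - y
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        d_hand = diff.mean() / diff.std(ddof=1)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.effect_size == pytest.approx(d_hand, abs=1e-10)


class TestRmAnova:
    def test_16_subjects_3_conditions_give_df_2_30(self):
        """16 subjects x 3 conditions -> F df (2, 30)."""
        rng = np.random.default_rng(1)
        res = rm_anova(rng.normal(size=(16, 3)))
        assert res.df == (2.0, 30.0)

    def test_partial_eta_squared_identity(self):
        """eta_p^2 == F*df1 / (F*df1 + df2) algebraically; e.g.
        F(2,30) = 10.02 corresponds to 0.40."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            table = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1))
            res = rm_anova(table)
            f, (df1, df2) = res.statistic, res.df
            assert res.effect_size == pytest.approx(
                f * df1 / (f * df1 + df2), abs=1e-12
            )
        assert 10.02 * 2 / (10.02 * 2 + 30) == pytest.approx(0.40, abs=0.005)

    def test_subject_offsets_without_condition_effect_give_zero_f(self):
        table = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        res = rm_anova(table)
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    def test_matches_pingouin(self):
        """Cross-check F, df, p and partial eta squared against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        wide = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "condition": np.tile(["a", "b", "c"], 12),
                "value": wide.ravel(),
            }
        )
        pg = pingouin.rm_anova(
            data=long, dv="value", within="condition", subject="subject",
            effsize="np2",
        )
        res = rm_anova(wide)
        assert res.statistic == pytest.approx(float(pg["F"][0]), rel=1e-9)
        assert res.p_two_tailed == pytest.approx(float(pg["p_unc"][0]), rel=1e-9)
        assert res.effect_size == pytest.approx(float(pg["np2"][0]), rel=1e-9)
        assert res.df == (float(pg["ddof1"][0]), float(pg["ddof2"][0]))

    def test_missing_cells_rejected(self):
        bad = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            rm_anova(bad)


class TestPearson:
    def test_perfect_linear_data(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_r_053_significant_at_n_16(self):
        """r = 0.53 with 16 patients is significant two-tailed at 5%."""
        assert pearson_p_from_r(0.53, 16) < 0.05
        assert pearson_p_from_r(0.30, 16) > 0.05

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = pearson_r(x, y)
        r_hand = np.corrcoef(x, y)[0, 1]
        assert res.statistic == pytest.approx(r_hand, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(
            pearson_p_from_r(r_hand, 20), abs=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_gender_count_table(self):
        """10/6 vs 4/10 males/females reproduces chi2 = 3.45."""
        res = chi_square_2x2([[10, 6], [4, 10]])
        assert res.statistic == pytest.approx(3.45, abs=0.005)
        assert res.df == (1.0,)

    def test_independent_table_gives_zero(self):
        assert chi_square_2x2([[5, 5], [5, 5]]).statistic == 0.0

    def test_matches_hand_computed_expecteds(self):
        t = np.array([[12.0, 8.0], [7.0, 13.0]])
        row, col, n = t.sum(axis=1), t.sum(axis=0), t.sum()
        expected = np.outer(row, col) / n
        chi2_hand = ((t - expected) ** 2 / expected).sum()
        assert chi_square_2x2(t).statistic == pytest.approx(chi2_hand, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestBonferroni:
    def test_scaling_and_clamping(self):
        assert bonferroni([0.01], family_size=3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], family_size=3) == [1.0]

    def test_family_smaller_than_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], family_size=2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], family_size=2)


class TestTypeOneErrorCalibration:
    """Each test keeps its nominal 5% size under its own null."""

    N_REPS = 2000
    BAND = (0.035, 0.065)

    def _rate(self, pvals):
        rate = np.mean(np.asarray(pvals) < 0.05)
        lo, hi = self.BAND
        assert lo <= rate <= hi, f"empirical size {rate}"

    def test_two_sample_t_size(self):
        rng = np.random.default_rng(10)
        self._rate(
            [
                two_sample_t(rng.normal(size=15), rng.normal(size=15)).p_two_tailed
                for _ in range(self.N_REPS)
            ]
        )

    def test_paired_t_size(self):
        rng = np.random.default_rng(11)
        self._rate(
            [
                paired_t(rng.normal(size=16), rng.normal(size=16)).p_two_tailed
                for _ in range(self.N_REPS)
            ]
        )

    def test_rm_anova_size(self):
        rng = np.random.default_rng(12)
        self._rate(
            [
                rm_anova(
                    rng.normal(size=(16, 3)) + rng.normal(size=(16, 1))
                ).p_two_tailed
                for _ in range(self.N_REPS)
            ]
        )

    def test_pearson_size(self):
        rng = np.random.default_rng(13)
        self._rate(
            [
                pearson_r(rng.normal(size=16), rng.normal(size=16)).p_two_tailed
                for _ in range(self.N_REPS)
            ]
        )
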