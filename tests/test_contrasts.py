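import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from selset import fixtures
from selset.contrasts import (
    bonferroni_tcrit,
    classify_cells,
    enhancement_test,
    infer_polarity,
    min_sig_diff,
    omnibus_anova,
    t_critical,
)
from selset.head_model import DEFAULT_LABELS
from selset.synthetic import GeneratorConfig, generate_epochs
from selset.vincent import BinTable, vincentize_epochs

from conftest import anova_oracle


def bin_table_from(y: np.ndarray) -> BinTable:
    """(group, unit, electrode, condition) array -> BinTable layout."""
    per_subject = np.transpose(y, (1, 3, 2, 0))
    g = y.shape[0]
    return BinTable(
        subjects=[f"S{i}" for i in range(y.shape[1])],
        conditions=["target", "distractor"][: y.shape[3]],
        electrodes=[f"E{i}" for i in range(y.shape[2])],
        bin_edges=np.arange(g + 1) * 100.0,
        per_subject=per_subject,
    )


class TestOmnibusAnova:
    def test_zero_variance(self):
        table = bin_table_from(np.full((2, 3, 2, 2), 1.25))
        res = omnibus_anova(table)
        assert np.allclose(res.table["ss"], 0.0)
        assert res.mse_within == 0.0

    def test_toy_hand_decomposition(self):
        # one group, two units; unit 1: E1 (1,3), E2 (2,6); unit 2: E1 (2,4),
        # E2 (1,5).  Grand mean 3; electrode means 2.5/3.5 -> SS_E = 4*(0.25+
        # 0.25) = 2; condition means 1.5/4.5 -> SS_C = 4*(2.25+2.25) = 18.
        y = np.array([[[[1.0, 3.0], [2.0, 6.0]], [[2.0, 4.0], [1.0, 5.0]]]])
        res = omnibus_anova(bin_table_from(y))
        assert res.table.loc["electrode", "ss"] == pytest.approx(2.0)
        assert res.table.loc["condition", "ss"] == pytest.approx(18.0)
        assert res.table.loc["electrode:condition", "ss"] == pytest.approx(2.0)
        assert res.table.loc["electrode:subject(bin)", "ss"] == pytest.approx(2.0)
        assert res.table.loc["condition:subject(bin)", "ss"] == pytest.approx(0.0)
        assert res.table.loc[
            "electrode:condition:subject(bin)", "ss"
        ] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g, n, a, c = rng.integers(1, 4), rng.integers(2, 5), rng.integers(2, 5), 2
        y = rng.normal(size=(g, n, a, c))
        res = omnibus_anova(bin_table_from(y))
        expected = anova_oracle(y)
        for name, ss in expected.items():
            assert res.table.loc[name, "ss"] == pytest.approx(ss, abs=1e-8), name

    def test_df_bookkeeping(self):
        y = np.zeros((3, 4, 5, 2))
        res = omnibus_anova(bin_table_from(y))
        total_df = int(res.table["df"].sum())
        assert total_df == y.size - 1
        assert res.table.loc["electrode:condition:subject(bin)", "df"] == 3 * 3 * 4 * 1

    def test_unbalanced_rejected(self):
        y = np.zeros((2, 2, 2, 2))
        table = bin_table_from(y)
        table.per_subject[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            omnibus_anova(table)


class TestThreshold:
    def test_reference_tcrit(self):
        assert t_critical(0.0001, 12) == pytest.approx(5.69, abs=0.01)

    def test_normal_limit(self):
        assert t_critical(0.05, 10000) == pytest.approx(1.96, abs=0.005)

    def test_cauchy_quartile(self):
        assert t_critical(0.5, 1) == pytest.approx(1.0, abs=1e-9)

    def test_bonferroni_divides_alpha(self):
        assert bonferroni_tcrit(0.0012, 12, 12) == pytest.approx(
            t_critical(0.0001, 12)
        )

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            t_critical(0.05, 0)

    def test_reference_min_sig_diff(self):
        got = min_sig_diff(5.69, 0.132, (1.0, -1.0), 13)
        assert got == pytest.approx(0.80, abs=0.02)

    def test_zero_mse(self):
        assert min_sig_diff(5.69, 0.0, (1.0, -1.0), 13) == 0.0

    def test_hand_arithmetic(self):
        assert min_sig_diff(2.0, 0.5, (1.0, -1.0), 4) == pytest.approx(1.0)

    def test_negative_mse_rejected(self):
        with pytest.raises(ValueError):
            min_sig_diff(2.0, -0.1, (1.0, -1.0), 4)

    def test_nonzero_sum_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            min_sig_diff(2.0, 1.0, (1.0, -0.5), 4)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_homogeneous_in_contrast_weights(self, scale):
        base = min_sig_diff(3.0, 0.7, (1.0, -1.0), 8)
        scaled = min_sig_diff(3.0, 0.7, (scale, -scale), 8)
        assert scaled == pytest.approx(abs(scale) * base, rel=1e-12)


class TestClassify:
    def test_all_zero_differences(self):
        diffs = np.zeros((12, 7))
        sig = classify_cells(diffs, 0.8, np.ones((12, 7)))
        assert sig.counts() == (0, 0)

    def test_worked_example_counts(self, worked_example_sig):
        n_t, n_d = worked_example_sig.counts()
        assert n_d == 5
        assert n_t == 50

    def test_worked_example_flags_match_labels(self, worked_example_sig):
        table = fixtures.enhancement_table()
        for row in table.itertuples(index=False):
            i = list(DEFAULT_LABELS).index(row.electrode)
            assert worked_example_sig.flags[i, row.bin - 1] == row.label

    def test_single_positive_cell(self):
        diffs = np.zeros((3, 7))
        diffs[1, 2] = 1.0
        sig = classify_cells(diffs, 0.8, np.ones((3, 7)))
        assert sig.flags[1, 2] == "T"
        assert (sig.flags != "").sum() == 1

    def test_negative_peak_interpretation(self):
        diffs = np.array([[-1.0]])
        pol = np.array([[-1.0]])
        sig = classify_cells(diffs, 0.8, pol, window_ms=(0.0, 100.0))
        assert sig.flags[0, 0] == "T"  # more negative at a negative peak

    def test_missing_polarity_for_significant_cell(self):
        diffs = np.array([[1.0]])
        with pytest.raises(ValueError, match="polarity"):
            classify_cells(diffs, 0.5, np.array([[0.0]]), window_ms=(0.0, 100.0))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_cells(np.zeros((1, 1)), -0.1, np.ones((1, 1)))


class TestEnhancementChi2:
    def test_reference_value(self):
        chi2, p = enhancement_test(46, 5, 84)
        assert chi2 == pytest.approx(45.05, abs=0.05)
        assert p < 0.0001

    def test_equal_counts_give_zero(self):
        chi2, _ = enhancement_test(10, 10, 84)
        assert chi2 == 0.0

    def test_textbook_oracle(self):
        # frozen from the independent textbook-formula computation
        chi2, _ = enhancement_test(20, 5, 40)
        assert chi2 == pytest.approx(11.403636363636364, rel=1e-12)

    def test_matches_scipy_contingency(self):
        for n_t, n_d, n in [(46, 5, 84), (20, 5, 40), (9, 3, 20)]:
            chi2, p = enhancement_test(n_t, n_d, n)
            ref = chi2_contingency(
                [[n_t, n - n_t], [n_d, n - n_d]], correction=True
            )
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetric_in_rows(self):
        assert enhancement_test(30, 7, 84)[0] == pytest.approx(
            enhancement_test(7, 30, 84)[0]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            enhancement_test(0, 0, 84)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            enhancement_test(90, 5, 84)


class TestPolarity:
    def test_dominant_sign(self):
        table = BinTable(
            subjects=["a", "b"],
            conditions=["target", "distractor"],
            electrodes=["E1"],
            bin_edges=[0.0, 100.0],
            per_subject=np.array(
                [[[[3.0]], [[-1.0]]], [[[3.0]], [[-1.0]]]]
            ),
        )
        assert infer_polarity(table)[0, 0] == 1.0

    def test_negative_dominant(self):
        table = BinTable(
            subjects=["a", "b"],
            conditions=["target", "distractor"],
            electrodes=["E1"],
            bin_edges=[0.0, 100.0],
            per_subject=np.array(
                [[[[-3.0]], [[1.0]]], [[[-3.0]], [[1.0]]]]
            ),
        )
        assert infer_polarity(table)[0, 0] == -1.0


class TestRecoveryAndCalibration:
    def test_parameter_recovery_single_hotspot(self):
        enhancement = np.zeros((12, 7))
        pz = list(DEFAULT_LABELS).index("Pz")
        enhancement[pz, 6] = 3.0  # +3 uV at Pz in the 601-700 ms bin
        cfg = GeneratorConfig(
            sampling_rate=200.0,
            enhancement=enhancement,
            noise_sd=0.3,
            noise_phi=0.3,
        )
        epochs = generate_epochs(cfg, seed=21)
        bins = vincentize_epochs(epochs)
        res = omnibus_anova(bins)
        window = bins.window(0.0, 700.0)
        tcrit = bonferroni_tcrit(0.05, 12, 12)
        threshold = min_sig_diff(tcrit, res.mse_within, (1.0, -1.0), 13)
        sig = classify_cells(bins, threshold, infer_polarity(window))
        assert sig.flags[pz, 6] == "T"
        assert sig.counts() == (1, 0)

    def test_type_one_calibration_on_null_data(self):
        # across >= 200 seeded null runs the flagged-cell fraction must not
        # exceed the per-cell Bonferroni-corrected alpha beyond Monte-Carlo
        # error
        n_runs = 200
        alpha_cell = 0.05 / 12
        flagged = 0
        total = 0
        cfg = GeneratorConfig(
            sampling_rate=100.0,
            enhancement=np.zeros((12, 7)),
            noise_phi=0.0,
            noise_sd=1.0,
            subject_sd=0.5,
        )
        for seed in range(n_runs):
            epochs = generate_epochs(cfg, seed=seed)
            bins = vincentize_epochs(epochs)
            res = omnibus_anova(bins)
            df_err = int(res.table.loc["electrode:condition:subject(bin)", "df"])
            tcrit = bonferroni_tcrit(0.05, 12, df_err)
            threshold = min_sig_diff(tcrit, res.mse_within, (1.0, -1.0), 13)
            window = bins.window(0.0, 700.0)
            sig = classify_cells(bins, threshold, infer_polarity(window))
            n_t, n_d = sig.counts()
            flagged += n_t + n_d
            total += len(sig.electrodes) * sig.n_bins
        fraction = flagged / total
        mc_err = 3.0 * np.sqrt(alpha_cell * (1 - alpha_cell) / total)
        assert fraction <= alpha_cell + mc_err
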