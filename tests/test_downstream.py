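"""Diagnosis/age probes and the exact statistics behind them."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from brainid.downstream import (
    evaluate_age,
    evaluate_diagnosis,
    fit_age,
    fit_diagnosis,
    pearson_test,
    predict_age,
    predict_diagnosis,
    run_experiment3,
    sign_test,
)
from brainid.features import IdentitySet


def _ids(values, sids=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    sids = sids or [f"s{i}" for i in range(n)]
    return IdentitySet(values=values, subject_ids=np.array(sids, dtype=object),
                       n_averaged=np.ones(n, dtype=int))


def exact_binomial_upper_tail(k: int, n: int) -> Fraction:
    """Independent oracle: rational-arithmetic enumeration of P(X >= k)."""
    return sum(
        (Fraction(comb(n, j)) / Fraction(2) ** n for j in range(k, n + 1)),
        Fraction(0),
    )


class TestSignTest:
    def test_fourteen_of_eighteen(self):
        assert sign_test(14, 18) == pytest.approx(0.015, abs=5e-4)

    def test_thirteen_of_eighteen(self):
        assert sign_test(13, 18) == pytest.approx(0.048, abs=5e-4)

    def test_all_correct_closed_form(self):
        assert sign_test(18, 18) == pytest.approx(2.0**-18, rel=1e-9)

    def test_zero_correct_is_one(self):
        assert sign_test(0, 18) == 1.0

    @pytest.mark.parametrize("n", range(1, 26))
    def test_matches_rational_enumeration(self, n):
        """Exact-rational binomial oracle for every (k, n) with n <= 25."""
        for k in range(n + 1):
            expected = float(exact_binomial_upper_tail(k, n))
            assert sign_test(k, n) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_n_correct(self):
        ps = [sign_test(k, 20) for k in range(21)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sign_test(5, 4)


class TestPearson:
    def test_identical_vectors_r_one(self):
        r, _ = pearson_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_r057_n18_p_near_0013(self):
        """r = 0.57 at n = 18 corresponds to p ~ 0.013-0.014 two-sided."""
        rng = np.random.default_rng(0)
        # construct an n=18 pair with sample correlation exactly 0.57
        x = rng.standard_normal(18)
        y = rng.standard_normal(18)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)  # orthogonalize
        y /= y.std()
        target = 0.57
        z = target * x + np.sqrt(1 - target**2) * y
        r, p = pearson_test(z, x)
        assert r == pytest.approx(0.57, abs=1e-12)
        assert 0.012 <= p <= 0.015

    def test_matches_t_transform_formula(self):
        """Oracle: p from t = r sqrt(n-2)/sqrt(1-r^2) on a 5-point dataset."""
        from scipy import stats

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.2, 1.9, 3.4, 3.6, 5.5])
        r, p = pearson_test(x, y)
        r_hand = np.corrcoef(x, y)[0, 1]
        t = r_hand * np.sqrt(3) / np.sqrt(1 - r_hand**2)
        p_hand = 2 * stats.t.sf(abs(t), df=3)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestDiagnosisModel:
    def test_separable_data_perfect_training_accuracy(self):
        ids = _ids([[-2, 0], [-1, 0], [1, 0], [2, 0]])
        groups = ["control", "control", "patient", "patient"]
        model = fit_diagnosis(ids, groups)
        assert list(predict_diagnosis(model, ids)) == groups

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_diagnosis(_ids([[1], [2]]), ["patient", "patient"])

    def test_deterministic_refit(self):
        rng = np.random.default_rng(1)
        ids = _ids(rng.standard_normal((10, 4)))
        groups = ["patient"] * 5 + ["control"] * 5
        m1 = fit_diagnosis(ids, groups)
        m2 = fit_diagnosis(ids, groups)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_shuffled_labels_near_chance(self):
        """Null: permuted labels give test accuracy within binomial noise of 0.5."""
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(20):
            x = rng.standard_normal((36, 5))
            groups = np.array(["patient"] * 18 + ["control"] * 18)
            rng.shuffle(groups)
            model = fit_diagnosis(_ids(x[:18]), groups[:18])
            pred = predict_diagnosis(model, _ids(x[18:]))
            accs.append(np.mean(pred == groups[18:]))
        # mean of 20 replicates of Bin(18, .5)/18: SE ~ 0.026
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_sign_rule_and_tie_to_control(self):
        from brainid.downstream import LinearModel

        model = LinearModel(weights=[1.0, 0.0], intercept=0.0,
                            task="diagnosis", loss="logistic")
        preds = predict_diagnosis(model, _ids([[2, 9], [-2, 9], [0, 9]]))
        assert list(preds) == ["patient", "control", "control"]


class TestAgeModel:
    def test_exact_linear_recovery_without_regularization(self):
        ids = _ids([[1.0], [2.0], [3.0], [4.0]])
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        model = fit_age(ids, ages, alpha=0.0)
        assert model.weights[0] == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(predict_age(model, ids), ages, atol=1e-7)

    def test_noise_features_no_test_correlation(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(10):
            x = rng.standard_normal((36, 4))
            ages = rng.uniform(20, 60, 36)
            model = fit_age(_ids(x[:18]), ages[:18])
            r, _ = pearson_test(predict_age(model, _ids(x[18:])), ages[18:])
            rs.append(r)
        assert abs(np.mean(rs)) < 0.25

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        ids = _ids(rng.standard_normal((8, 3)))
        ages = rng.uniform(20, 60, 8)
        np.testing.assert_array_equal(fit_age(ids, ages).weights,
                                      fit_age(ids, ages).weights)


def _cohort(n=12):
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["patient"] * (n // 2) + ["control"] * (n // 2),
            "age": rng.uniform(20, 60, n).round(1),
            "sex": ["m"] * n,
        }
    )


class TestRunExperiment3:
    def test_signal_vs_noise_features(self):
        """Group-informative features reach p < 0.05; pure noise does not."""
        rng = np.random.default_rng(6)
        cohort = _cohort(40)
        groups = cohort.set_index("subject_id")["group"]
        train_ids = [f"s{i}" for i in list(range(10)) + list(range(20, 30))]
        test_ids = [f"s{i}" for i in list(range(10, 20)) + list(range(30, 40))]
        all_ids = train_ids + test_ids
        signal = np.array(
            [[3.0 if groups[s] == "patient" else -3.0, 0.0] for s in all_ids]
        ) + rng.standard_normal((40, 2))
        noise = rng.standard_normal((40, 2))
        table = run_experiment3(
            {"signal": _ids(signal, all_ids), "noise": _ids(noise, all_ids)},
            cohort, train_ids, test_ids, tasks=("diagnosis",),
        )
        p = table.set_index("method")["p_value"]
        assert p["signal"] < 0.05
        assert p["noise"] > 0.05

    def test_empty_method_list_empty_table(self):
        table = run_experiment3({}, _cohort(), ["s0", "s6"], ["s1", "s7"])
        assert len(table) == 0
        assert list(table.columns) == ["method", "task", "n_test", "metric",
                                       "statistic", "p_value"]

    def test_accuracy_times_n_is_integer(self):
        rng = np.random.default_rng(7)
        cohort = _cohort(12)
        ids = _ids(rng.standard_normal((12, 3)), list(cohort["subject_id"]))
        res = evaluate_diagnosis(ids, cohort, ["s0", "s1", "s6", "s7"],
                                 ["s2", "s3", "s8", "s9"])
        assert res.metric * res.n_test == pytest.approx(round(res.metric * res.n_test))

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        cohort = _cohort(12)
        ids = _ids(rng.standard_normal((12, 3)), list(cohort["subject_id"]))
        t1 = run_experiment3({"m": ids}, cohort, ["s0", "s1", "s6", "s7"],
                             ["s2", "s3", "s8", "s9"], seed=1)
        t2 = run_experiment3({"m": ids}, cohort, ["s0", "s1", "s6", "s7"],
                             ["s2", "s3", "s8", "s9"], seed=1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_age_task_reports_pearson(self):
        cohort = _cohort(12)
        ages = cohort.set_index("subject_id")["age"]
        ids = _ids([[ages[f"s{i}"]] for i in range(12)],
                   list(cohort["subject_id"]))
        res = evaluate_age(ids, cohort, ["s0", "s1", "s2", "s6", "s7", "s8"],
                           ["s3", "s4", "s5", "s9", "s10", "s11"], alpha=1e-8)
        assert res.metric == pytest.approx(1.0, abs=1e-6)
        assert res.p_value < 1e-6
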