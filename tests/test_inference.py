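"""Feature selection, tuning, classification, regression, PPC."""

import numpy as np
import pandas as pd
import pytest

from ecoassembly import inference
from ecoassembly.inference import (
    MaskMismatchError,
    TrainingTable,
    boruta_select,
    cross_validate,
    estimate_parameters,
    posterior_predictive_check,
    predict_assembly_model,
    train_classifier,
    train_regressor,
    tune_hyperparameters,
)
from ecoassembly.sumstats import STAT_NAMES, SummaryVector


def synthetic_classification_table(n=300, seed=0, informative=2):
    """Rows whose class is encoded in a couple of 'statistic' columns."""
    rng = np.random.default_rng(seed)
    classes = np.array(["neutral", "filtering", "competition"])[
        rng.integers(3, size=n)
    ]
    frame = pd.DataFrame({"model": classes})
    signal = {"neutral": 0.0, "filtering": 2.0, "competition": -2.0}
    base = np.array([signal[c] for c in classes])
    stat_cols = [c for c in STAT_NAMES if c != "S"]
    for j, col in enumerate(stat_cols):
        if j < informative:
            frame[col] = base + rng.normal(0, 0.3, size=n)
        else:
            frame[col] = rng.normal(size=n)
    frame["S"] = rng.integers(5, 50, size=n).astype(float)
    return TrainingTable(
        frame=frame, mask={"abundance": True, "pi": True, "trait": True}
    )


def obs_from_row(row: pd.Series) -> SummaryVector:
    return SummaryVector(
        values=row[STAT_NAMES].astype(float),
        mask={"abundance": True, "pi": True, "trait": True},
    )


class TestBoruta:
    def test_informative_feature_kept_noise_dropped(self):
        rng = np.random.default_rng(1)
        n = 400
        y = rng.normal(size=n)
        X = pd.DataFrame({f"noise_{i}": rng.normal(size=n) for i in range(9)})
        X["signal"] = y + rng.normal(0, 0.1, size=n)
        kept = boruta_select(X, y, task="regress", seed=2, max_iter=25)
        assert "signal" in kept
        dropped = 9 - sum(k.startswith("noise") for k in kept)
        assert dropped >= 8

    def test_constant_column_always_dropped(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({
            "const": np.ones(200),
            "signal": rng.normal(size=200),
        })
        y = X["signal"].to_numpy() + rng.normal(0, 0.1, 200)
        kept = boruta_select(X, y, task="regress", seed=4, max_iter=15)
        assert "const" not in kept

    def test_fixed_seed_identical_retained_set(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(150, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = X["f0"].to_numpy() + rng.normal(0, 0.5, 150)
        k1 = boruta_select(X, y, task="regress", seed=7, max_iter=10)
        k2 = boruta_select(X, y, task="regress", seed=7, max_iter=10)
        assert k1 == k2


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(150, 5)),
                     columns=[f"f{i}" for i in range(5)])
    y = (X["f0"] > 0).astype(int).to_numpy()
    return X, y


class TestTuning:
    def test_single_draw_returns_a_configuration(self, xy):
        X, y = xy
        hp = tune_hyperparameters(X, y, n_draws=1, seed=1)
        assert set(hp) == {"n_estimators", "max_depth", "max_features"}
        assert 100 <= hp["n_estimators"] <= 1000
        assert 2 <= hp["max_depth"] <= 32

    def test_fixed_seed_identical_choice(self, xy):
        X, y = xy
        assert tune_hyperparameters(X, y, n_draws=3, seed=9) == \
            tune_hyperparameters(X, y, n_draws=3, seed=9)


class TestClassifier:
    def test_separable_features_classify_almost_perfectly(self):
        table = synthetic_classification_table(seed=10)
        report = cross_validate(table, task="classify", seed=11)
        assert report["error_rate"] < 0.05

    def test_permuted_labels_give_chance_error(self):
        table = synthetic_classification_table(n=450, seed=12, informative=0)
        report = cross_validate(table, task="classify", seed=13)
        assert report["error_rate"] == pytest.approx(2 / 3, abs=0.08)

    def test_probabilities_sum_to_one_and_mask_enforced(self):
        table = synthetic_classification_table(seed=14)
        est = train_classifier(table, seed=15, select_features=False)
        obs = obs_from_row(table.frame.iloc[0])
        res = predict_assembly_model(est, obs)
        assert sum(res.class_probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.best_class in res.class_probabilities
        obs_masked = SummaryVector(values=obs.values,
                                   mask={"abundance": True, "pi": False, "trait": True})
        with pytest.raises(MaskMismatchError):
            predict_assembly_model(est, obs_masked)

    def test_confusion_matrix_rows_sum_to_one(self):
        table = synthetic_classification_table(seed=16)
        report = cross_validate(table, task="classify", seed=17)
        sums = report["confusion"].sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0)


class TestRegressor:
    def test_duplicated_target_recovered_with_tight_interval(self):
        rng = np.random.default_rng(18)
        table = synthetic_classification_table(n=400, seed=18, informative=0)
        table.frame["theta"] = rng.uniform(0, 1, size=len(table.frame))
        # leak the target into a feature, noiselessly
        table.frame["abund_mean"] = table.frame["theta"]
        regs = train_regressor(table, ["theta"], seed=19, select_features=False)
        report = cross_validate(table, task="regress", targets=["theta"], seed=20)
        assert report["r2"]["theta"] > 0.95
        obs = obs_from_row(table.frame.iloc[5])
        res = estimate_parameters(regs, obs)
        lo, point, hi = res.estimates["theta"]
        assert lo <= point <= hi
        assert hi - lo < 0.2
        assert point == pytest.approx(table.frame["theta"].iloc[5], abs=0.05)

    def test_interval_coverage_near_nominal(self):
        """y = f(x) + noise: 95% leaf-pool intervals should cover ~95% of
        held-out cases."""
        rng = np.random.default_rng(21)
        n = 700
        x = rng.uniform(-2, 2, size=(n, 3))
        y = np.sin(x[:, 0]) + 0.5 * x[:, 1] + rng.normal(0, 0.3, n)
        cols = ["abund_mean", "abund_std", "abund_skew"]
        frame = pd.DataFrame(x, columns=cols)
        frame["model"] = "neutral"
        frame["theta"] = y
        table = TrainingTable(frame=frame.iloc[:500].reset_index(drop=True),
                              mask={"abundance": True, "pi": False, "trait": False})
        regs = train_regressor(table, ["theta"], seed=22, select_features=False)
        covered = 0
        held = frame.iloc[500:]
        for _, row in held.iterrows():
            obs = SummaryVector(values=row.reindex(STAT_NAMES).astype(float),
                                mask=table.mask)
            lo, _, hi = estimate_parameters(regs, obs).estimates["theta"]
            covered += lo <= row["theta"] <= hi
        coverage = covered / len(held)
        assert coverage == pytest.approx(0.95, abs=0.05)

    def test_noise_target_has_non_positive_skill(self):
        table = synthetic_classification_table(n=300, seed=23, informative=0)
        rng = np.random.default_rng(24)
        table.frame["theta"] = rng.normal(size=len(table.frame))
        report = cross_validate(table, task="regress", targets=["theta"], seed=25)
        assert report["r2"]["theta"] < 0.1

    def test_absent_target_rejected(self):
        table = synthetic_classification_table(n=200, seed=26)
        with pytest.raises(ValueError):
            train_regressor(table, ["not_a_parameter"], seed=27,
                            select_features=False)


class TestPosteriorPredictiveCheck:
    @staticmethod
    def _simulator(params, seed):
        rng = np.random.default_rng(seed)
        vals = pd.Series(rng.normal(size=len(STAT_NAMES)), index=STAT_NAMES)
        return SummaryVector(values=vals,
                             mask={"abundance": True, "pi": True, "trait": True})

    def test_typical_observation_is_central(self):
        obs = self._simulator({}, 12345)
        report = posterior_predictive_check(obs, {}, self._simulator,
                                            n_sims=60, seed=1)
        assert report.distance_percentile < 0.99
        assert report.n_simulations == 60

    def test_extreme_outlier_is_most_distant(self):
        vals = pd.Series(10.0 * np.ones(len(STAT_NAMES)), index=STAT_NAMES)
        obs = SummaryVector(values=vals,
                            mask={"abundance": True, "pi": True, "trait": True})
        report = posterior_predictive_check(obs, {}, self._simulator,
                                            n_sims=60, seed=2)
        assert report.distance_percentile > 0.98

    def test_fixed_seed_identical_report(self):
        obs = self._simulator({}, 99)
        r1 = posterior_predictive_check(obs, {}, self._simulator, n_sims=40, seed=3)
        r2 = posterior_predictive_check(obs, {}, self._simulator, n_sims=40, seed=3)
        assert r1 == r2

    def test_majority_failures_abort(self):
        def bad_simulator(params, seed):
            raise RuntimeError("boom")

        obs = self._simulator({}, 1)
        with pytest.raises(RuntimeError, match="aborted"):
            posterior_predictive_check(obs, {}, bad_simulator, n_sims=10, seed=4)
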