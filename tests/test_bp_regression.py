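"""Forward selection, per-group OLS models and end-to-end estimation."""

import dataclasses

import numpy as np
import pytest

from cufflessbp.config import RunConfig
from cufflessbp.errors import MissingFeatureError
from cufflessbp.grouping import GroupBoundaries
from cufflessbp.regression import (PipelineModel, estimate_bp,
                                   fit_group_regressors, forward_select)
from cufflessbp.types import GroupRegressor


class TestForwardSelect:
    def test_dominant_predictor_selected_first(self, rng):
        """Against brute-force single-feature fits, the generating column
        wins step one."""
        n = 120
        X = rng.normal(size=(n, 10))
        y = 2.0 * X[:, 3] + rng.normal(0, 0.05, n)
        names = [f"x{j}" for j in range(10)]
        # oracle: best single-feature training MSE
        mses = []
        for j in range(10):
            A = np.column_stack([np.ones(n), X[:, j]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            mses.append(np.mean((y - A @ beta) ** 2))
        assert int(np.argmin(mses)) == 3
        sel = forward_select(X, y, names, rng_seed=1)
        assert sel[0] == "x3"

    def test_constant_target_selects_nothing(self, rng):
        X = rng.normal(size=(50, 5))
        sel = forward_select(X, np.full(50, 120.0),
                             [f"x{j}" for j in range(5)])
        assert sel == []

    def test_selection_deterministic(self, rng):
        X = rng.normal(size=(80, 12))
        y = X[:, 0] - 0.5 * X[:, 7] + rng.normal(0, 0.1, 80)
        names = [f"x{j}" for j in range(12)]
        assert forward_select(X, y, names, rng_seed=5) \
            == forward_select(X, y, names, rng_seed=5)


class TestGroupRegressors:
    def _synthetic_groups(self, rng, n_per=30, noise=0.0):
        rows, gs, ys, yd = [], [], [], []
        slopes = {1: 47000, 2: 40000, 3: 33000, 4: 26000, 5: 19000}
        for g, c in slopes.items():
            inv_ptt = rng.uniform(1 / 320, 1 / 180, n_per)
            sbp = c * inv_ptt + rng.normal(0, noise, n_per)
            rows.append(np.column_stack([inv_ptt, rng.normal(size=(n_per, 3))]))
            gs.append(np.full(n_per, g))
            ys.append(sbp)
            yd.append(0.65 * sbp + rng.normal(0, noise, n_per))
        X = np.vstack(rows)
        names = ["inv_ptt", "z1", "z2", "z3"]
        return X, names, np.concatenate(ys), np.concatenate(yd), \
            np.concatenate(gs)

    def test_ten_regressors_and_noiseless_interpolation(self, rng):
        """Noiseless per-group linear data: 5 groups x 2 targets models with
        ~zero in-group training residuals."""
        X, names, ysbp, ydbp, g = self._synthetic_groups(rng)
        regs = fit_group_regressors(X, ysbp, ydbp, g, names)
        assert len(regs) == 10
        assert {k for k in regs} == {(gg, t) for gg in range(1, 6)
                                     for t in ("sbp", "dbp")}
        for gg in range(1, 6):
            mask = g == gg
            reg = regs[(gg, "sbp")]
            pred = np.array([
                reg.predict({n: v for n, v in zip(names, row)})
                for row in X[mask]])
            assert np.max(np.abs(pred - ysbp[mask])) < 1e-6

    def test_coefficients_match_normal_equations(self, rng):
        """Closed-form (X'X)^-1 X'y oracle on a tiny n=12, p=2 group."""
        X = rng.normal(size=(12, 2))
        y = 3.0 + 1.5 * X[:, 0] - 2.0 * X[:, 1] + rng.normal(0, 0.2, 12)
        cfg = dataclasses.replace(RunConfig(), min_group_n=10,
                                  selection_tol=-np.inf, max_features=2)
        regs = fit_group_regressors(X, y, y, np.ones(12, int), ["a", "b"],
                                    cfg)
        reg = regs[(1, "sbp")]
        A = np.column_stack([np.ones(12)]
                            + [X[:, ["a", "b"].index(n)]
                               for n in reg.selected_features])
        beta = np.linalg.inv(A.T @ A) @ A.T @ y
        assert reg.intercept == pytest.approx(beta[0], abs=1e-8)
        assert reg.coefficients == pytest.approx(beta[1:], abs=1e-8)

    def test_small_group_inherits_pooled_model(self, rng):
        X, names, ysbp, ydbp, g = self._synthetic_groups(rng, n_per=30)
        g[g == 2] = 1
        g[:4] = 2          # group 2 now holds 4 samples only
        regs = fit_group_regressors(X, ysbp, ydbp, g, names)
        assert regs[(2, "sbp")].pooled_fallback
        assert not regs[(1, "sbp")].pooled_fallback


def test_oracle_group_routing_never_worse_than_predicted(small_cohort,
                                                         small_table):
    """Routing held-out sessions through their true stiffness group gives
    an SD of error no worse than routing through the SVM-predicted group."""
    from cufflessbp.pipeline import predict_table, train_pipeline
    from cufflessbp.simulate import cohort_profiles

    retained, _ = small_table
    profiles = cohort_profiles(small_cohort)
    pids = sorted(retained["participant_id"].unique())
    test_p = set(pids[::4])
    train = retained[~retained["participant_id"].isin(test_p)]
    test = retained[retained["participant_id"].isin(test_p)]
    model = train_pipeline(train, RunConfig(), 21)
    sbp_pred, _, _ = predict_table(model, test)
    sbp_oracle = np.array([
        model.regressors[(profiles[row["participant_id"]].stiffness_class,
                          "sbp")].predict(row.to_dict())
        for _, row in test.iterrows()])
    ref = test["ref_sbp"].to_numpy(float)
    sd_pred = np.std(sbp_pred - ref, ddof=1)
    sd_oracle = np.std(sbp_oracle - ref, ddof=1)
    assert sd_oracle <= sd_pred + 1e-9


class TestEstimateBp:
    def _model(self, intercepts=(120.0, 80.0)):
        class Unanimous:
            members = [None]

            def __init__(self, label):
                self.label = label

        from cufflessbp.grouping import GroupClassifier
        from sklearn.preprocessing import StandardScaler
        import numpy as np

        X = np.array([[0.0], [1.0]])
        scaler = StandardScaler().fit(X)

        class Fixed:
            def predict(self, X):
                return np.full(len(X), 3)

        clf = GroupClassifier(scaler=scaler, members=[Fixed()] * 35,
                              bootstrap_seeds=list(range(35)),
                              feature_names=["inv_ptt"])
        regs = {}
        for g in range(1, 6):
            regs[(g, "sbp")] = GroupRegressor(g, "sbp", [], np.array([]),
                                              intercepts[0])
            regs[(g, "dbp")] = GroupRegressor(g, "dbp", [], np.array([]),
                                              intercepts[1])
        return PipelineModel(
            boundaries=GroupBoundaries(40.0, 30.0, 20.0, 10.0),
            classifier=clf, regressors=regs, feature_names=["inv_ptt"],
            classifier_feature_names=["inv_ptt"])

    def test_intercept_only_model_returns_intercepts(self):
        est = estimate_bp(self._model(), {"inv_ptt": 0.004})
        assert (est.sbp_hat, est.dbp_hat) == (120.0, 80.0)
        assert est.group_used == 3 and not est.clamped

    def test_consistency_clamp(self):
        est = estimate_bp(self._model(intercepts=(80.0, 120.0)),
                          {"inv_ptt": 0.004})
        assert est.clamped
        assert est.dbp_hat == est.sbp_hat - 5.0

    def test_missing_feature_named(self):
        with pytest.raises(MissingFeatureError, match="inv_ptt"):
            estimate_bp(self._model(), {"ptt_ms": 250.0})

    def test_unselected_feature_perturbation_is_inert(self, rng):
        """Estimates ignore candidates that selection excluded."""
        reg = GroupRegressor(1, "sbp", ["inv_ptt"], np.array([30000.0]), 5.0)
        a = reg.predict({"inv_ptt": 0.004, "noise": 1.0})
        b = reg.predict({"inv_ptt": 0.004, "noise": 99.0})
        assert a == b == pytest.approx(125.0)
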