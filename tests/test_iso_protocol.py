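"""Observer merging, exclusion rules, distribution audit, baseline and CV."""

import numpy as np
import pandas as pd
import pytest

from cufflessbp.config import RunConfig
from cufflessbp.errors import CufflessBPError
from cufflessbp.protocol import (audit_distribution,
                                 check_prepost, crossval_evaluate,
                                 enforce_participant_minimum, make_folds,
                                 merge_observers, ptt_baseline,
                                 rebalance_to_quota)
from cufflessbp.types import ReferenceMeasurement


def _ref(s1, d1, s2, d2):
    return ReferenceMeasurement(obs1_sbp=s1, obs1_dbp=d1,
                                obs2_sbp=s2, obs2_dbp=d2)


class TestMergeObservers:
    @pytest.mark.parametrize("s1,s2,expected", [
        (120, 122, 121.0),     # within 4 -> arithmetic mean
        (118, 118, 118.0),     # identical readings
        (120, 124, 122.0),     # exactly 4 apart is accepted
    ])
    def test_agreeing_observers_merge_to_mean(self, s1, s2, expected):
        ref = merge_observers(_ref(s1, 80, s2, 80))
        assert ref.valid and ref.merged_sbp == expected

    def test_disagreement_beyond_4_excludes(self):
        ref = merge_observers(_ref(120, 80, 126, 80))
        assert not ref.valid
        assert ref.reason == "observer_disagreement"
        assert ref.merged_sbp is None

    def test_dbp_disagreement_also_excludes(self):
        ref = merge_observers(_ref(120, 80, 120, 86))
        assert not ref.valid

    def test_odd_reading_rejected(self):
        with pytest.raises(CufflessBPError):
            merge_observers(_ref(121, 80, 120, 80))


class TestPrepost:
    def test_sbp_change_beyond_12_excludes(self):
        a = merge_observers(_ref(120, 80, 120, 80))
        b = merge_observers(_ref(134, 80, 134, 80))
        assert check_prepost(a, b) == (False, "sbp_unstable")

    def test_dbp_change_of_9_excludes(self):
        a = merge_observers(_ref(120, 80, 120, 80))
        b = ReferenceMeasurement(120, 90, 120, 88, merged_sbp=120.0,
                                 merged_dbp=89.0, valid=True)
        assert check_prepost(a, b) == (False, "dbp_unstable")

    def test_identical_references_valid(self):
        a = merge_observers(_ref(120, 80, 120, 80))
        b = merge_observers(_ref(120, 80, 120, 80))
        assert check_prepost(a, b) == (True, None)

    def test_unmerged_references_rejected(self):
        with pytest.raises(CufflessBPError):
            check_prepost(_ref(120, 80, 120, 80), _ref(120, 80, 120, 80))


class TestParticipantMinimum:
    def test_boundary_inclusive_at_three(self):
        by_pid = {"A": ["s1", "s2"], "B": ["s3", "s4", "s5"]}
        retained, audit = enforce_participant_minimum(by_pid)
        assert "B" in retained and "A" not in retained
        assert {e["session_id"] for e in audit} == {"s1", "s2"}
        assert all(e["reason"] == "participant_minimum" for e in audit)

    def test_retained_count_matches_log_replay(self, small_table):
        retained, audit = small_table
        replay = audit[audit["status"] == "retained"]["session_id"]
        assert sorted(replay) == sorted(retained["session_id"])


class TestAuditDistribution:
    def _cohort(self, n=260, n_low=39):
        rng = np.random.default_rng(1)
        sbp = np.concatenate([np.full(n_low, 95.0),
                              rng.uniform(105, 175, n - n_low)])
        return pd.DataFrame({
            "sbp": sbp, "dbp": 0.65 * sbp,
            "participant_id": [f"P{i % 84}" for i in range(n)],
            "sex": ["female" if i % 2 else "male" for i in range(n)]})

    def test_low_sbp_share_matches_hand_count(self):
        audit = audit_distribution(self._cohort())
        row = audit[audit["name"] == "sbp_le_100"].iloc[0]
        assert row["count"] == 39
        assert row["share"] == pytest.approx(0.15)
        assert row["passed"]

    def test_underfilled_stratum_fails(self):
        cohort = self._cohort()
        cohort.loc[cohort.index[:12], "sbp"] = 165.0
        cohort.loc[cohort.index[12:], "sbp"] = 120.0
        audit = audit_distribution(cohort)
        row = audit[audit["name"] == "sbp_ge_160"].iloc[0]
        assert row["count"] == 12 and not row["passed"]

    def test_single_stratum_cohort_fails_everything_else(self):
        cohort = self._cohort()
        cohort["sbp"] = 120.0
        cohort["dbp"] = 78.0
        audit = audit_distribution(cohort)
        bp_rows = audit[audit["name"].str.startswith(("sbp", "dbp"))]
        assert not bp_rows["passed"].any()

    def test_empty_cohort_rejected(self):
        with pytest.raises(CufflessBPError):
            audit_distribution(pd.DataFrame(columns=["sbp", "dbp",
                                                     "participant_id", "sex"]))


class TestRebalance:
    def test_drops_noisiest_normal_sessions_until_shares_pass(self, rng):
        """A normotensive-heavy cohort is thinned from the normal range, in
        descending order of within-session PTT fluctuation, until the
        high/low strata shares recover."""
        n_norm, n_ext = 200, 30
        sbp = np.concatenate([rng.uniform(105, 135, n_norm),
                              np.full(n_ext, 96.0), np.full(n_ext, 165.0)])
        dbp = 0.65 * sbp
        dbp[n_norm:n_norm + n_ext] = 55.0      # low stratum reaches DBP <= 60
        table = pd.DataFrame({
            "session_id": [f"s{i}" for i in range(len(sbp))],
            "participant_id": [f"P{i % 80}" for i in range(len(sbp))],
            "sex": ["female" if i % 2 else "male" for i in range(len(sbp))],
            "ref_sbp": sbp, "ref_dbp": dbp,
            "ptt_cv": rng.uniform(0, 0.1, len(sbp))})
        before = audit_distribution(table.rename(
            columns={"ref_sbp": "sbp", "ref_dbp": "dbp"}))
        row = before[before["name"] == "sbp_ge_140"].iloc[0]
        assert row["share"] < row["min_share"]   # diluted by normals
        slim = rebalance_to_quota(table)
        after = audit_distribution(slim.rename(
            columns={"ref_sbp": "sbp", "ref_dbp": "dbp"}))
        share_rows = after[after["name"].str.startswith(("sbp", "dbp"))]
        assert (share_rows["share"] >= share_rows["min_share"]).all()
        # extreme-BP sessions are untouched; dropped ones were the noisiest
        assert (slim["ref_sbp"] <= 100).sum() == n_ext
        assert (slim["ref_sbp"] >= 160).sum() == n_ext
        dropped = set(table["session_id"]) - set(slim["session_id"])
        kept_norm = slim[(slim["ref_sbp"] > 100) & (slim["ref_sbp"] < 140)]
        if dropped and len(kept_norm):
            worst_kept = kept_norm["ptt_cv"].max()
            best_dropped = table[table["session_id"].isin(dropped)][
                "ptt_cv"].min()
            assert best_dropped >= worst_kept - 1e-12


class TestPttBaseline:
    def test_exactly_identified_model_has_zero_residuals(self, rng):
        inv_ptt = rng.uniform(1 / 320, 1 / 180, 40)
        df = pd.DataFrame({"inv_ptt": inv_ptt, "ref_sbp": 30000 * inv_ptt,
                           "ref_dbp": 20000 * inv_ptt})
        sbp_hat, dbp_hat = ptt_baseline(df.iloc[:30], df.iloc[30:])
        assert np.allclose(sbp_hat, df.iloc[30:]["ref_sbp"], atol=1e-8)
        assert np.allclose(dbp_hat, df.iloc[30:]["ref_dbp"], atol=1e-8)

    def test_coefficients_match_normal_equations_on_worked_set(self):
        """Five-point worked example against the closed-form solve."""
        train = pd.DataFrame({"inv_ptt": [0.0030, 0.0035, 0.0040, 0.0045,
                                          0.0050],
                              "ref_sbp": [100.0, 112.0, 126.0, 140.0, 150.0],
                              "ref_dbp": [64.0, 70.0, 80.0, 88.0, 94.0]})
        test = pd.DataFrame({"inv_ptt": [0.0042], "ref_sbp": [0.0],
                             "ref_dbp": [0.0]})
        sbp_hat, dbp_hat = ptt_baseline(train, test)
        A = np.column_stack([np.ones(5), train["inv_ptt"]])
        bs = np.linalg.inv(A.T @ A) @ A.T @ train["ref_sbp"].to_numpy()
        bd = np.linalg.inv(A.T @ A) @ A.T @ train["ref_dbp"].to_numpy()
        assert sbp_hat[0] == pytest.approx(bs[0] + bs[1] * 0.0042, abs=1e-8)
        assert dbp_hat[0] == pytest.approx(bd[0] + bd[1] * 0.0042, abs=1e-8)

    def test_degenerate_ptt_rejected(self):
        df = pd.DataFrame({"inv_ptt": np.full(10, 0.004),
                           "ref_sbp": np.arange(10.0),
                           "ref_dbp": np.arange(10.0)})
        with pytest.raises(CufflessBPError):
            ptt_baseline(df, df)


class TestCrossval:
    def test_folds_partition_participants(self, small_table):
        retained, _ = small_table
        folds = make_folds(retained, 5, 3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == sorted(retained.index)
        fold_pids = [set(retained.loc[f, "participant_id"]) for f in folds]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not fold_pids[i] & fold_pids[j]

    def test_perfect_oracle_predictor_scores_zero(self, small_table):
        retained, _ = small_table

        def oracle_factory(train, seed):
            def predict(test):
                return (test["ref_sbp"].to_numpy(float),
                        test["ref_dbp"].to_numpy(float))
            return predict

        rep = crossval_evaluate(retained, RunConfig(), k=5, rng_seed=1,
                                estimator_factory=oracle_factory)
        assert rep.sd_error_sbp == 0.0 and rep.sd_error_dbp == 0.0

    def test_constant_predictor_sd_equals_reference_sd(self, small_table):
        """Training-mean predictor: pooled SD of error matches the held-out
        reference SD (direct variance identity, up to fold-mean offsets)."""
        retained, _ = small_table

        def mean_factory(train, seed):
            ms, md = train["ref_sbp"].mean(), train["ref_dbp"].mean()

            def predict(test):
                return (np.full(len(test), ms), np.full(len(test), md))
            return predict

        rep = crossval_evaluate(retained, RunConfig(), k=5, rng_seed=1,
                                estimator_factory=mean_factory)
        assert rep.pooled_sd_sbp == pytest.approx(rep.measured_sd_sbp,
                                                  rel=0.15)

    def test_evaluation_invariant_to_session_order(self, small_table):
        retained, _ = small_table
        shuffled = retained.sample(frac=1.0, random_state=9)

        def mean_factory(train, seed):
            m = train["ref_sbp"].mean()

            def predict(test):
                return (np.full(len(test), m), np.full(len(test), 0.7 * m))
            return predict

        r1 = crossval_evaluate(retained, RunConfig(), k=5, rng_seed=2,
                               estimator_factory=mean_factory)
        r2 = crossval_evaluate(shuffled, RunConfig(), k=5, rng_seed=2,
                               estimator_factory=mean_factory)
        assert r1.sd_error_sbp == pytest.approx(r2.sd_error_sbp, abs=1e-9)

    def test_too_few_participants_rejected(self, small_table):
        retained, _ = small_table
        with pytest.raises(CufflessBPError):
            make_folds(retained[retained["participant_id"] == "P000"], 10, 0)
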