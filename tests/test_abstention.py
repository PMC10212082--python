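"""Abstention rules, mean-based calibration, AA/RE metrics and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from a3som.abstention import (
    ABSTAIN,
    ThresholdSet,
    abstention_metrics,
    ambiguity_rule,
    apply_abstention,
    calibrate_thresholds,
    distance_rule,
    pareto_front,
    threshold_sweep,
)


def ts_global(C, dist=0.0, amb=0.0):
    return ThresholdSet.globally(C, dist=dist, amb=amb)


class TestDistanceRule:
    def test_confident_prediction_accepted(self):
        assert distance_rule(np.array([0.9, 0.1, 0.1]), ts_global(3, dist=0.5)) == 0

    def test_low_confidence_abstains(self):
        assert distance_rule(np.array([0.3, 0.1, 0.1]), ts_global(3, dist=0.5)) == 1

    def test_equality_accepts_strict_inequality(self):
        # the rule fires only on strictly smaller top probability
        assert distance_rule(np.array([0.5, 0.1, 0.1]), ts_global(3, dist=0.5)) == 0

    def test_uses_threshold_of_the_argmax_class(self):
        ts = ThresholdSet(np.array([0.9, 0.1]), np.zeros(2))
        assert distance_rule(np.array([0.5, 0.4]), ts) == 1  # class 0: beta 0.9
        assert distance_rule(np.array([0.4, 0.5]), ts) == 0  # class 1: beta 0.1

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            distance_rule(np.array([]), ts_global(3))


class TestAmbiguityRule:
    def test_narrow_margin_abstains(self):
        assert ambiguity_rule(np.array([0.6, 0.55, 0.1]), ts_global(3, amb=0.1)) == 1

    def test_wide_margin_accepted(self):
        assert ambiguity_rule(np.array([0.9, 0.1, 0.05]), ts_global(3, amb=0.1)) == 0

    def test_exact_tie_always_abstains_for_positive_threshold(self):
        assert ambiguity_rule(np.array([0.5, 0.5]), ts_global(2, amb=0.01)) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ambiguity_rule(np.array([0.9]), ts_global(1))


class TestApplyAbstention:
    def test_zero_thresholds_abstain_nothing(self, rng):
        P = rng.dirichlet(np.ones(4), size=20)
        preds = apply_abstention(P, ts_global(4))
        assert all(p.reason == "none" and not p.abstained for p in preds)

    def test_distance_precedence_over_ambiguity(self):
        # both rules fire for every row; reason must be "distance"
        P = np.array([[0.5, 0.45], [0.3, 0.29]])
        ts = ThresholdSet(np.ones(2), np.ones(2))
        preds = apply_abstention(P, ts)
        assert all(p.abstained and p.reason == "distance" for p in preds)

    def test_matches_independent_rule_composition(self, rng):
        P = rng.dirichlet(np.ones(3), size=50)
        ts = ThresholdSet(rng.random(3), rng.random(3))
        preds = apply_abstention(P, ts)
        for row, p in zip(P, preds):
            if distance_rule(row, ts):
                assert p.reason == "distance" and p.decision == ABSTAIN
            elif ambiguity_rule(row, ts):
                assert p.reason == "ambiguity" and p.decision == ABSTAIN
            else:
                assert p.decision == int(np.argmax(row))
            assert p.top_prob >= p.runner_up_prob

    def test_abstained_invariant_reason_iff_abstain(self, rng):
        P = rng.dirichlet(np.ones(3), size=30)
        ts = ThresholdSet(rng.random(3), rng.random(3))
        for p in apply_abstention(P, ts):
            assert (p.reason == "none") == (p.decision != ABSTAIN)


class TestCalibration:
    def test_mean_of_assigned_top_probs(self):
        P = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        ts = calibrate_thresholds(P)
        assert ts.beta_dist[0] == pytest.approx(0.7)  # mean(0.8, 0.6)
        assert ts.beta_dist[1] == pytest.approx(0.9)
        assert ts.beta_amb[0] == pytest.approx(np.mean([0.6, 0.2]))

    def test_single_sample_class_gets_its_own_statistic(self):
        P = np.array([[0.75, 0.25], [0.3, 0.7]])
        ts = calibrate_thresholds(P)
        assert ts.beta_dist[0] == pytest.approx(0.75)
        assert ts.beta_amb[1] == pytest.approx(0.4)

    def test_unassigned_class_gets_zero(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2]])
        ts = calibrate_thresholds(P)
        assert ts.beta_dist[1] == 0.0
        assert ts.beta_amb[1] == 0.0

    def test_mode_zeroes_other_rule(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.all(calibrate_thresholds(P, "distance").beta_amb == 0)
        assert np.all(calibrate_thresholds(P, "ambiguity").beta_dist == 0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(np.empty((0, 3)))


class TestMetrics:
    def test_zero_rejections_aa_is_accuracy_re_zero(self, rng):
        P = rng.dirichlet(np.ones(3), size=40)
        y = rng.integers(0, 3, size=40)
        preds = apply_abstention(P, ts_global(3))
        rep = abstention_metrics(y, preds)
        assert rep.rejection_rate == 0.0
        assert rep.aa == pytest.approx(np.mean(np.argmax(P, axis=1) == y))
        assert rep.re == 0.0 or len(rep.error) == 0

    def test_set_arithmetic_example(self):
        # |G∩A| = 8 of |A| = 10 accepted -> AA = 0.8
        y = np.array([0] * 14)
        P = np.array(
            [[0.9, 0.1]] * 8  # accepted, argmax 0, correct
            + [[0.1, 0.9]] * 2  # accepted, argmax 1, error
            + [[0.3, 0.4]] * 3  # rejected (top 0.4 < 0.5), argmax 1, error
            + [[0.4, 0.3]] * 1  # rejected, argmax 0, correct
        )
        rep = abstention_metrics(y, apply_abstention(P, ts_global(2, dist=0.5)))
        assert rep.aa == pytest.approx(0.8)
        # |E∩R| = 3 of |E| = 4 errors -> RE = 0.75
        y2 = np.array([0] * 9)
        P2 = np.array(
            [[0.9, 0.1]] * 5  # accepted, correct
            + [[0.1, 0.9]] * 1  # accepted, error
            + [[0.3, 0.4]] * 3  # rejected, error
        )
        rep2 = abstention_metrics(y2, apply_abstention(P2, ts_global(2, dist=0.5)))
        assert rep2.re == pytest.approx(0.75)

    def test_matches_brute_force_sets(self, rng):
        P = rng.dirichlet(np.ones(3), size=60)
        y = rng.integers(0, 3, size=60)
        ts = ThresholdSet(rng.random(3), rng.random(3))
        preds = apply_abstention(P, ts)
        rep = abstention_metrics(y, preds)
        G = {i for i in range(60) if np.argmax(P[i]) == y[i]}
        E = set(range(60)) - G
        R = {i for i, p in enumerate(preds) if p.abstained}
        A = set(range(60)) - R
        assert rep.good == G and rep.error == E
        assert rep.accepted == A and rep.rejected == R
        assert rep.aa == pytest.approx(len(G & A) / len(A) if A else 1.0)
        assert rep.re == pytest.approx(len(E & R) / len(E) if E else 1.0)
        assert 0.0 <= rep.aa <= 1.0 and 0.0 <= rep.re <= 1.0

    def test_vacuous_denominators(self):
        y = np.array([0, 0])
        P = np.array([[0.2, 0.1], [0.15, 0.1]])
        all_rej = apply_abstention(P, ts_global(2, dist=1.0))
        rep = abstention_metrics(y, all_rej)
        assert rep.aa == 1.0  # nothing accepted
        none_rej = apply_abstention(P, ts_global(2))
        rep2 = abstention_metrics(y, none_rej)
        assert rep2.re == 1.0  # no errors at all

    def test_length_mismatch_rejected(self):
        preds = apply_abstention(np.array([[0.9, 0.1]]), ts_global(2))
        with pytest.raises(ValueError):
            abstention_metrics(np.array([0, 1]), preds)


@pytest.fixture(scope="module")
def sweep_data():
    r = np.random.default_rng(7)
    P = np.clip(r.beta(2, 2, size=(300, 4)), 1e-6, 1 - 1e-6)
    y = r.integers(0, 4, size=300)
    return P, y


class TestSweeps:
    def test_zero_threshold_point(self, sweep_data):
        P, y = sweep_data
        curve = threshold_sweep(P, y, "distance", "global", grid_resolution=11)
        first = curve.iloc[0]
        assert first["rejection_rate"] == 0.0
        assert first["re"] == 0.0

    def test_global_threshold_one_rejects_submaximal(self, sweep_data):
        P, y = sweep_data
        curve = threshold_sweep(P, y, "distance", "global", grid_resolution=11)
        last = curve.iloc[-1]
        assert last["rejection_rate"] == pytest.approx(np.mean(P.max(axis=1) < 1.0))

    def test_local_all_equal_reproduces_global_point(self, sweep_data):
        P, y = sweep_data
        g = threshold_sweep(P, y, "distance", "global", grid_resolution=5)
        loc = threshold_sweep(P, y, "distance", "local", grid_resolution=5,
                              n_samples=10, seed=0)
        # the diagonal candidates of the local sweep equal the global points
        for _, row in g.iterrows():
            match = loc[np.isclose(loc["threshold"], row["threshold"])]
            assert len(match) >= 1
            m = match.iloc[0]
            assert m["rejection_rate"] == pytest.approx(row["rejection_rate"])
            assert m["aa"] == pytest.approx(row["aa"])
            assert m["re"] == pytest.approx(row["re"])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 3))
    def test_rejection_monotone_in_each_threshold(self, t_low, t_high, c):
        if t_low > t_high:
            t_low, t_high = t_high, t_low
        r = np.random.default_rng(3)
        P = r.dirichlet(np.ones(4), size=100)
        base = np.full(4, 0.3)
        lo, hi = base.copy(), base.copy()
        lo[c], hi[c] = t_low, t_high
        for rule_arrays in (("dist", lo, hi), ("amb", lo, hi)):
            kind, a, b = rule_arrays
            if kind == "dist":
                ts_a = ThresholdSet(a, np.zeros(4))
                ts_b = ThresholdSet(b, np.zeros(4))
            else:
                ts_a = ThresholdSet(np.zeros(4), a)
                ts_b = ThresholdSet(np.zeros(4), b)
            rej_a = sum(p.abstained for p in apply_abstention(P, ts_a))
            rej_b = sum(p.abstained for p in apply_abstention(P, ts_b))
            assert rej_b >= rej_a

    def test_pareto_front_is_nondominated(self, sweep_data):
        P, y = sweep_data
        loc = threshold_sweep(P, y, "distance", "local", n_samples=200, seed=1)
        front = pareto_front(loc, "re")
        pts = front[["rejection_rate", "re"]].to_numpy()
        for i in range(len(pts)):
            for j in range(len(pts)):
                if i != j:
                    dominated = (
                        pts[j, 0] <= pts[i, 0] and pts[j, 1] >= pts[i, 1]
                        and (pts[j, 0] < pts[i, 0] or pts[j, 1] > pts[i, 1])
                    )
                    assert not dominated


def test_threshold_set_json_roundtrip(tmp_path):
    ts = ThresholdSet(np.array([0.2, 0.7]), np.array([0.1, 0.05]))
    path = tmp_path / "ts.json"
    ts.to_json(path)
    back = ThresholdSet.from_json(path)
    assert np.allclose(back.beta_dist, ts.beta_dist)
    assert np.allclose(back.beta_amb, ts.beta_amb)
    assert ts.scope == "local"
    assert ThresholdSet.globally(3, 0.5, 0.1).scope == "global"


def test_threshold_bounds_enforced():
    with pytest.raises(ValueError):
        ThresholdSet(np.array([1.2]), np.array([0.0]))
    with pytest.raises(ValueError):
        ThresholdSet(np.array([0.5]), np.array([-0.1]))
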