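"""Selection curves, overlap accounting, IPCW Brier machinery, 0.632+ algebra."""

import numpy as np
import pytest

from seqsig.boostfit import BoostPath
from seqsig.errors import InvalidArgumentError
from seqsig.evaluate import (
    added_value,
    brier_curves,
    breslow_cumhaz,
    estimator_632plus,
    ipec,
    km_censoring,
    overlap_table,
    predicted_survival,
    pred_err_result,
    selection_curve,
    _ipcw_brier,
)


def _path(selected, p=100):
    """A boosting path selecting the given covariates once each (unit updates)."""
    selected = np.asarray(selected, dtype=int)
    coef = np.zeros(p)
    for j in selected:
        coef[j] += 1.0
    k = len(selected)
    return BoostPath(
        family="logistic",
        penalized=np.arange(p),
        selected=selected,
        updates=np.ones(k),
        intercept_path=np.zeros(k + 1),
        mandatory=np.array([], dtype=int),
        mandatory_path=np.zeros((k + 1, 0)),
        loglik_path=np.zeros(k + 1),
        penalty=1.0,
        coef=coef,
    )


class TestSelectionCurve:
    def test_all_informative_first_scores_full_area(self):
        truth = set(range(10))
        path = _path(list(range(10)) + [50, 51, 52])
        assert selection_curve(path, truth).pauc10 == 10.0

    def test_no_informative_scores_zero(self):
        path = _path([20, 21, 22, 23])
        assert selection_curve(path, set(range(10))).pauc10 == 0.0

    def test_alternating_entry_matches_enumeration(self):
        # T,F,T,F,...: after f false positives, f+1 true positives are in
        truth = set(range(10))
        order = []
        for k in range(10):
            order += [k, 50 + k]
        path = _path(order)
        curve = selection_curve(path, truth)
        # oracle: TP*(f) = min(f + 1, 10) for f = 0..10
        expected = np.mean([min(f + 1, 10) for f in range(11)])
        assert curve.pauc10 == pytest.approx(expected)

    def test_empty_truth_rejected(self):
        with pytest.raises(InvalidArgumentError):
            selection_curve(_path([1]), set())

    def test_earlier_true_positive_never_hurts(self):
        truth = {0, 1}
        late = _path([50, 51, 0, 1])
        early = _path([0, 50, 51, 1])
        assert selection_curve(early, truth).pauc10 >= selection_curve(late, truth).pauc10


class TestOverlapTable:
    def test_identical_and_disjoint_sets(self):
        sets = {
            "a": [{"g1", "g2"}, {"g3", "g4"}],
            "b": [{"g1", "g2"}, {"g3", "g4"}],
            "c": [{"x1"}, {"x2"}],
        }
        table = overlap_table(sets)
        assert table.loc["a", "a"] == "2.0 (0.0)"
        assert table.loc["b", "a"] == "2.0 (0.0)"
        assert table.loc["c", "a"] == "0.0 (0.0)"

    def test_block_all_from_enumeration(self):
        sets = {
            "a": [{"g1", "g2", "g3"}, {"g1"}],
            "b": [{"g2", "g3"}, {"g1", "g5"}],
            "c": [{"g3"}, {"g1", "g6"}],
        }
        blocks = {"left": ["a", "b"], "right": ["c"]}
        table = overlap_table(sets, blocks=blocks)
        # intersection across a,b: rep1 {g2,g3} (2), rep2 {g1} (1) -> mean 1.5
        assert table.loc["all:left", "all:left"].startswith("1.5")
        # across all three tags: rep1 {g3}, rep2 {g1} -> mean 1.0, sd 0.0
        assert table.loc["all:right", "all:left"] == "1.0 (0.0)"

    def test_unequal_replicates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            overlap_table({"a": [set()], "b": [set(), set()]})


class TestBrier:
    def test_constant_half_prediction_without_censoring(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        surv = np.full((4, 1), 0.5)
        g = km_censoring(time, event)  # no censoring: G = 1 everywhere
        out = _ipcw_brier(surv, time, event, np.array([2.5]), g)
        assert out[0] == pytest.approx(0.25)

    def test_perfect_predictions_score_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        grid = np.array([2.5])
        surv = (time > 2.5).astype(float)[:, None]
        g = km_censoring(time, event)
        assert _ipcw_brier(surv, time, event, grid, g)[0] == 0.0

    def test_worked_censored_example(self):
        # 5 subjects; censoring KM and weights computed by hand
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 0, 1])
        t0 = 3.5
        # censoring KM: drops at t=2 (4 at risk) and t=4 (2 at risk)
        # G(t) = 3/4 on [2, 4), 3/8 on [4, inf)
        g = km_censoring(time, event)
        assert g(np.array([1.0]))[0] == pytest.approx(1.0)
        assert g(np.array([2.5]))[0] == pytest.approx(0.75)
        assert g(np.array([4.5]))[0] == pytest.approx(0.375)
        surv = np.full((5, 1), 0.6)
        out = _ipcw_brier(surv, time, event, np.array([t0]), g)
        # died by 3.5: subjects 1 (t=1, G(1-)=1) and 3 (t=3, G(3-)=0.75)
        # alive at 3.5: subjects 4, 5 with weight 1/G(3.5) = 1/0.75
        manual = (0.36 / 1.0 + 0.36 / 0.75 + 0.16 / 0.75 + 0.16 / 0.75) / 5
        assert out[0] == pytest.approx(manual)

    def test_brier_components_and_container(self, rng):
        n = 80
        z = rng.standard_normal(n)
        t = rng.exponential(1, n) / np.exp(0.8 * z)
        c = rng.uniform(0, 4, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        tr, te = np.arange(50), np.arange(50, n)
        grid = np.linspace(0.05, np.quantile(time, 0.9), 10)
        comp = brier_curves(z[tr], time[tr], event[tr], z[te], time[te], event[te], grid)
        res = pred_err_result(grid, comp)
        for curve in (res.apparent, res.out_of_sample, res.no_information, res.estimate_632plus):
            assert np.all((curve >= 0) & (curve <= 1))
        assert res.ipec == pytest.approx(ipec(grid, res.estimate_632plus))
        # 0.632+ lies between apparent and the smaller of oob / no-information
        upper = np.maximum(res.apparent, np.minimum(res.out_of_sample, res.no_information))
        lower = np.minimum(res.apparent, np.minimum(res.out_of_sample, res.no_information))
        assert np.all(res.estimate_632plus >= lower - 1e-12)
        assert np.all(res.estimate_632plus <= upper + 1e-12)


class TestBreslow:
    def test_null_model_matches_nelson_aalen(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        h0 = breslow_cumhaz(np.zeros(4), time, event)
        # Nelson-Aalen: 1/4 at t=1, +1/3 at t=2, +1/1 at t=4
        assert h0(np.array([1.5]))[0] == pytest.approx(0.25)
        assert h0(np.array([3.9]))[0] == pytest.approx(0.25 + 1 / 3)
        assert h0(np.array([10.0]))[0] == pytest.approx(0.25 + 1 / 3 + 1.0)

    def test_km_reference_no_better_than_oracle_on_clean_data(self, rng):
        # sanity ordering: the covariate-free reference cannot beat the
        # generating linear predictor on noiseless exponential data
        n = 300
        eta = rng.standard_normal(n)
        time = rng.exponential(1, n) / np.exp(eta)
        event = np.ones(n, dtype=int)
        grid = np.linspace(0.05, np.quantile(time, 0.9), 15)
        tr = np.arange(200)
        te = np.arange(200, n)
        km = brier_curves(np.zeros(200), time[tr], event[tr], np.zeros(100), time[te], event[te], grid)
        oracle = brier_curves(eta[tr], time[tr], event[tr], eta[te], time[te], event[te], grid)
        assert ipec(grid, km["out_of_sample"]) >= ipec(grid, oracle["out_of_sample"])


class TestEstimator632Plus:
    def test_no_overfitting_case(self):
        a = np.array([0.2])
        est = estimator_632plus(a, a, np.array([0.5]))
        assert est[0] == pytest.approx(0.2)  # w = 0.632 but oob == apparent

    def test_full_overfitting_case(self):
        est = estimator_632plus(np.array([0.1]), np.array([0.3]), np.array([0.3]))
        assert est[0] == pytest.approx(0.3)  # R = 1, w = 1 -> no-information error

    def test_intermediate_case_hand_computed(self):
        apparent, oob, noinf = np.array([0.1]), np.array([0.2]), np.array([0.3])
        r = 0.5
        w = 0.632 / (1 - 0.368 * r)
        expected = (1 - w) * 0.1 + w * 0.2
        assert estimator_632plus(apparent, oob, noinf)[0] == pytest.approx(expected)

    def test_bounded_on_random_curves(self, rng):
        a = rng.uniform(0, 0.5, 50)
        o = rng.uniform(0, 0.5, 50)
        ni = rng.uniform(0, 0.5, 50)
        est = estimator_632plus(a, o, ni)
        lower = np.minimum(a, np.minimum(o, ni))
        upper = np.maximum(a, np.minimum(o, ni))
        assert np.all(est >= lower - 1e-12) and np.all(est <= upper + 1e-12)


class TestAddedValue:
    def test_equality_gives_zero_and_worse_gives_negative(self):
        out = added_value(np.array([0.2, 0.2]), np.array([0.2, 0.3]))
        assert out.deltas[0] == 0.0 and out.deltas[1] < 0.0

    def test_hand_computed_quarter(self):
        out = added_value(np.array([0.2]), np.array([0.15]))
        assert out.deltas[0] == pytest.approx(0.25)

    def test_common_rescaling_invariance(self, rng):
        clin = rng.uniform(0.1, 0.5, 20)
        comb = rng.uniform(0.1, 0.5, 20)
        a = added_value(clin, comb).deltas
        b = added_value(3.7 * clin, 3.7 * comb).deltas
        assert np.allclose(a, b)

    def test_nonpositive_clinical_rejected(self):
        with pytest.raises(InvalidArgumentError):
            added_value(np.array([0.0]), np.array([0.1]))


def test_predicted_survival_decreases_with_risk(rng):
    n = 100
    eta = rng.standard_normal(n)
    time = rng.exponential(1, n) / np.exp(eta)
    event = np.ones(n, dtype=int)
    grid = np.array([np.median(time)])
    s = predicted_survival(eta, time, event, np.array([-2.0, 0.0, 2.0]), grid)
    assert s[0, 0] > s[1, 0] > s[2, 0]
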