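"""Metrics, Clarke zones, hypoglycemia tabulation, ranking and ablation."""

import numpy as np
import pytest

from glucowear import ConfigError
from glucowear.evaluation import (
    ablation_r2, build_report, clarke_grid, clarke_zone,
    hypoglycemia_proportions, rank_features, regression_metrics,
)
from glucowear.features import FeatureSpec
from glucowear.modeling import Fold, FoldPredictions
from glucowear.scenarios import ablation_cohort_config
from glucowear.synthetic import (
    ChannelCoupling, CouplingSpec, generate_cohort,
)


def test_regression_metric_examples():
    assert regression_metrics([100.0, 100], [110.0, 90]) == (
        pytest.approx(10.0), pytest.approx(10.0))
    assert regression_metrics([80.0, 120], [80.0, 120]) == (0.0, 0.0)
    rmse, mape = regression_metrics([50.0, 150], [60.0, 140])
    assert rmse == pytest.approx(10.0)
    assert mape == pytest.approx(100 * (0.2 + 1 / 15) / 2, abs=1e-6)
    with pytest.raises(ConfigError):
        regression_metrics([100.0], [100.0, 100.0])


def test_regression_metrics_against_brute_force(rng):
    for _ in range(20):
        ref = rng.uniform(45, 350, 30)
        pred = ref + rng.normal(0, 15, 30)
        rmse, mape = regression_metrics(ref, pred)
        brute_rmse = np.sqrt(sum((p - r) ** 2 for r, p in zip(ref, pred))
                             / len(ref))
        brute_mape = 100 * sum(abs(p - r) / r for r, p in zip(ref, pred)) \
            / len(ref)
        assert rmse == pytest.approx(brute_rmse)
        assert mape == pytest.approx(brute_mape)


@pytest.mark.parametrize("ref, pred, zone", [
    (100, 100, "A"),   # zero error
    (200, 65, "E"),    # hyperglycemic reference called hypoglycemic
    (50, 55, "A"),     # both below 70 with small error
    (100, 121, "B"),
    (150, 270, "C"),   # overcorrection wedge
    (250, 120, "D"),   # dangerous failure to detect
    (65, 190, "E"),
])
def test_clarke_zone_examples(ref, pred, zone):
    assert clarke_zone(ref, pred) == zone


def test_clarke_fractions_sum_to_100(rng):
    ref = rng.uniform(41, 399, 500)
    pred = np.clip(ref + rng.normal(0, 40, 500), 41, 399)
    res = clarke_grid(ref, pred)
    assert sum(res.fractions().values()) == pytest.approx(100.0, abs=1e-9)
    assert res.zones.size == 500


def test_clarke_a_zone_symmetric_for_moderate_errors(rng):
    """Swapping reference and prediction keeps zone A when both are >= 70 and
    within 20% of each other."""
    for _ in range(200):
        r = rng.uniform(70, 350)
        p = rng.uniform(max(70.0, 0.8 * r), min(350.0, 1.2 * r))
        if abs(p - r) <= 0.2 * r and abs(r - p) <= 0.2 * p:
            assert clarke_zone(r, p) == "A"
            assert clarke_zone(p, r) == "A"


def test_hypoglycemia_examples():
    l1, l2, lo = hypoglycemia_proportions([65.0, 53.0, 80.0])
    assert l1 == pytest.approx(200 / 3)
    assert l2 == pytest.approx(100 / 3)
    assert lo == 53.0
    assert hypoglycemia_proportions([90.0, 110.0]) == (0.0, 0.0, 90.0)
    l1, l2, _ = hypoglycemia_proportions([54.0])
    assert (l1, l2) == (100.0, 0.0)  # strict inequality at the boundary


def _specs(names):
    return [FeatureSpec(n, "sensor_data", "electrodermal activity", "EDA")
            for n in names]


def test_rank_features_contracts():
    names = ["a", "b", "c"]
    single = rank_features([np.array([0.0, 0.0, 5.0])], names, _specs(names))
    assert single.importance["c"] == pytest.approx(1.0)
    two = rank_features([np.array([1.0, 2, 3])] * 2, names, _specs(names))
    assert all(v == 0 for v in two.variance.values())
    assert sum(two.importance.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(two.category_rollup.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(two.subcategory_rollup.values()) == pytest.approx(1.0, abs=1e-9)
    # invariant to uniform scaling of the raw vectors
    scaled = rank_features([np.array([10.0, 20, 30])] * 2, names, _specs(names))
    assert scaled.importance == pytest.approx(two.importance)


def test_rank_features_order_invariance():
    names = ["a", "b"]
    fwd = rank_features([np.array([1.0, 3.0])], names, _specs(names))
    rev = rank_features([np.array([3.0, 1.0])], ["b", "a"], _specs(names))
    assert fwd.importance == pytest.approx(rev.importance)


def test_build_report_shape():
    folds = [
        Fold("P1", np.arange(3), np.array([100.0, 110, 90]),
             np.array([105.0, 100, 95])),
        Fold("P2", np.arange(3, 6), np.array([120.0, 60, 80]),
             np.array([110.0, 70, 85])),
    ]
    rep = build_report(FoldPredictions(folds=folds))
    assert set(rep.rmse_per_fold) == {"P1", "P2"}
    assert sum(rep.clarke_fractions.values()) == pytest.approx(100.0)
    assert rep.hypo_level1_pct == pytest.approx(100 / 6)
    d = rep.to_dict()
    assert "hypoglycemia" in d and d["hypoglycemia"]["min_mgdl"] == 60.0


def _tiny_ablation_cfg(gain):
    cfg = ablation_cohort_config(0)
    cfg.n_participants = 3
    cfg.days_per_participant = 2
    cfg.glucose_noise_sd = 0.0
    cfg.meal_amplitude_rel_sd = 0.0
    cfg.meal_time_jitter_min = 0.0
    cfg.seasonal_amplitude = 0.0
    cfg.coupling = CouplingSpec(channels={
        "EDA": ChannelCoupling(gain=gain, nonlinearity="linear",
                               noise_sd=0.0 if gain else 0.5,
                               confound_sd=0.0 if gain else 1.5, baseline=6.0)})
    cfg.channel_rates = {"EDA": 4.0}
    return cfg


def test_ablation_perfect_fit_limit():
    """Glucose a noiseless affine function of the only channel => R^2 ~ 1."""
    records = generate_cohort(_tiny_ablation_cfg(gain=0.1))
    res = ablation_r2(records, ["EDA"], "MMT", n_folds=16, fast=True, seed=0)
    assert res.mean_r2["gbtree"] >= 0.99
    assert res.mean_r2["tree"] >= 0.99


def test_ablation_independent_channel_no_skill():
    records = generate_cohort(_tiny_ablation_cfg(gain=0.0))
    res = ablation_r2(records, ["EDA"], "MMT", n_folds=16, fast=True, seed=0)
    assert res.mean_r2["gbtree"] <= 0.05
    assert res.mean_r2["tree"] <= 0.05


def test_ablation_requires_phase_annotations(mini_records):
    bare = [type(r)(id=r.id, demographics=r.demographics, streams=r.streams,
                    glucose=r.glucose, phases=None, study_arm=r.study_arm)
            for r in mini_records]
    with pytest.raises(ConfigError, match="phase"):
        ablation_r2(bare, ["EDA"], "MMT", fast=True)
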