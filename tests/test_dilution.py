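"""Critical-N dilution curve construction and NNI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricenni.dilution import (
    CriticalNDilution,
    CriticalPoint,
    DilutionCurve,
    OrganSample,
    classify_n_status,
    compute_nni,
    critical_concentration,
    critical_point,
    fit_dilution_curve,
    plant_n_accumulation,
)


class TestPlantNAccumulation:
    def test_hand_computed_example(self):
        organs = [
            OrganSample("leaf", 2000.0, 1.5),
            OrganSample("stem", 3000.0, 0.8),
            OrganSample("panicle", 0.0, 0.0),
        ]
        assert plant_n_accumulation(organs) == pytest.approx(54.0)

    def test_zero_concentrations(self):
        organs = [OrganSample("leaf", 2000.0, 0.0), OrganSample("stem", 500.0, 0.0)]
        assert plant_n_accumulation(organs) == 0.0

    def test_single_organ(self):
        assert plant_n_accumulation([OrganSample("leaf", 1000.0, 1.0)]) == pytest.approx(10.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            plant_n_accumulation([(-5.0, 1.0)])

    @given(
        weights=st.lists(st.floats(0, 1e4), min_size=1, max_size=3),
        concs=st.lists(st.floats(0, 5), min_size=3, max_size=3),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_and_degree_one_in_weights(self, weights, concs, scale):
        pairs = list(zip(weights, concs))
        total = sum(plant_n_accumulation([p]) for p in pairs)
        assert plant_n_accumulation(pairs) == pytest.approx(total, rel=1e-9, abs=1e-9)
        scaled = [(w * scale, n) for w, n in pairs]
        assert plant_n_accumulation(scaled) == pytest.approx(scale * total, rel=1e-9, abs=1e-9)


def _date_table(means, reps=3, sd=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, mean in enumerate(means):
        for _ in range(reps):
            rows.append({"n_rate": i * 50.0, "shoot_dm": mean + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestClassifyNStatus:
    def test_plateau_partition(self):
        """(2,4,6,6,6) with tiny scatter: first three limited, top two not."""
        grouping = classify_n_status(_date_table([2, 4, 6, 6, 6]))
        assert grouping.n_limited == [0.0, 50.0, 100.0]
        assert grouping.non_limited == [150.0, 200.0]
        assert grouping.usable
        assert np.isfinite(grouping.f_statistic)

    def test_flat_date_flagged_unusable(self):
        grouping = classify_n_status(_date_table([5, 5, 5, 5, 5]))
        assert not grouping.usable

    def test_matches_generator_plateau_membership(self, noisefree_trial, noisefree_config):
        cfg = noisefree_config
        saturated = [r for r in cfg.n_rates if r > cfg.rate_sat]
        for stage in cfg.stages:
            sub = noisefree_trial[noisefree_trial["stage"] == stage]
            grouping = classify_n_status(sub)
            assert grouping.non_limited == saturated

    def test_rejects_too_few_replicates(self):
        table = _date_table([2, 4, 6], reps=1)
        with pytest.raises(ValueError, match="replicate"):
            classify_n_status(table)

    def test_rejects_too_few_treatments(self):
        with pytest.raises(ValueError, match="3 N treatments"):
            classify_n_status(_date_table([2, 4]))


class TestCriticalPoint:
    def test_oblique_intersection(self):
        point = critical_point((-0.2, 3.0), dm_max=5.0)
        assert (point.dm, point.nc) == (5.0, pytest.approx(2.0))

    def test_flat_oblique(self):
        assert critical_point((0.0, 2.5), dm_max=7.3).nc == pytest.approx(2.5)

    def test_rejects_negative_ordinate(self):
        with pytest.raises(ValueError, match="must be > 0"):
            critical_point((-1.0, 1.0), dm_max=2.0)

    def test_rejects_bad_dm(self):
        with pytest.raises(ValueError):
            critical_point((0.0, 2.0), dm_max=0.0)


class TestFitDilutionCurve:
    @pytest.mark.parametrize("a,b,dms", [(2.24, 0.35, (1, 2, 4, 8)), (2.78, 0.46, (0.5, 1, 2, 4, 8))])
    def test_exact_on_power_law(self, a, b, dms):
        points = [CriticalPoint(dm=d, nc=a * d ** (-b)) for d in dms]
        curve = fit_dilution_curve(points)
        assert curve.a == pytest.approx(a, abs=1e-9)
        assert curve.b == pytest.approx(b, abs=1e-9)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)

    def test_mean_a_unbiased_under_noise(self):
        """5% multiplicative noise, 200 replicates: mean a within 2%."""
        rng = np.random.default_rng(7)
        dms = np.array([1.0, 2.0, 4.0, 8.0])
        a_hats = []
        for _ in range(200):
            nc = 2.24 * dms ** (-0.35) * np.exp(rng.normal(0, 0.05, dms.size))
            a_hats.append(fit_dilution_curve([CriticalPoint(d, v) for d, v in zip(dms, nc)]).a)
        assert abs(np.mean(a_hats) / 2.24 - 1) < 0.02

    def test_rejects_too_few_points(self):
        pts = [CriticalPoint(1.0, 2.0), CriticalPoint(2.0, 1.5)]
        with pytest.raises(ValueError, match=">= 3"):
            fit_dilution_curve(pts)

    def test_rejects_duplicate_dm(self):
        pts = [CriticalPoint(1.0, 2.0), CriticalPoint(1.0, 2.1), CriticalPoint(2.0, 1.5)]
        with pytest.raises(ValueError, match="distinct"):
            fit_dilution_curve(pts)


class TestCriticalConcentration:
    @pytest.mark.parametrize(
        "dm,a,b,expected",
        [
            (1.0, 2.24, 0.35, 2.24),
            (4.0, 2.24, 0.35, 2.24 * 4 ** (-0.35)),
            (1.0, 2.78, 0.46, 2.78),
        ],
    )
    def test_power_law_values(self, dm, a, b, expected):
        curve = DilutionCurve(a=a, b=b, dm_min=0.3, dm_max=12.0)
        assert critical_concentration(dm, curve) == pytest.approx(expected, rel=1e-12)

    def test_high_precision_evaluation(self):
        curve = DilutionCurve(a=2.24, b=0.35, dm_min=0.3, dm_max=12.0)
        assert critical_concentration(4.0, curve) == pytest.approx(1.379, abs=5e-4)

    def test_strictly_decreasing_in_dm(self):
        curve = DilutionCurve(a=2.24, b=0.35, dm_min=0.3, dm_max=13.0)
        values = critical_concentration(np.linspace(0.34, 12.47, 200), curve)
        assert (np.diff(values) < 0).all()

    def test_warns_outside_validity_range(self):
        curve = DilutionCurve(a=2.24, b=0.35, dm_min=1.0, dm_max=9.0)
        with pytest.warns(UserWarning, match="validity range"):
            critical_concentration(0.2, curve)

    def test_rejects_nonpositive_dm(self):
        curve = DilutionCurve(a=2.24, b=0.35)
        with pytest.raises(ValueError):
            critical_concentration(0.0, curve)


class TestComputeNNI:
    def test_identity(self):
        assert compute_nni(2.24, 2.24).nni == pytest.approx(1.0)

    def test_division(self):
        value = compute_nni(1.5, 1.379)
        assert value.nni == pytest.approx(1.088, abs=5e-4)
        assert value.classification == "surplus"

    def test_zero_measured_is_deficient(self):
        value = compute_nni(0.0, 1.5)
        assert value.nni == 0.0
        assert value.deficient

    def test_rejects_nonpositive_critical(self):
        with pytest.raises(ValueError):
            compute_nni(1.0, 0.0)


class TestCriticalNDilutionModel:
    def test_full_procedure_recovery(self, indica_config):
        from ricenni.synthetic import generate_trial

        res = CriticalNDilution(generate_trial(indica_config)).fit()
        a, b = indica_config.true_curve
        assert res.curve.a == pytest.approx(a, abs=1e-6)
        assert res.curve.b == pytest.approx(b, abs=1e-6)
        assert len(res.critical_points) == 4
        assert res.skipped_stages == []

    def test_summary_and_nni_table(self, noisefree_trial):
        res = CriticalNDilution(noisefree_trial).fit()
        text = res.summary()
        assert "Critical-N dilution curve" in text and "a (% at 1 t/ha)" in text
        table = res.nni_table()
        assert np.isfinite(table["nni"]).all()
        np.testing.assert_allclose(table["nni"], table["shoot_n"] / table["nc"])

    def test_leaf_component_runs(self, noisefree_trial):
        res = CriticalNDilution(noisefree_trial, component="leaf").fit()
        assert res.curve.component == "leaf"
        assert 0 < res.curve.b < 1
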