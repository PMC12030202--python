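"""Linear-plateau response and N-balance topdressing arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricenni.nbalance import (
    LinearPlateau,
    LinearPlateauParams,
    NBalanceInputs,
    NitrogenBalance,
    fit_linear_plateau,
    grain_n_accumulation,
    grain_yield,
    predict_relative_yield,
    required_n,
    topdressing_plan,
)

YJ37 = LinearPlateauParams(slope=1.088, intercept=0.08, breakpoint=1.01, plateau=1.01)
JY6135 = LinearPlateauParams(slope=2.266, intercept=0.86, breakpoint=0.82, plateau=0.99)


def _plateau_data(params=YJ37, n_below=8, extra=(1.01, 1.1, 1.2, 1.3)):
    nni = np.concatenate([np.linspace(0.5, 1.0, n_below), extra])
    return nni, predict_relative_yield(nni, params)


class TestFitLinearPlateau:
    def test_exact_recovery_noise_free(self):
        nni, ry = _plateau_data()
        est = fit_linear_plateau(nni, ry)
        assert est.slope == pytest.approx(1.088, abs=1e-6)
        assert est.intercept == pytest.approx(0.08, abs=1e-6)
        assert est.breakpoint == pytest.approx(1.01, abs=1e-6)
        assert est.plateau == pytest.approx(1.01, abs=1e-6)

    def test_continuous_variant_joins_at_breakpoint(self):
        nni, ry = _plateau_data()
        est = fit_linear_plateau(nni, ry, continuous=True)
        assert est.plateau == pytest.approx(est.slope * est.breakpoint - est.intercept)

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_linear_plateau(np.linspace(0.5, 1.2, 10), np.full(10, 1.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_linear_plateau([0.5, 0.8, 1.1], [0.4, 0.8, 1.0])

    def test_breakpoint_bias_small_under_noise(self):
        rng = np.random.default_rng(23)
        estimates = []
        for _ in range(100):
            nni = rng.uniform(0.5, 1.3, 40)
            ry = predict_relative_yield(nni, YJ37) + rng.normal(0, 0.02, 40)
            estimates.append(fit_linear_plateau(nni, ry).breakpoint)
        assert abs(np.mean(estimates) - 1.01) < 0.05


class TestPredictRelativeYield:
    @pytest.mark.parametrize(
        "model,nni,expected",
        [
            (YJ37, 1.2, 1.01),
            (YJ37, 1.01, 1.01),
            (YJ37, 0.5, 1.088 * 0.5 - 0.08),
            (JY6135, 0.9, 0.99),
            (JY6135, 0.5, 2.266 * 0.5 - 0.86),
        ],
    )
    def test_piecewise_rule(self, model, nni, expected):
        assert predict_relative_yield(nni, model) == pytest.approx(expected)

    def test_nonpositive_nni_rejected(self):
        with pytest.raises(ValueError):
            predict_relative_yield(0.0, YJ37)

    def test_nondecreasing_for_continuous_model(self):
        # a model whose plateau meets the line at the breakpoint
        model = LinearPlateauParams(1.0, 0.0, 1.0, 1.0)
        grid = np.linspace(0.2, 1.6, 300)
        assert (np.diff(predict_relative_yield(grid, model)) >= -1e-12).all()

    def test_japonica_model_is_discontinuous_at_breakpoint(self):
        # the fitted japonica parameters step down by ~0.009 at NNI_max;
        # monotonicity holds within each regime
        below = predict_relative_yield(1.01 - 1e-9, YJ37)
        at = predict_relative_yield(1.01, YJ37)
        assert below > at
        grid = np.linspace(0.2, 1.0, 100)
        assert (np.diff(predict_relative_yield(grid, YJ37)) > 0).all()

    def test_model_results_wrapper(self):
        nni, ry = _plateau_data()
        res = LinearPlateau(ry, nni).fit()
        assert res.r2 == pytest.approx(1.0)
        assert "NNI_max" in res.summary()
        assert res.predict(1.2) == pytest.approx(1.01)


class TestBalanceArithmetic:
    def test_grain_yield(self):
        assert grain_yield(1.01, 10573.3) == pytest.approx(10679.033)
        assert grain_yield(0.0, 9000.0) == 0.0
        assert grain_yield(1.0, 9505.8) == pytest.approx(9505.8)

    def test_grain_n_accumulation(self):
        assert grain_n_accumulation(10679.033, 1.97) == pytest.approx(210.38, abs=0.005)
        assert grain_n_accumulation(0.0, 2.0) == 0.0
        assert grain_n_accumulation(9505.8, 2.13) == pytest.approx(202.47, abs=0.005)

    def test_required_n_yj37(self):
        inputs = NBalanceInputs(y_max=10573.3, apgn=1.97, ns=128.90)
        gna = grain_n_accumulation(grain_yield(1.01, inputs.y_max), inputs.apgn)
        nr, deficit = required_n(gna, inputs)
        assert nr == pytest.approx(191.26, abs=0.005)
        assert not deficit

    def test_required_n_jy6135(self):
        inputs = NBalanceInputs(y_max=9505.8, apgn=2.13, ns=118.56)
        gna = grain_n_accumulation(grain_yield(1.0, inputs.y_max), inputs.apgn)
        nr, _ = required_n(gna, inputs)
        assert nr == pytest.approx(196.98, abs=0.005)

    def test_balance_point_clamped(self):
        inputs = NBalanceInputs(y_max=9000.0, apgn=2.0, ns=150.0, n_applied=30.0)
        nr, deficit = required_n(150.0, inputs)
        assert nr == 0.0 and deficit

    def test_invalid_nue_rejected(self):
        with pytest.raises(ValueError):
            NBalanceInputs(y_max=9000.0, apgn=2.0, ns=100.0, nue=0.0)


class TestTopdressingPlan:
    def test_two_to_one_split_yj37(self):
        plan = topdressing_plan(191.26, basal=80.0)
        assert plan.topdressings[0] == pytest.approx(74.1733, abs=5e-4)
        assert plan.topdressings[1] == pytest.approx(37.0867, abs=5e-4)
        assert plan.as_row() == {
            "basal": 80.0,
            "total": 191.26,
            "topdress_JT": 74.17,
            "topdress_HD": 37.09,
        }

    def test_two_to_one_split_jy6135(self):
        plan = topdressing_plan(196.98, basal=64.0)
        assert plan.as_row()["topdress_JT"] == pytest.approx(88.65)
        assert plan.as_row()["topdress_HD"] == pytest.approx(44.33)

    def test_basal_equals_total(self):
        plan = topdressing_plan(120.0, basal=120.0)
        assert plan.topdressings == (0.0, 0.0)

    def test_basal_above_total_rejected(self):
        with pytest.raises(ValueError, match="basal"):
            topdressing_plan(100.0, basal=120.0)

    @given(
        total=st.floats(0, 400),
        basal_frac=st.floats(0, 1),
        ratios=st.lists(st.floats(0.1, 5), min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, total, basal_frac, ratios):
        basal = total * basal_frac
        stages = tuple(f"S{i}" for i in range(len(ratios)))
        plan = topdressing_plan(total, basal, tuple(ratios), stages)
        assert plan.basal + sum(plan.topdressings) == pytest.approx(plan.total, abs=1e-9)
        assert all(t >= 0 for t in plan.topdressings)


class TestNitrogenBalanceCalculator:
    def test_plateau_policy_yj37(self):
        calc = NitrogenBalance(YJ37, NBalanceInputs(y_max=10573.3, apgn=1.97, ns=128.90))
        row = calc.recommend(1.2, basal=80.0).as_row()
        assert row == {"basal": 80.0, "total": 191.26, "topdress_JT": 74.17, "topdress_HD": 37.09}

    def test_unity_policy_jy6135(self):
        calc = NitrogenBalance(
            JY6135,
            NBalanceInputs(y_max=9505.8, apgn=2.13, ns=118.56),
            saturated_ry="unity",
        )
        n3 = calc.recommend(1.0, basal=64.0).as_row()
        n4 = calc.recommend(1.0, basal=80.0).as_row()
        assert (n3["topdress_JT"], n3["topdress_HD"]) == (88.65, 44.33)
        assert (n4["topdress_JT"], n4["topdress_HD"]) == (77.99, 38.99)
        assert n3["total"] == n4["total"] == 196.98

    def test_replicate_table_reports_rmse(self):
        calc = NitrogenBalance(YJ37, NBalanceInputs(y_max=10573.3, apgn=1.97, ns=128.90))
        table = calc.recommend_table({"N4": [1.15, 1.2, 1.25]}, {"N4": 80.0})
        assert table.loc[0, "total"] == pytest.approx(191.26, abs=0.005)
        assert table.loc[0, "rmse_total"] == pytest.approx(0.0, abs=1e-9)

    def test_deficient_crop_needs_more_n(self):
        calc = NitrogenBalance(YJ37, NBalanceInputs(y_max=10573.3, apgn=1.97, ns=128.90))
        low = calc.recommend(0.95, basal=80.0)
        high = calc.recommend(1.2, basal=80.0)
        assert low.total < high.total  # below the plateau yields (and N demand) drop
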