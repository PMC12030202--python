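"""NNI -> relative-yield linear plateau and N-balance topdressing.

The yield response to N status follows a linear-plateau ("linear
platform") law: relative yield RY = slope * NNI - intercept below a
breakpoint NNI_max, and a constant plateau c at or above it.  Combined
with a historical maximum yield Ymax, the N uptake per 100 kg grain
(APGN), the soil N supply measured on the zero-N control (Ns) and a
fixed N use efficiency (NUE), the in-season NNI translates into a total
fertilizer requirement

    GY  = Ymax * RY
    GNA = APGN * GY / 100
    Nr  = (GNA - Ns) / NUE - Napplied

which is then split into the basal dose already given and stage-wise
topdressings in fixed ratios (default 2:1, i.e. 40%/20% of total N at
the two topdressing stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinearPlateauParams",
    "NBalanceInputs",
    "TopdressingPlan",
    "fit_linear_plateau",
    "predict_relative_yield",
    "grain_yield",
    "grain_n_accumulation",
    "required_n",
    "topdressing_plan",
    "LinearPlateau",
    "LinearPlateauResults",
    "NitrogenBalance",
]

#: Fixed nitrogen use efficiency (fraction of applied N recovered by the crop).
DEFAULT_NUE = 0.426


@dataclass(frozen=True)
class LinearPlateauParams:
    """slope/intercept/breakpoint/plateau of RY = f(NNI)."""

    slope: float
    intercept: float
    breakpoint: float
    plateau: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.breakpoint <= 0:
            raise ValueError("breakpoint must be > 0")

    def predict(self, nni):
        return predict_relative_yield(nni, self)


@dataclass(frozen=True)
class NBalanceInputs:
    """Cultivar-level constants of the N balance.

    y_max : historical maximum yield (kg/ha).
    apgn : N uptake per 100 kg grain at high yield (kg).
    ns : N uptake of the zero-N control (kg/ha), the soil N supply.
    nue : N use efficiency, fraction in (0, 1].
    n_applied : fertilizer N already applied and counted against the
        requirement (kg/ha).
    """

    y_max: float
    apgn: float
    ns: float
    nue: float = DEFAULT_NUE
    n_applied: float = 0.0

    def __post_init__(self) -> None:
        for name in ("y_max", "apgn", "ns", "n_applied"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.nue <= 1:
            raise ValueError("nue must lie in (0, 1]")


@dataclass(frozen=True)
class TopdressingPlan:
    """Basal + stage-wise N amounts (kg/ha); conserves the total exactly."""

    basal: float
    topdressings: tuple
    stages: tuple
    split_ratios: tuple
    total: float
    deficit: bool = False  # requirement was negative and clamped to zero

    def __post_init__(self) -> None:
        if any(t < -1e-9 for t in self.topdressings) or self.basal < -1e-9:
            raise ValueError("all amounts must be >= 0")
        if abs(self.basal + sum(self.topdressings) - self.total) > 1e-9:
            raise ValueError("plan violates conservation: basal + topdressings != total")

    def as_row(self, round_to: int | None = 2) -> dict:
        row = {"basal": self.basal, "total": self.total}
        for stage, amount in zip(self.stages, self.topdressings):
            row[f"topdress_{stage}"] = amount
        if round_to is not None:
            row = {k: round(v, round_to) for k, v in row.items()}
        return row


# ---------------------------------------------------------------------------
# linear plateau


def _fit_for_breakpoint(x, y, bp, continuous):
    """Least squares for a fixed breakpoint; returns (params, sse)."""
    below = x < bp
    above = ~below
    if continuous:
        # single LS problem in (slope, intercept): plateau = slope*bp - intercept
        design = np.column_stack([np.where(below, x, bp), -np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        plateau = slope * bp - intercept
    else:
        if below.sum() < 2 or len(np.unique(x[below])) < 2:
            return None, np.inf
        slope, neg_intercept = np.polyfit(x[below], y[below], 1)
        slope, intercept = float(slope), float(-neg_intercept)
        plateau = float(y[above].mean()) if above.any() else np.nan
    if slope <= 0 or (above.any() and np.isnan(plateau)):
        return None, np.inf
    pred = np.where(below, slope * x - intercept, plateau)
    sse = float(np.sum((y - pred) ** 2))
    params = LinearPlateauParams(slope, intercept, float(bp), plateau)
    return params, sse


def fit_linear_plateau(nni, relative_yield, continuous: bool = False) -> LinearPlateauParams:
    """Fit the linear-plateau response by breakpoint grid search.

    Every observed NNI value is a candidate breakpoint (points at or
    above the candidate belong to the plateau); for each candidate the
    line below and the plateau mean above are fitted by least squares
    and the candidate with minimum total SSE wins (ties -> smallest
    breakpoint).  ``continuous=True`` constrains the plateau to meet the
    line at the breakpoint; the default leaves it free, which permits a
    (slightly) discontinuous fit.
    """
    x = np.asarray(nni, dtype=float)
    y = np.asarray(relative_yield, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need >= 5 paired (NNI, RY) observations")
    if np.ptp(y) == 0:
        raise ValueError("all relative yields identical: slope is undefined")
    candidates = np.unique(x)[1:]  # at least one point below each candidate
    best, best_sse = None, np.inf
    for bp in candidates:
        params, sse = _fit_for_breakpoint(x, y, bp, continuous)
        if params is not None and sse < best_sse - 1e-15:
            best, best_sse = params, sse
    if best is None:
        raise ValueError("no candidate breakpoint separates the two regimes")
    return best


def predict_relative_yield(nni, model: LinearPlateauParams):
    """RY = slope*NNI - intercept below the breakpoint, plateau c at/above."""
    nni_arr = np.asarray(nni, dtype=float)
    if np.any(nni_arr <= 0):
        raise ValueError("NNI must be > 0")
    out = np.where(
        nni_arr >= model.breakpoint,
        model.plateau,
        model.slope * nni_arr - model.intercept,
    )
    return float(out) if np.isscalar(nni) else out


class LinearPlateau:
    """Linear-plateau model of relative yield against NNI.

    ``endog`` is relative yield, ``exog`` the NNI values (statsmodels
    argument order).
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, nni_col: str = "nni", ry_col: str = "relative_yield"):
        return cls(data[ry_col], data[nni_col])

    def fit(self, continuous: bool = False) -> "LinearPlateauResults":
        params = fit_linear_plateau(self.exog, self.endog, continuous=continuous)
        return LinearPlateauResults(self, params)


class LinearPlateauResults:
    def __init__(self, model, params: LinearPlateauParams):
        self.model = model
        self.params = params
        pred = predict_relative_yield(model.exog, params)
        resid = model.endog - pred
        self.sse = float(resid @ resid)
        sst = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.r2 = 1.0 - self.sse / sst if sst > 0 else 1.0
        self.rmse = float(np.sqrt(np.mean(resid**2)))

    def predict(self, nni):
        return predict_relative_yield(nni, self.params)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Linear-plateau response: RY = a*NNI - b (NNI < NNI_max), RY = c otherwise",
                "=" * 64,
                f"slope a:      {p.slope:.4f}",
                f"intercept b:  {p.intercept:.4f}",
                f"NNI_max:      {p.breakpoint:.4f}",
                f"plateau c:    {p.plateau:.4f}",
                f"n={self.model.endog.size}  R2={self.r2:.4f}  RMSE={self.rmse:.4f}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.exog, self.model.endog, marker="^", label="observations")
        grid = np.linspace(self.model.exog.min(), self.model.exog.max(), 200)
        ax.plot(grid, self.predict(grid), label="linear plateau")
        ax.set_xlabel("NNI")
        ax.set_ylabel("relative yield")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# nitrogen balance


def grain_yield(ry: float, y_max: float) -> float:
    """Predicted grain yield GY = Ymax * RY (kg/ha)."""
    if ry < 0 or y_max < 0:
        raise ValueError("ry and y_max must be >= 0")
    return y_max * ry


def grain_n_accumulation(gy: float, apgn: float) -> float:
    """Grain N demand GNA = APGN * GY / 100 (kg/ha; GY in 100-kg units)."""
    if gy < 0 or apgn < 0:
        raise ValueError("gy and apgn must be >= 0")
    return apgn * gy / 100.0


def required_n(gna: float, inputs: NBalanceInputs) -> tuple[float, bool]:
    """Fertilizer requirement Nr = (GNA - Ns)/NUE - Napplied (kg/ha).

    Negative requirements (soil supply already covers the demand) are
    clamped to zero; the second return value flags that case.
    """
    if inputs.nue <= 0:
        raise ValueError("nue must be > 0")
    nr = (gna - inputs.ns) / inputs.nue - inputs.n_applied
    if nr < 0:
        return 0.0, True
    return nr, False


def topdressing_plan(
    total_n: float,
    basal: float,
    split_ratios=(2.0, 1.0),
    stages=("JT", "HD"),
    deficit: bool = False,
) -> TopdressingPlan:
    """Allocate total N into the basal dose plus stage-wise topdressings.

    The remainder after the basal dose is split proportionally to
    ``split_ratios`` (default 2:1, i.e. 40% and 20% of a total of which
    40% was basal).  Amounts are kept at full precision; round only at
    report time.
    """
    ratios = tuple(float(r) for r in split_ratios)
    if not ratios or any(r <= 0 for r in ratios):
        raise ValueError("split_ratios must be positive and non-empty")
    if len(ratios) != len(stages):
        raise ValueError("one split ratio per topdressing stage required")
    if basal < 0 or total_n < 0:
        raise ValueError("amounts must be >= 0")
    if basal > total_n + 1e-9:
        raise ValueError("basal dose exceeds the total N requirement")
    remaining = max(total_n - basal, 0.0)
    weight = sum(ratios)
    tops = tuple(remaining * r / weight for r in ratios)
    return TopdressingPlan(
        basal=basal,
        topdressings=tops,
        stages=tuple(stages),
        split_ratios=ratios,
        total=basal + sum(tops),
        deficit=deficit,
    )


@dataclass
class NitrogenBalance:
    """NNI-based topdressing calculator for one cultivar.

    Combines a fitted linear-plateau response with the cultivar's
    balance constants.  ``saturated_ry`` chooses what relative yield a
    plateau-saturated crop (NNI >= breakpoint) is credited with:
    ``"plateau_c"`` uses the fitted plateau value, ``"unity"`` uses
    RY = 1 (full historical maximum).
    """

    plateau: LinearPlateauParams
    inputs: NBalanceInputs
    stages: tuple = ("JT", "HD")
    split_ratios: tuple = (2.0, 1.0)
    saturated_ry: str = "plateau_c"

    def __post_init__(self) -> None:
        if self.saturated_ry not in ("plateau_c", "unity"):
            raise ValueError("saturated_ry must be 'plateau_c' or 'unity'")

    def relative_yield(self, nni: float) -> float:
        if nni >= self.plateau.breakpoint and self.saturated_ry == "unity":
            return 1.0
        return predict_relative_yield(nni, self.plateau)

    def recommend(self, nni: float, basal: float) -> TopdressingPlan:
        """Full chain: NNI -> RY -> GY -> GNA -> Nr -> stage split."""
        ry = self.relative_yield(nni)
        gy = grain_yield(ry, self.inputs.y_max)
        gna = grain_n_accumulation(gy, self.inputs.apgn)
        total, deficit = required_n(gna, self.inputs)
        basal = min(basal, total)  # a deficit soil needs no further N
        return topdressing_plan(total, basal, self.split_ratios, self.stages, deficit)

    def recommend_table(self, nni_by_treatment: dict, basal_by_treatment: dict) -> pd.DataFrame:
        """Per-treatment plan table; replicate NNIs give an RMSE column.

        ``nni_by_treatment`` maps treatment -> scalar NNI or a sequence
        of replicate NNIs (e.g. inverted per plot); the plan is computed
        per replicate and reported as mean with the root-mean-square
        spread of the totals.
        """
        rows = []
        for treatment, nni in nni_by_treatment.items():
            basal = basal_by_treatment[treatment]
            reps = np.atleast_1d(np.asarray(nni, dtype=float))
            plans = [self.recommend(v, basal) for v in reps]
            row = {"treatment": treatment}
            mean_plan = {
                k: float(np.mean([p.as_row(round_to=None)[k] for p in plans]))
                for k in plans[0].as_row(round_to=None)
            }
            row.update(mean_plan)
            row["rmse_total"] = float(
                np.sqrt(np.mean((np.array([p.total for p in plans]) - mean_plan["total"]) ** 2))
            )
            rows.append(row)
        return pd.DataFrame(rows)
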