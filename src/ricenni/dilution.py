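"""Critical-N dilution curve and nitrogen nutrition index (NNI).

The critical N concentration Nc (%) is the minimum plant N concentration
that still permits maximum growth at a given shoot dry matter DM (t/ha),
modelled as the power law ``Nc = a * DM**-b``.  The curve is built by the
grouping-and-intersection procedure of Justes: at each sampling date the
N treatments are split by ANOVA into an N-limited group (biomass still
responds to N) and a non-limited group (biomass saturated, N% still
rising); a straight line through the limited points (the oblique) is
intersected with the vertical at the non-limited group's mean dry matter
to give one critical point per date; the power law is then fitted to the
critical points.  NNI = Na / Nc diagnoses N status (1 optimal,
< 1 deficient, > 1 surplus).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "OrganSample",
    "CriticalPoint",
    "DilutionCurve",
    "NNIValue",
    "GroupingResult",
    "plant_n_accumulation",
    "classify_n_status",
    "critical_point",
    "fit_dilution_curve",
    "critical_concentration",
    "compute_nni",
    "CriticalNDilution",
    "DilutionCurveResults",
]

_ORGANS = ("leaf", "stem", "panicle")


@dataclass(frozen=True)
class OrganSample:
    organ: str
    dry_weight: float  # kg/ha
    n_conc: float  # %

    def __post_init__(self) -> None:
        if self.organ not in _ORGANS:
            raise ValueError(f"organ must be one of {_ORGANS}, got {self.organ!r}")
        if self.dry_weight < 0:
            raise ValueError("dry_weight must be >= 0")
        if not 0 <= self.n_conc <= 10:
            raise ValueError("n_conc (%) must lie in [0, 10]")


@dataclass(frozen=True)
class CriticalPoint:
    """One (DM, Nc) point: the oblique/vertical intersection at one date."""

    dm: float  # t/ha, maximum shoot DM of the non-limited group
    nc: float  # %, ordinate of the intersection
    stage: str = ""

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("dm must be > 0")
        if self.nc <= 0:
            raise ValueError(f"critical N concentration must be > 0, got {self.nc:.4g}")


@dataclass(frozen=True)
class DilutionCurve:
    """Fitted allometric pair ``Nc = a * DM**-b`` with its validity range."""

    a: float  # % at 1 t/ha
    b: float  # dimensionless
    dm_min: float = 0.0
    dm_max: float = np.inf
    r2: float = np.nan
    component: str = "shoot"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not 0 < self.b < 1:
            raise ValueError("b must lie in (0, 1)")
        if not self.dm_min < self.dm_max:
            raise ValueError("dm_min must be < dm_max")

    def __call__(self, dm):
        return critical_concentration(dm, self)


@dataclass(frozen=True)
class NNIValue:
    na: float  # measured N %
    nc: float  # critical N %
    nni: float
    classification: str

    @property
    def deficient(self) -> bool:
        return self.nni < 1.0


@dataclass
class GroupingResult:
    """Per-date partition of treatments into N-limited / non-limited."""

    n_limited: list
    non_limited: list
    f_statistic: float
    p_value: float
    usable: bool
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# elementary operations


def plant_n_accumulation(organs) -> float:
    """Plant N accumulation (kg N/ha): sum of dry weight x N fraction.

    ``organs`` is an iterable of :class:`OrganSample` (or (dry_weight,
    n_conc) pairs); N concentrations are percentages, so each term is
    dry_weight * n_conc / 100.
    """
    total = 0.0
    for organ in organs:
        if isinstance(organ, OrganSample):
            w, n = organ.dry_weight, organ.n_conc
        else:
            w, n = organ
        if w < 0 or n < 0:
            raise ValueError("negative dry weight or N concentration")
        total += w * n / 100.0
    return total


_ZERO_VAR = 1e-12


def _one_way_anova(groups):
    """F statistic and p for k groups; robust to zero within-group variance."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((np.asarray(g) - m) ** 2) for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    scale = max(grand**2, 1.0)
    if ssw / df_w < _ZERO_VAR * scale:
        # degenerate replicates: significant iff the means actually differ
        if ssb / df_b < _ZERO_VAR * scale:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


def _lsd_pvalue(m1, n1, m2, n2, mse, df):
    scale = max(abs(m1), abs(m2), 1.0)
    if mse < _ZERO_VAR * scale**2:
        return 0.0 if abs(m2 - m1) > 1e-9 * scale else 1.0
    t = (m2 - m1) / np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), df))


def classify_n_status(date_table: pd.DataFrame, alpha: float = 0.05) -> GroupingResult:
    """Partition the treatments of one sampling date by N limitation.

    One-way ANOVA on shoot dry matter across N rates, then pairwise LSD
    tests between adjacent rates at significance level ``alpha``.  The
    control is N-limited by definition; any other treatment is N-limited
    iff its dry matter is significantly above the previous (lower) rate.
    A date where no treatment pair differs is flagged unusable.

    ``date_table`` needs columns ``n_rate`` and ``shoot_dm`` with >= 2
    replicate rows per rate and >= 3 rates.
    """
    rates = np.sort(date_table["n_rate"].unique())
    if len(rates) < 3:
        raise ValueError("need >= 3 N treatments for grouping")
    groups = [date_table.loc[date_table["n_rate"] == r, "shoot_dm"].to_numpy() for r in rates]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 replicate plots per treatment")
    f, p = _one_way_anova(groups)
    mse = float(
        sum(np.sum((g - g.mean()) ** 2) for g in groups)
        / (sum(len(g) for g in groups) - len(groups))
    )
    df_w = sum(len(g) for g in groups) - len(groups)
    limited = [rates[0]]
    pair_rows = []
    for lo, hi, g_lo, g_hi in zip(rates[:-1], rates[1:], groups[:-1], groups[1:]):
        p_pair = _lsd_pvalue(g_lo.mean(), len(g_lo), g_hi.mean(), len(g_hi), mse, df_w)
        increased = g_hi.mean() > g_lo.mean() and p_pair < alpha
        pair_rows.append({"low_rate": lo, "high_rate": hi, "p_value": p_pair, "increase": increased})
        if increased:
            limited.append(hi)
    non_limited = [r for r in rates if r not in limited]
    usable = p < alpha and len(non_limited) > 0
    if not usable:
        log.warning("sampling date unusable for curve fitting (F=%.3g, p=%.3g)", f, p)
    return GroupingResult(
        n_limited=list(limited),
        non_limited=non_limited,
        f_statistic=f,
        p_value=p,
        usable=usable,
        pairwise=pd.DataFrame(pair_rows),
    )


def critical_point(oblique: tuple[float, float], dm_max: float, stage: str = "") -> CriticalPoint:
    """Intersect the oblique N%-vs-DM line with the vertical at ``dm_max``.

    ``oblique`` is (slope, intercept) of the line fitted through the
    N-limited observations; the returned ordinate is the critical N
    concentration at the non-limited group's maximum dry matter.
    """
    if dm_max <= 0:
        raise ValueError("dm_max must be > 0")
    slope, intercept = oblique
    nc = slope * dm_max + intercept
    return CriticalPoint(dm=dm_max, nc=nc, stage=stage)


def fit_dilution_curve(points, component: str = "shoot") -> DilutionCurve:
    """Fit ``Nc = a * DM**-b`` to critical points by log-log least squares.

    Exact on noise-free power-law input.  R^2 is reported in the
    original (Nc) space.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 critical points")
    dm = np.array([p.dm for p in pts], dtype=float)
    nc = np.array([p.nc for p in pts], dtype=float)
    if np.any(dm <= 0) or np.any(nc <= 0):
        raise ValueError("critical points must have dm > 0 and nc > 0")
    if len(np.unique(dm)) < 3:
        raise ValueError("need >= 3 distinct dry-matter values")
    slope, log_a = np.polyfit(np.log(dm), np.log(nc), 1)
    a, b = float(np.exp(log_a)), float(-slope)
    fitted = a * dm ** (-b)
    sst = float(np.sum((nc - nc.mean()) ** 2))
    sse = float(np.sum((nc - fitted) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return DilutionCurve(
        a=a, b=b, dm_min=float(dm.min()), dm_max=float(dm.max()), r2=r2, component=component
    )


def critical_concentration(dm, curve: DilutionCurve):
    """Evaluate Nc (%) = a * DM**-b; warns outside the fitted DM range."""
    dm_arr = np.asarray(dm, dtype=float)
    if np.any(dm_arr <= 0):
        raise ValueError("dm must be > 0")
    if np.any(dm_arr < curve.dm_min) or np.any(dm_arr > curve.dm_max):
        warnings.warn(
            f"dry matter outside the curve validity range "
            f"[{curve.dm_min:.3g}, {curve.dm_max:.3g}] t/ha",
            stacklevel=2,
        )
    out = curve.a * dm_arr ** (-curve.b)
    return float(out) if np.isscalar(dm) else out


def compute_nni(na: float, nc: float) -> NNIValue:
    """Nitrogen nutrition index NNI = Na / Nc with its diagnosis."""
    if nc <= 0:
        raise ValueError("critical N concentration must be > 0")
    if na < 0:
        raise ValueError("measured N concentration must be >= 0")
    nni = na / nc
    label = "surplus" if nni > 1 else ("optimal" if nni == 1 else "deficient")
    return NNIValue(na=na, nc=nc, nni=nni, classification=label)


# ---------------------------------------------------------------------------
# model / results


class CriticalNDilution:
    """Critical-N dilution curve model for a plot-level trial table.

    Parameters
    ----------
    data : tidy plot table with columns ``stage``, ``n_rate``,
        ``shoot_dm`` (t/ha) and ``shoot_n`` (%); one row per plot x
        stage.  ``leaf_dm``/``leaf_n`` (kg/ha, %) etc. are used instead
        when ``component`` is ``"leaf"`` or ``"stem"``.
    component : which dry-matter basis to build the curve on
        ({"shoot", "leaf", "stem"}).
    """

    def __init__(self, data: pd.DataFrame, component: str = "shoot"):
        if component not in ("shoot", "leaf", "stem"):
            raise ValueError("component must be shoot, leaf or stem")
        self.component = component
        self.data = data.reset_index(drop=True)
        if component == "shoot":
            dm = self.data["shoot_dm"].to_numpy(dtype=float)
            n = self.data["shoot_n"].to_numpy(dtype=float)
        else:
            dm = self.data[f"{component}_dm"].to_numpy(dtype=float) / 1000.0  # kg -> t/ha
            n = self.data[f"{component}_n"].to_numpy(dtype=float)
        self._work = pd.DataFrame(
            {
                "stage": self.data["stage"].astype(str),
                "n_rate": self.data["n_rate"].to_numpy(dtype=float),
                "shoot_dm": dm,
                "shoot_n": n,
            }
        )
        # keep the sampling-date order of the input
        self._stage_order = list(dict.fromkeys(self._work["stage"]))

    def fit(self, alpha: float = 0.05) -> "DilutionCurveResults":
        """Run grouping, intersection and the allometric fit per date."""
        points, groupings, skipped = [], {}, []
        for stage in self._stage_order:
            date_table = self._work[self._work["stage"] == stage]
            grouping = classify_n_status(date_table, alpha=alpha)
            groupings[str(stage)] = grouping
            if not grouping.usable:
                skipped.append(str(stage))
                continue
            dm = date_table["shoot_dm"].to_numpy()
            n = date_table["shoot_n"].to_numpy()
            rates = date_table["n_rate"].to_numpy()
            lim = np.isin(rates, grouping.n_limited)
            non = np.isin(rates, grouping.non_limited)
            slope, intercept = np.polyfit(dm[lim], n[lim], 1)
            dm_max = float(dm[non].mean())
            try:
                points.append(critical_point((slope, intercept), dm_max, stage=str(stage)))
            except ValueError as err:
                log.warning("stage %s skipped: %s", stage, err)
                skipped.append(str(stage))
        curve = fit_dilution_curve(points, component=self.component)
        return DilutionCurveResults(self, curve, points, groupings, skipped)


class DilutionCurveResults:
    """Fitted dilution curve with its critical points and diagnostics."""

    def __init__(self, model, curve, points, groupings, skipped):
        self.model = model
        self.curve = curve
        self.critical_points = points
        self.groupings = groupings
        self.skipped_stages = skipped
        dm = np.array([p.dm for p in points])
        nc = np.array([p.nc for p in points])
        # standard errors from the log-log regression
        x, y = np.log(dm), np.log(nc)
        n = len(x)
        if n > 2:
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            s2 = float(resid @ resid) / (n - 2)
            sxx = float(np.sum((x - x.mean()) ** 2))
            self.bse_b = float(np.sqrt(s2 / sxx))
            self.bse_log_a = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))
        else:
            self.bse_b = self.bse_log_a = np.nan

    @property
    def params(self) -> dict:
        return {"a": self.curve.a, "b": self.curve.b}

    def predict(self, dm):
        """Critical N concentration (%) at the given dry matter (t/ha)."""
        return critical_concentration(dm, self.curve)

    def nni(self, na, dm) -> NNIValue:
        """NNI of a measured N concentration at a given dry matter."""
        return compute_nni(na, self.predict(dm))

    def nni_table(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-row NNI for a plot table (defaults to the fitting data)."""
        if data is None:
            table = self.model.data
            dm = self.model._work["shoot_dm"].to_numpy()
            na = self.model._work["shoot_n"].to_numpy()
        else:
            table = data
            dm = table["shoot_dm"].to_numpy(dtype=float)
            na = table["shoot_n"].to_numpy(dtype=float)
        nc = critical_concentration(dm, self.curve)
        out = table.copy()
        out["nc"] = nc
        out["nni"] = na / nc
        return out

    def summary(self) -> str:
        lines = [
            "Critical-N dilution curve (Nc = a * DM^-b)",
            "=" * 46,
            f"component:        {self.curve.component}",
            f"a (% at 1 t/ha):  {self.curve.a:.4f}  (log-a SE {self.bse_log_a:.4f})",
            f"b (dimensionless):{self.curve.b:9.4f}  (SE {self.bse_b:.4f})",
            f"R^2:              {self.curve.r2:.4f}",
            f"DM validity:      {self.curve.dm_min:.2f} - {self.curve.dm_max:.2f} t/ha",
            f"critical points:  {len(self.critical_points)}"
            + (f"  (skipped stages: {', '.join(self.skipped_stages)})" if self.skipped_stages else ""),
        ]
        for p in self.critical_points:
            lines.append(f"  {p.stage:>4}: DM={p.dm:6.3f} t/ha  Nc={p.nc:.4f} %")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot critical points and the fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dm = np.array([p.dm for p in self.critical_points])
        ax.scatter(dm, [p.nc for p in self.critical_points], label="critical points")
        grid = np.linspace(dm.min(), dm.max(), 200)
        ax.plot(grid, self.curve.a * grid ** (-self.curve.b), label=f"Nc = {self.curve.a:.2f} DM^-{self.curve.b:.2f}")
        ax.set_xlabel("shoot dry matter (t/ha)")
        ax.set_ylabel("critical N concentration (%)")
        ax.legend()
        return ax
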