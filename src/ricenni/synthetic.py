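"""Synthetic nitrogen-rate trial generator.

Emulates a two-site rice N-response experiment: five N rates (a zero-N
control plus increasing doses), replicated plots, destructive sampling at
four growth stages (tillering TR, jointing JT, heading HD, filling FL),
and five-band canopy reflectance linked monotonically to the nitrogen
nutrition index (NNI).

The generator is built so that, with all noise switched off, the full
downstream analysis (N-status grouping, oblique/vertical intersection,
allometric fit) recovers the true dilution-curve parameters to machine
precision.  Dry matter responds to N rate through a saturating ramp that
levels off at the middle rate, so the two highest rates share the same
biomass (they differ only in N concentration).  For N-limited rates the
plant N concentration is placed exactly on a straight line through the
critical point (DM_max, a * DM_max**-b), which is the geometry the
grouping-and-intersection procedure inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialConfig",
    "NoiseSpec",
    "generate_trial",
    "generate_reflectance",
    "dm_multiplier",
    "nni_for_rate",
]

#: Default shoot dry-matter reached at each stage by a non-limited plot (t/ha).
STAGE_DM = {"TR": 1.0, "JT": 3.0, "HD": 6.0, "FL": 9.0}

#: Leaf / stem / panicle dry-weight fractions per stage (panicle absent pre-HD).
ORGAN_FRACTIONS = {
    "TR": (0.55, 0.45, 0.00),
    "JT": (0.45, 0.55, 0.00),
    "HD": (0.32, 0.48, 0.20),
    "FL": (0.25, 0.45, 0.30),
}

#: Organ N concentration relative to the shoot mean (leaf-enriched, stem-poor).
LEAF_N_RATIO = 1.4
PANICLE_N_RATIO = 1.1


@dataclass(frozen=True)
class NoiseSpec:
    """Relative noise levels (standard deviations) for the generator.

    ``dm``, ``n_conc`` and ``yield_`` are multiplicative lognormal
    (median 1), which keeps biomass and concentrations positive;
    ``reflectance`` is additive Gaussian, clipped to [0, 1].
    """

    dm: float = 0.05
    n_conc: float = 0.03
    reflectance: float = 0.02
    yield_: float = 0.04

    def __post_init__(self) -> None:
        for name in ("dm", "n_conc", "reflectance", "yield_"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise SD {name!r} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TrialConfig:
    """Design of one synthetic single-cultivar N-rate trial.

    Parameters
    ----------
    n_rates : applied N (kg/ha), strictly increasing, first element 0.
    plots_per_rate : replicate plots per treatment (>= 2; ANOVA grouping
        needs replication).  The default 4 gives 5 x 4 x 4 = 80 records.
    stages : ordered growth-stage labels sampled destructively.
    true_curve : (a, b) of the critical dilution curve Nc = a * DM**-b,
        a in % at 1 t/ha, b dimensionless in (0, 1).
    plateau_true : (slope, intercept, breakpoint, plateau) of the
        NNI -> relative-yield linear-plateau response.
    y_max : attainable yield (kg/ha) at relative yield 1.
    apgn_true : N uptake per 100 kg grain (kg).
    noise : relative noise SDs, see :class:`NoiseSpec`.
    seed : master seed; all randomness descends from it.
    rate_sat : N rate (kg/ha) at which dry matter saturates.  With the
        default 120 the two highest default rates sit on the plateau.
    dm_floor : dry-matter multiplier of the zero-N control (fraction of
        the non-limited biomass).
    oblique_strength : slope of the N-limited N%-vs-DM line, as a
        fraction of Nc(DM_max)/DM_max; larger means N concentration
        climbs faster with rate among limited treatments.
    nni_plateau : NNI assigned to non-N-limited (saturated) rates; must
        exceed 0 and normally sits at or above the yield breakpoint.
    """

    n_rates: tuple[float, ...] = (0.0, 60.0, 120.0, 160.0, 200.0)
    plots_per_rate: int = 4
    stages: tuple[str, ...] = ("TR", "JT", "HD", "FL")
    true_curve: tuple[float, float] = (2.24, 0.35)
    plateau_true: tuple[float, float, float, float] = (1.088, 0.08, 1.01, 1.01)
    y_max: float = 10573.3
    apgn_true: float = 1.97
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    cultivar: str = "YJ-37"
    rate_sat: float = 120.0
    dm_floor: float = 0.55
    oblique_strength: float = 0.45
    nni_plateau: float = 1.05
    stage_dm: dict = field(default_factory=lambda: dict(STAGE_DM))

    def __post_init__(self) -> None:
        rates = np.asarray(self.n_rates, dtype=float)
        if rates.size < 3:
            raise ValueError("need at least 3 N rates")
        if rates[0] != 0.0:
            raise ValueError("first N rate must be the 0 control")
        if np.any(np.diff(rates) <= 0):
            raise ValueError("n_rates must be strictly increasing")
        if self.plots_per_rate < 2:
            raise ValueError("plots_per_rate must be >= 2 (replication needed)")
        a, b = self.true_curve
        if a <= 0:
            raise ValueError("a_true must be > 0")
        if not 0 < b < 1:
            raise ValueError("b_true must lie in (0, 1)")
        if not 0 < self.dm_floor <= 1:
            raise ValueError("dm_floor must lie in (0, 1]")
        if self.nni_plateau <= 0:
            raise ValueError("nni_plateau must be > 0")
        for s in self.stages:
            if s not in self.stage_dm:
                raise ValueError(f"no stage_dm entry for stage {s!r}")
            if s not in ORGAN_FRACTIONS:
                raise ValueError(f"unknown stage label {s!r}")

    def with_noise(self, **kwargs: float) -> "TrialConfig":
        return replace(self, noise=replace(self.noise, **kwargs))


def dm_multiplier(config: TrialConfig, n_rate: float) -> float:
    """Dry-matter multiplier m(rate): saturating ramp from dm_floor to 1."""
    frac = min(n_rate, config.rate_sat) / config.rate_sat
    return config.dm_floor + (1.0 - config.dm_floor) * frac


def nni_for_rate(config: TrialConfig, n_rate: float) -> float:
    """True NNI implied by an N rate.

    N-limited rates (up to and including the saturation rate) follow
    NNI = m**b * (1 + c*(m - 1)) with m the dry-matter multiplier, which
    places their N concentration exactly on the oblique line through the
    critical point (the saturation rate itself lands on NNI = 1, i.e. on
    the dilution curve); rates beyond saturation take the configured
    plateau NNI - same biomass, higher N concentration.
    """
    if n_rate > config.rate_sat:
        return config.nni_plateau
    m = dm_multiplier(config, n_rate)
    _, b = config.true_curve
    return m**b * (1.0 + config.oblique_strength * (m - 1.0))


def _plateau_predict(params: tuple[float, float, float, float], nni: float) -> float:
    slope, intercept, breakpoint, plateau = params
    return plateau if nni >= breakpoint else slope * nni - intercept


def _lognormal_factor(rng: np.random.Generator, sd: float, size=None):
    if sd == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


def generate_trial(config: TrialConfig) -> pd.DataFrame:
    """Generate the plot-level agronomic table of one trial.

    Returns a tidy frame with one row per plot x stage:
    ``plot_id, cultivar, stage, n_rate, leaf_dm, stem_dm, panicle_dm``
    (kg/ha), ``leaf_n, stem_n, panicle_n`` (%), ``shoot_dm`` (t/ha),
    ``shoot_n`` (%, dry-weight-weighted mean) and ``yield_kg_ha``
    (final-stage rows only, NaN elsewhere).

    Deterministic for a fixed config (bit-identical across calls).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    a_true, b_true = config.true_curve
    rows = []
    final_stage = config.stages[-1]
    for rate in config.n_rates:
        m = dm_multiplier(config, rate)
        nni_true = nni_for_rate(config, rate)
        for plot in range(config.plots_per_rate):
            plot_id = f"{config.cultivar}-N{int(rate)}-P{plot + 1}"
            ry = _plateau_predict(config.plateau_true, nni_true)
            yield_kg = config.y_max * ry * _lognormal_factor(rng, config.noise.yield_)
            for stage in config.stages:
                shoot_t = m * config.stage_dm[stage]  # t/ha before noise
                f_leaf, f_stem, f_pan = ORGAN_FRACTIONS[stage]
                organ_kg = 1000.0 * shoot_t * np.array([f_leaf, f_stem, f_pan])
                organ_kg = organ_kg * _lognormal_factor(rng, config.noise.dm, 3)
                shoot_kg = organ_kg.sum()
                # plant N% on the dilution geometry, then organ partition
                plant_n = nni_true * a_true * (m * config.stage_dm[stage]) ** (-b_true)
                plant_n *= _lognormal_factor(rng, config.noise.n_conc)
                r_leaf = LEAF_N_RATIO
                r_pan = PANICLE_N_RATIO if f_pan > 0 else 0.0
                w = organ_kg / shoot_kg
                r_stem = (1.0 - w[0] * r_leaf - w[2] * r_pan) / w[1]
                organ_n = plant_n * np.array([r_leaf, r_stem, r_pan])
                rows.append(
                    {
                        "plot_id": plot_id,
                        "cultivar": config.cultivar,
                        "stage": stage,
                        "n_rate": rate,
                        "leaf_dm": organ_kg[0],
                        "stem_dm": organ_kg[1],
                        "panicle_dm": organ_kg[2],
                        "leaf_n": organ_n[0],
                        "stem_n": organ_n[1],
                        "panicle_n": organ_n[2],
                        "shoot_dm": shoot_kg / 1000.0,
                        "shoot_n": float(w @ organ_n),
                        "nni_true": nni_true,
                        "yield_kg_ha": yield_kg if stage == final_stage else np.nan,
                    }
                )
    frame = pd.DataFrame(rows)
    frame["stage"] = pd.Categorical(frame["stage"], categories=list(config.stages), ordered=True)
    return frame


def generate_reflectance(
    nni_values, config: TrialConfig, plot_ids=None, stages=None
) -> pd.DataFrame:
    """Five-band canopy reflectance monotonically linked to NNI.

    The deterministic part makes NIR (840 nm) increase and red (650 nm)
    decrease with NNI, so NDVI-family indices rise with N status; the
    red edge tracks NIR weakly and the visible bands shrink slowly.
    Additive Gaussian noise is clipped to keep reflectance in [0, 1].
    This is an empirical monotone surrogate, not a radiative-transfer
    canopy model.
    """
    nni = np.asarray(nni_values, dtype=float)
    if np.any(nni <= 0):
        raise ValueError("NNI values must be > 0")
    if np.any(nni > 2):
        raise ValueError("NNI values above 2 are outside the supported range")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    t = nni / 2.0  # (0, 1]
    bands = {
        "b450": 0.06 - 0.02 * t,
        "g560": 0.14 - 0.04 * t,
        "r650": 0.32 - 0.14 * t,
        "re730": 0.20 + 0.10 * t,
        "nir840": 0.15 + 0.45 * t,
    }
    out = {}
    for name, clean in bands.items():
        noisy = clean + rng.normal(0.0, config.noise.reflectance, size=nni.shape) \
            if config.noise.reflectance > 0 else clean
        # truncate into [0, 1]; the tiny positive floor keeps ratio
        # indices (NIR/R, NIR/G) defined under heavy noise
        out[name] = np.clip(noisy, 1e-4, 1.0)
    frame = pd.DataFrame(out)
    if plot_ids is not None:
        frame.insert(0, "plot_id", np.asarray(plot_ids))
    if stages is not None:
        frame.insert(1 if plot_ids is not None else 0, "stage", np.asarray(stages))
    frame["nni_true"] = nni
    return frame
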