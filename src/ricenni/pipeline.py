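"""End-to-end pipeline: trial data -> curve -> NNI -> inversion -> plan.

One configuration object drives the whole chain.  All randomness flows
from a single seed split into named substreams (trial generation, the
train/test split, the forest), so a run is reproducible from one number;
every output directory carries a run manifest recording the
configuration, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dilution import CriticalNDilution
from .gra import gray_relational_analysis, rank_and_select
from .indices import INDEX_NAMES, indices_table
from .inversion import InversionModelSpec, NNIInversion
from .io import read_plot_table, read_reflectance_table, write_plot_table, write_recommendations
from .nbalance import NBalanceInputs, NitrogenBalance
from .nbalance import LinearPlateau
from .synthetic import NoiseSpec, TrialConfig, generate_reflectance, generate_trial

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


def _substream_seed(seed: int, name: str) -> int:
    """Deterministic named child seed (< 2**31) of the master seed."""
    ss = np.random.SeedSequence([seed, abs(hash_name(name))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_name(name: str) -> int:
    # stable across processes (unlike built-in hash on str)
    h = 0
    for ch in name:
        h = (h * 31 + ord(ch)) % (2**31)
    return h


@dataclass
class PipelineConfig:
    """Configuration of one full run (synthetic or file-based)."""

    output_dir: str = "ricenni_out"
    plot_table: str | None = None  # CSV path; None -> synthesize
    reflectance_table: str | None = None  # CSV path; None -> synthesize
    seed: int = 0
    curve_component: str = "shoot"
    gca_threshold: float = 0.7
    gca_rho: float = 0.5
    ndre_dialect: str = "as_printed"
    soil_mask_threshold: float = 0.3
    train_fraction: float = 0.7
    inversion: dict = field(default_factory=dict)  # InversionModelSpec overrides
    balance: dict = field(default_factory=dict)  # NBalanceInputs fields
    basal_by_treatment: dict = field(default_factory=dict)  # rate -> basal kg/ha
    topdress_stages: tuple = ("JT", "HD")
    split_ratios: tuple = (2.0, 1.0)
    saturated_ry: str = "plateau_c"
    trial: dict = field(default_factory=dict)  # TrialConfig overrides
    noise: dict = field(default_factory=dict)  # NoiseSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("topdress_stages", "split_ratios"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def trial_config(self) -> TrialConfig:
        noise = NoiseSpec(**self.noise) if self.noise else NoiseSpec()
        overrides = dict(self.trial)
        for name in ("n_rates", "stages", "true_curve", "plateau_true"):
            if name in overrides:
                overrides[name] = tuple(overrides[name])
        return TrialConfig(
            seed=_substream_seed(self.seed, "trial"), noise=noise, **overrides
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    curve_results: object
    selected_indices: list
    inversion_results: object
    plateau_results: object
    recommendations: pd.DataFrame
    manifest: dict


class StageFailure(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageFailure:
                raise
            except Exception as err:
                raise StageFailure(f"[{name}] {err}") from err

        return wrapper

    return deco


@_stage("load")
def _load_plot_table(config: PipelineConfig, trial_cfg: TrialConfig) -> pd.DataFrame:
    if config.plot_table is not None:
        if not Path(config.plot_table).exists():
            raise FileNotFoundError(f"plot table {config.plot_table!r} does not exist")
        return read_plot_table(config.plot_table)
    return generate_trial(trial_cfg)


@_stage("spectral")
def _load_reflectance(config: PipelineConfig, trial_cfg, plot_table) -> pd.DataFrame:
    if config.reflectance_table is not None:
        if not Path(config.reflectance_table).exists():
            raise FileNotFoundError(
                f"reflectance table {config.reflectance_table!r} does not exist"
            )
        return read_reflectance_table(config.reflectance_table)
    return generate_reflectance(
        plot_table["nni_true"].to_numpy()
        if "nni_true" in plot_table
        else np.ones(len(plot_table)),
        trial_cfg,
        plot_ids=plot_table["plot_id"],
        stages=plot_table["stage"].astype(str),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full diagnosis-and-recommendation chain.

    Stages: data load/synthesis -> dilution-curve fit -> per-plot NNI ->
    vegetation indices -> gray relational selection -> random-forest
    inversion -> linear-plateau fit -> per-treatment topdressing plan.
    Writes CSV/JSON reports plus ``manifest.json`` into ``output_dir``;
    idempotent for a fixed config and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_cfg = config.trial_config()

    plot_table = _load_plot_table(config, trial_cfg)
    write_plot_table(plot_table, out / "plot_table.csv")

    # --- dilution curve & NNI -------------------------------------------
    try:
        curve_res = CriticalNDilution(plot_table, component=config.curve_component).fit()
        nni_table = curve_res.nni_table(plot_table)
    except Exception as err:
        raise StageFailure(f"[curve] {err}") from err
    (out / "curve.json").write_text(
        json.dumps(
            {
                "component": curve_res.curve.component,
                "a": curve_res.curve.a,
                "b": curve_res.curve.b,
                "r2": curve_res.curve.r2,
                "dm_min": curve_res.curve.dm_min,
                "dm_max": curve_res.curve.dm_max,
                "skipped_stages": curve_res.skipped_stages,
            },
            indent=2,
        )
    )
    nni_table.to_csv(out / "nni.csv", index=False)

    # --- spectral indices ------------------------------------------------
    reflectance = _load_reflectance(config, trial_cfg, plot_table)
    try:
        idx_table = indices_table(reflectance, ndre_dialect=config.ndre_dialect)
    except Exception as err:
        raise StageFailure(f"[spectral] {err}") from err
    idx_table.to_csv(out / "indices.csv", index=False)

    # --- join NNI to indices and run GCA per stage ----------------------
    try:
        joined = idx_table.reset_index(drop=True).copy()
        joined["nni"] = nni_table["nni"].to_numpy()
        joined["n_rate"] = nni_table["n_rate"].to_numpy()
        if "cultivar" in nni_table:
            joined["cultivar"] = nni_table["cultivar"].to_numpy()
        degrees_by_stage = {}
        for stage, sub in joined.groupby("stage", observed=True):
            result = gray_relational_analysis(
                sub["nni"].to_numpy(),
                {name: sub[name].to_numpy() for name in INDEX_NAMES},
                rho=config.gca_rho,
            )
            degrees_by_stage[str(stage)] = result.degrees
        selected = rank_and_select(
            degrees_by_stage, threshold=config.gca_threshold, order=INDEX_NAMES
        )
        if not selected:
            log.warning("GCA selected no indices; falling back to all nine")
            selected = list(INDEX_NAMES)
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure(f"[gca] {err}") from err
    pd.DataFrame(degrees_by_stage).rename_axis("index").to_csv(out / "gca_degrees.csv")

    # --- random-forest inversion ----------------------------------------
    try:
        spec = InversionModelSpec(
            features=tuple(selected),
            seed=_substream_seed(config.seed, "forest"),
            **config.inversion,
        )
        inv = NNIInversion(joined, features=tuple(selected)).fit(
            spec=spec,
            train_fraction=config.train_fraction,
            seed=_substream_seed(config.seed, "split"),
        )
    except Exception as err:
        raise StageFailure(f"[inversion] {err}") from err
    inv.save_report(out / "inversion_metrics.json")

    # --- linear plateau on the final stage ------------------------------
    try:
        final = plot_table[plot_table["yield_kg_ha"].notna()].copy()
        final["relative_yield"] = final["yield_kg_ha"] / final["yield_kg_ha"].max()
        final_nni = nni_table.loc[final.index, "nni"]
        plateau_res = LinearPlateau(final["relative_yield"], final_nni).fit()
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure(f"[plateau] {err}") from err
    (out / "plateau.json").write_text(
        json.dumps(
            {
                "slope": plateau_res.params.slope,
                "intercept": plateau_res.params.intercept,
                "breakpoint": plateau_res.params.breakpoint,
                "plateau": plateau_res.params.plateau,
                "r2": plateau_res.r2,
            },
            indent=2,
        )
    )

    # --- topdressing recommendation -------------------------------------
    try:
        balance_inputs = NBalanceInputs(
            y_max=config.balance.get("y_max", float(final["yield_kg_ha"].max())),
            apgn=config.balance.get("apgn", trial_cfg.apgn_true),
            ns=config.balance.get("ns", _control_n_uptake(plot_table)),
            nue=config.balance.get("nue", 0.426),
        )
        calculator = NitrogenBalance(
            plateau=plateau_res.params,
            inputs=balance_inputs,
            stages=config.topdress_stages,
            split_ratios=config.split_ratios,
            saturated_ry=config.saturated_ry,
        )
        # inverted NNI per treatment at the diagnosis stage (last stage with data)
        diag = inv.predict(joined)
        nni_by_treatment, basal_by_treatment = {}, {}
        for rate, sub in diag.groupby("n_rate"):
            label = f"N{sorted(diag['n_rate'].unique()).index(rate)}"
            nni_by_treatment[label] = sub["nni_pred"].to_numpy()
            basal_by_treatment[label] = config.basal_by_treatment.get(
                label, 0.4 * float(rate)
            )
        recommendations = calculator.recommend_table(nni_by_treatment, basal_by_treatment)
        plans = {
            row["treatment"]: calculator.recommend(
                float(np.mean(nni_by_treatment[row["treatment"]])),
                basal_by_treatment[row["treatment"]],
            )
            for _, row in recommendations.iterrows()
        }
        write_recommendations(plans, out / "recommendations.csv")
        recommendations.round(2).to_csv(out / "recommendations_replicates.csv", index=False)
    except StageFailure:
        raise
    except Exception as err:
        raise StageFailure(f"[recommend] {err}") from err

    manifest = {
        "package": "ricenni",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "curve": {"a": curve_res.curve.a, "b": curve_res.curve.b, "r2": curve_res.curve.r2},
        "selected_indices": list(selected),
        "plateau": dataclasses.asdict(plateau_res.params),
        "n_records": int(len(plot_table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        config=config,
        curve_results=curve_res,
        selected_indices=list(selected),
        inversion_results=inv,
        plateau_results=plateau_res,
        recommendations=recommendations,
        manifest=manifest,
    )


def _control_n_uptake(plot_table: pd.DataFrame) -> float:
    """Soil N supply Ns: plant N accumulation of the zero-N control at the
    final sampled stage (kg/ha), averaged over replicate plots."""
    control = plot_table[plot_table["n_rate"] == 0]
    final_stage = control["stage"].astype(str).iloc[-1]
    rows = control[control["stage"].astype(str) == final_stage]
    pna = (
        rows["leaf_dm"] * rows["leaf_n"]
        + rows["stem_dm"] * rows["stem_n"]
        + rows["panicle_dm"] * rows["panicle_n"]
    ) / 100.0
    return float(pna.mean())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
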