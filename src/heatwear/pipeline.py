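"""End-to-end pipeline: simulate/ingest -> exposure -> QC -> link -> models.

Each stage writes plain-CSV intermediates under the output directory and
contributes row counts to a JSON run manifest that records the config
hash, seed and package version, so identical configurations produce
byte-identical output trees.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, exposure, linkage, models, wearable_qc
from .io import SCHEMAS, read_csv, validate_inputs
from .synthetic_data import SimConfig, simulate_outcomes, simulate_sites
from .thresholds import Thresholds

__all__ = ["PipelineConfig", "run_all", "OUTCOME_SETTINGS"]

#: per-outcome model wiring: panel kind, outcome column, heat metric,
#: fallback air-temperature metric, and binary extreme flags
OUTCOME_SETTINGS = {
    "steps": {
        "kind": "day",
        "outcome": "steps",
        "heat": "wbgt_max_day",
        "temp_metric": "tmax_day",
        "heat_flag": "is_heat_stress_day",
        "rain_flag": "is_heavy_rain_day",
    },
    "sleep": {
        "kind": "night",
        "outcome": "duration_h",
        "heat": "hi_min_night",
        "temp_metric": "tmin_night",
        "heat_flag": "is_heat_stress_night",
        "rain_flag": "is_heavy_rain_day",
    },
    "hr": {
        "kind": "night",
        "outcome": "hr_night_mean",
        "heat": "hi_min_night",
        "temp_metric": "tmin_night",
        "heat_flag": "is_heat_stress_night",
        "rain_flag": "is_heavy_rain_day",
    },
}


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``simulate`` holds :class:`SimConfig` overrides (inputs are
    generated) or ``inputs`` maps input kinds to existing CSV paths.
    ``thresholds`` overrides analysis cut-offs; every override is logged
    in the manifest.
    """

    out_dir: str = "heatwear_out"
    seed: int = 7
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)
    outcomes: tuple[str, ...] = ("steps", "sleep", "hr")
    alpha: float = 0.05
    candidates: tuple[str, ...] = models.CANDIDATE_ORDER
    run_loso: bool = True
    run_metric_comparison: bool = True
    run_extremes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcomes", "candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical(self) -> dict[str, Any]:
        d = {
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "thresholds": self.thresholds,
            "outcomes": list(self.outcomes),
            "alpha": self.alpha,
            "candidates": list(self.candidates),
            "run_loso": self.run_loso,
            "run_metric_comparison": self.run_metric_comparison,
            "run_extremes": self.run_extremes,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return len(df)


def _simulate_inputs(cfg: PipelineConfig, out: Path) -> tuple[dict, dict]:
    overrides = dict(cfg.simulate or {})
    sim = SimConfig(**overrides)
    bundle = simulate_outcomes(sim, cfg.seed)
    stations, villages = simulate_sites(sim, cfg.seed)
    inputs_dir = out / "inputs"
    paths = {}
    for kind, df in (
        ("weather", bundle["weather"]),
        ("steps", bundle["steps"]),
        ("sleep", bundle["sleep"]),
        ("hr", bundle["hr"]),
        ("roster", bundle["roster"]),
    ):
        p = inputs_dir / f"{kind}.csv"
        _write(df, p)
        paths[kind] = str(p)
    _write(stations, inputs_dir / "stations.csv")
    _write(villages, inputs_dir / "villages.csv")
    paths["stations"] = str(inputs_dir / "stations.csv")
    paths["villages"] = str(inputs_dir / "villages.csv")
    truth_dir = out / "truth"
    _write(bundle["truth"], truth_dir / "participants.csv")
    for name, panel in bundle["panels"].items():
        _write(panel, truth_dir / f"panel_{name}.csv")
    (truth_dir / "ledger.json").write_text(
        json.dumps(bundle["ledger"], sort_keys=True, indent=2)
    )
    meta = {
        "sim_config": sim.asdict(),
        "ledger": bundle["ledger"],
        "study_start": sim.start_date,
        "study_days": sim.study_days,
    }
    return paths, meta


def _fit_block(
    panel: pd.DataFrame,
    settings: dict,
    cfg: PipelineConfig,
    out: Path,
    outcome_name: str,
    manifest_stage: dict,
) -> None:
    spec = models.ModelSpec(
        outcome=settings["outcome"],
        heat=settings["heat"],
        precip="rain_total",
    )
    try:
        spec, quad_audit, resid = models.add_quadratic_if_curved(
            spec, panel, cfg.alpha
        )
        _write(quad_audit, out / f"{outcome_name}_quadratic_lrt.csv")
        _write(resid, out / f"{outcome_name}_residuals.csv")
        spec, trail = models.stepwise_build(spec, cfg.candidates, panel, cfg.alpha)
        _write(trail, out / f"{outcome_name}_stepwise.csv")
        fit = models.fit_lmm(spec, panel)
    except (models.FitError, ValueError) as exc:
        manifest_stage[outcome_name] = {"skipped": str(exc)}
        return

    b1 = fit.params.get(settings["heat"], np.nan)
    b2 = fit.params.get(f"I({settings['heat']} ** 2)", 0.0)
    coef = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_lower": fit.conf_int["lower"].to_numpy(),
            "ci_upper": fit.conf_int["upper"].to_numpy(),
        }
    )
    summary = pd.DataFrame(
        [
            {
                "outcome": outcome_name,
                "formula": spec.formula(),
                "n_obs": fit.nobs,
                "n_participants": fit.n_participants,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "re_var": fit.re_var,
                "resid_var": fit.resid_var,
                "effect_at_20C": models.marginal_effect(b1, b2, 20.0),
                "effect_at_30C": models.marginal_effect(b1, b2, 30.0),
            }
        ]
    )
    _write(coef, out / f"{outcome_name}_coefficients.csv")
    _write(summary, out / f"{outcome_name}_model_summary.csv")
    manifest_stage[outcome_name] = {
        "n_obs": fit.nobs,
        "n_participants": fit.n_participants,
        "formula": spec.formula(),
    }

    if cfg.run_metric_comparison:
        try:
            comp = models.compare_heat_metrics(
                spec,
                panel,
                {"heat_metric": settings["heat"],
                 "air_temperature": settings["temp_metric"]},
            )
            _write(comp, out / f"{outcome_name}_metric_aic.csv")
        except (models.FitError, ValueError) as exc:
            manifest_stage[outcome_name]["metric_comparison"] = f"skipped: {exc}"
    if cfg.run_loso:
        try:
            loso = models.loso_cv(spec, panel)
            _write(loso.per_participant, out / f"{outcome_name}_loso.csv")
            manifest_stage[outcome_name]["loso_mean_r2"] = loso.mean_r2
            manifest_stage[outcome_name]["loso_mean_rmse"] = loso.mean_rmse
        except (models.FitError, ValueError) as exc:
            manifest_stage[outcome_name]["loso"] = f"skipped: {exc}"
    if cfg.run_extremes:
        try:
            ext_spec = models.ModelSpec(
                outcome=settings["outcome"],
                heat=settings["heat_flag"],
                precip=settings["rain_flag"],
                covariates=spec.covariates,
            )
            ext = models.extreme_contrast(ext_spec, panel)
            ext_coef = pd.DataFrame(
                {
                    "term": ext.params.index,
                    "estimate": ext.params.to_numpy(),
                    "se": ext.bse.to_numpy(),
                    "p": ext.pvalues.to_numpy(),
                    "ci_lower": ext.conf_int["lower"].to_numpy(),
                    "ci_upper": ext.conf_int["upper"].to_numpy(),
                }
            )
            _write(ext_coef, out / f"{outcome_name}_extreme_coefficients.csv")
        except (models.FitError, ValueError) as exc:
            manifest_stage[outcome_name]["extremes"] = f"skipped: {exc}"


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage order: (optional) simulation, input validation, exposure
    summaries, wearable QC, linkage, models.  Any stage failure aborts
    with the stage name; the manifest written so far is preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "threshold_overrides": dict(cfg.thresholds),
        "stages": {},
    }
    thresholds = Thresholds.from_mapping(cfg.thresholds)

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2, default=str)
        )
        raise

    # --- inputs ---
    try:
        if cfg.simulate is not None:
            paths, meta = _simulate_inputs(cfg, out)
            manifest["stages"]["simulate"] = {
                "ledger": meta["ledger"],
                "study_start": meta["study_start"],
                "study_days": meta["study_days"],
            }
            study_start = pd.Timestamp(meta["study_start"])
            study_days = int(meta["study_days"])
        elif cfg.inputs is not None:
            paths = dict(cfg.inputs)
            study_start = None
            study_days = None
        else:
            raise ValueError("config needs either 'simulate' or 'inputs'")
        report = validate_inputs(
            {k: v for k, v in paths.items() if k in SCHEMAS and k != "sites"}
            | {"sites": paths["stations"]}
        )
        if not report.ok:
            _write(report.as_frame(), out / "validation_issues.csv")
            raise ValueError(
                f"input validation failed with {len(report.issues)} issue(s); "
                f"see validation_issues.csv"
            )
        manifest["stages"]["validate"] = {"issues": 0}
    except Exception as exc:  # noqa: BLE001
        fail("inputs", exc)

    # --- exposure ---
    try:
        weather = read_csv("weather", paths["weather"])
        daily = exposure.summarize_daily(weather, thresholds)
        n = _write(daily, out / "daily_weather.csv")
        ext_rows = []
        for (station, season), grp in daily.groupby(["station_id", "season"]):
            counts = exposure.extreme_indexes(grp)
            ext_rows.append({"station_id": station, "season": season, **counts})
        extremes = pd.DataFrame(ext_rows).sort_values(
            ["station_id", "season"]
        ).reset_index(drop=True)
        _write(extremes, out / "extreme_indexes.csv")
        manifest["stages"]["exposure"] = {"daily_rows": n}
    except Exception as exc:  # noqa: BLE001
        fail("exposure", exc)

    # --- QC ---
    try:
        roster = read_csv("roster", paths["roster"])
        steps_raw = read_csv("steps", paths["steps"])
        sleep_raw = read_csv("sleep", paths["sleep"])
        hr_raw = read_csv("hr", paths["hr"])
        if study_start is None:
            study_start = min(
                steps_raw["timestamp"].min().normalize(),
                sleep_raw["onset"].min().normalize(),
            )
        if study_days is None:
            last = max(
                steps_raw["timestamp"].max(), sleep_raw["offset"].max()
            ).normalize()
            study_days = int((last - study_start).days) + 1
        ages = (
            (study_start - roster.set_index("participant_id")["birth_date"])
            .dt.days / 365.25
        )

        audit = wearable_qc.QCAudit()
        steps_clean = wearable_qc.clean_steps(steps_raw, audit=audit)
        steps_daily = wearable_qc.daily_steps_table(steps_clean, thresholds)
        nights = wearable_qc.clean_sleep(sleep_raw, thresholds, audit=audit)
        nights["insufficient"] = [
            wearable_qc.flag_insufficient_sleep(
                d, ages[p], thresholds
            )
            for d, p in zip(nights["duration_h"], nights["participant_id"])
        ]
        hr_day, hr_night, hr_nightly = wearable_qc.clean_hr(
            hr_raw, ages, thresholds, audit=audit
        )

        kept = {}
        for stream, table, col in (
            ("steps", steps_daily, "date"),
            ("sleep", nights, "night_date"),
            ("hr", hr_nightly, "night_date"),
        ):
            coverage = (
                table.groupby("participant_id")[col]
                .nunique()
                .rename("valid_days")
                .reset_index()
            )
            coverage["study_days"] = study_days
            kept[stream] = wearable_qc.completeness_filter(
                coverage, thresholds.completeness_fraction
            )
        steps_daily = steps_daily[
            steps_daily["participant_id"].isin(kept["steps"])
        ].reset_index(drop=True)
        nights = nights[nights["participant_id"].isin(kept["sleep"])].reset_index(
            drop=True
        )
        hr_nightly = hr_nightly[
            hr_nightly["participant_id"].isin(kept["hr"])
        ].reset_index(drop=True)

        _write(steps_daily, out / "qc_steps_daily.csv")
        _write(nights, out / "qc_sleep_nights.csv")
        _write(hr_day, out / "qc_hr_day_intervals.csv")
        _write(hr_night, out / "qc_hr_night_intervals.csv")
        _write(hr_nightly, out / "qc_hr_nightly.csv")
        _write(audit.as_frame(), out / "qc_report.csv")
        manifest["stages"]["qc"] = {
            "steps_days": len(steps_daily),
            "sleep_nights": len(nights),
            "hr_nights": len(hr_nightly),
            "exclusions": audit.counts,
            "complete_participants": {
                k: len(v) for k, v in sorted(kept.items())
            },
        }
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)

    # --- linkage ---
    try:
        stations = pd.read_csv(paths["stations"])
        villages = pd.read_csv(paths["villages"])
        participants = linkage.derive_covariates(roster, study_start)
        participants = linkage.assign_stations(participants, villages, stations)
        _write(participants, out / "participants.csv")
        panels = {
            "steps": linkage.build_panel(steps_daily, daily, participants, "day"),
            "sleep": linkage.build_panel(nights, daily, participants, "night"),
            "hr": linkage.build_panel(hr_nightly, daily, participants, "night"),
        }
        for name, panel in panels.items():
            _write(panel, out / f"panel_{name}.csv")
        manifest["stages"]["link"] = {
            name: len(panel) for name, panel in panels.items()
        }
    except Exception as exc:  # noqa: BLE001
        fail("link", exc)

    # --- models ---
    try:
        stage: dict[str, Any] = {}
        for outcome_name in cfg.outcomes:
            settings = OUTCOME_SETTINGS[outcome_name]
            _fit_block(
                panels[outcome_name], settings, cfg, out, outcome_name, stage
            )
        manifest["stages"]["models"] = stage
    except Exception as exc:  # noqa: BLE001
        fail("models", exc)

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str)
    )
    return manifest
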