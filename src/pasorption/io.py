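"""CSV schemas, configuration handling and the pipeline entry points.

All files are headered UTF-8 CSV with period decimals; temperatures appear
in degrees Celsius in every file and on the CLI (Kelvin is internal only).

Schemas
-------
measurements.csv : condition_id, ethanol_pct, temperature_C, replicate,
    role{control|trial}, a_background, a_final  (or conc_mg_per_L directly)
calibration.csv : conc_mg_per_L, absorbance
isotherm_points.csv : c_mg_per_L, q_mg_per_mg [, ethanol_pct, temperature_C]
subunits.csv : species, position, nmol
gpc.csv : elution_mL, signal        gpc_cal.csv : elution_mL, log10_mw
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from .assay import AssayCalibration, concentration_from_absorbance, AbsorbanceReading
from .errors import ConfigError
from .ramp import RampSchedule, simulate_ramp
from .reference import empirical_fractions
from .scenario import ScenarioSpec, scenario_report
from .sorption import (
    BatchSystem,
    Condition,
    RationalSurfaceCoefficients,
    DEFAULT_KEQ_COEFFS,
    DEFAULT_SCWM_COEFFS,
)
from .stats import anova_letters, model_error, summarize_desorption
from .synth import NoiseModel, generate_measurements

logger = logging.getLogger("pasorption")

__all__ = [
    "RunConfig",
    "load_config",
    "run_pipeline",
    "read_measurements",
    "write_measurements",
    "read_calibration_standards",
    "read_isotherm_points",
    "write_isotherm_points",
    "read_subunit_profile",
    "write_subunit_profile",
    "read_gpc_trace",
    "write_gpc_trace",
    "quantify_measurements",
    "coefficients_from_dict",
    "coefficients_to_dict",
]

# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    base = ["condition_id", "ethanol_pct", "temperature_C", "replicate", "role"]
    _require_columns(df, base, path)
    if "conc_mg_per_L" not in df.columns:
        _require_columns(df, ["a_background", "a_final"], path)
    bad = set(df["role"].unique()) - {"control", "trial"}
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_calibration_standards(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["conc_mg_per_L", "absorbance"], path)
    return df[["conc_mg_per_L", "absorbance"]].to_numpy(dtype=float)


def read_isotherm_points(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["c_mg_per_L", "q_mg_per_mg"], path)
    return df


def write_isotherm_points(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_subunit_profile(path) -> comp.SubunitProfile:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "position", "nmol"], path)
    amounts = {}
    for row in df.itertuples(index=False):
        key = (row.species, row.position)
        amounts[key] = amounts.get(key, 0.0) + float(row.nmol)
    return comp.SubunitProfile(amounts=amounts)


def write_subunit_profile(profile: comp.SubunitProfile, path) -> None:
    rows = [
        {"species": sp, "position": pos, "nmol": nmol}
        for (sp, pos), nmol in sorted(profile.amounts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gpc_trace(trace_path, cal_path) -> comp.GPCTrace:
    trace = pd.read_csv(trace_path)
    _require_columns(trace, ["elution_mL", "signal"], trace_path)
    cal = pd.read_csv(cal_path)
    _require_columns(cal, ["elution_mL", "log10_mw"], cal_path)
    return comp.GPCTrace(
        elution_mL=trace["elution_mL"].to_numpy(),
        signal=trace["signal"].to_numpy(),
        cal_elution_mL=cal["elution_mL"].to_numpy(),
        cal_log10_mw=cal["log10_mw"].to_numpy(),
    )


def write_gpc_trace(trace: comp.GPCTrace, trace_path, cal_path) -> None:
    pd.DataFrame({"elution_mL": trace.elution_mL, "signal": trace.signal}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        {"elution_mL": trace.cal_elution_mL, "log10_mw": trace.cal_log10_mw}
    ).to_csv(cal_path, index=False)


# ---------------------------------------------------------------------------
# Coefficient (de)serialization

_COEFF_KEYS = ("num_const", "num_T", "num_E", "den_const", "den_T", "den_E", "den_TE")


def coefficients_from_dict(d: dict, label: str = "") -> RationalSurfaceCoefficients:
    """Build surface coefficients from the seven named config entries."""
    unknown = set(d) - set(_COEFF_KEYS)
    if unknown:
        raise ConfigError(f"unknown coefficient keys {sorted(unknown)}; expected {_COEFF_KEYS}")
    missing = set(_COEFF_KEYS) - set(d)
    if missing:
        raise ConfigError(f"missing coefficient keys {sorted(missing)}")
    return RationalSurfaceCoefficients(
        numerator=(float(d["num_const"]), float(d["num_T"]), float(d["num_E"])),
        denominator=(
            float(d["den_const"]),
            float(d["den_T"]),
            float(d["den_E"]),
            float(d["den_TE"]),
        ),
        label=label,
    )


def coefficients_to_dict(coeffs: RationalSurfaceCoefficients) -> dict:
    n0, nT, nE = coeffs.numerator
    d0, dT, dE, dTE = coeffs.denominator
    return {
        "num_const": n0, "num_T": nT, "num_E": nE,
        "den_const": d0, "den_T": dT, "den_E": dE, "den_TE": dTE,
    }


# ---------------------------------------------------------------------------
# Configuration

_DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "model": {
        "coefficients": {
            "keq": coefficients_to_dict(DEFAULT_KEQ_COEFFS),
            "scwm": coefficients_to_dict(DEFAULT_SCWM_COEFFS),
        }
    },
    "system": {"volume_L": 0.0045, "cwm_mass_mg": 10.0, "total_pa_mg": 6.75},
    "ramp": {
        "ethanol_pct": 15.0,
        "temperatures_C": [15.0, 22.5, 30.0, 35.0],
        "mode": "equilibrium",
        "fractions": None,
        "phi": None,
        "withdrawal_uL": 0.0,
    },
    "assay": {
        "slope": 0.001,
        "intercept": 0.0,
        "dilution_factor": 1000.0 / 75.0,
        "background_scale": 0.875,
    },
    "noise": {"cv": 0.03, "replicates": 3, "placement": "concentration"},
    "synth": {"ethanol_levels": [0.0, 7.5, 12.0, 15.0], "a_background": 0.05},
    "scenario": {
        "berries_per_L": 750.0,
        "cwm_mg_per_berry": 10.0,
        "pa_mg_per_L": 1500.0,
        "volume_L": 1.0,
        "coldsoak_temperature_C": 15.0,
        "coldsoak_ethanol_pct": 0.0,
        "final_temperature_C": 35.0,
        "final_ethanol_pct": 15.0,
        "final_desorption_fraction": 0.4796,
    },
    "paths": {
        "measurements": None,
        "calibration": None,
        "isotherm_points": None,
        "subunits": None,
        "gpc": None,
        "gpc_cal": None,
    },
}


def _merge(defaults: dict, user: dict, context: str = "") -> dict:
    out = {}
    unknown = set(user) - set(defaults)
    if unknown:
        where = context or "top level"
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at {where}")
    for key, default in defaults.items():
        if key not in user or user[key] is None:
            out[key] = default
        elif isinstance(default, dict) and default:
            if not isinstance(user[key], dict):
                raise ConfigError(f"config key {context}{key} must be a mapping")
            out[key] = _merge(default, user[key], f"{context}{key}.")
        else:
            out[key] = user[key]
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with all defaults applied."""

    raw: dict = field(repr=False)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def keq_coeffs(self) -> RationalSurfaceCoefficients:
        return coefficients_from_dict(self.raw["model"]["coefficients"]["keq"], "Keq")

    @property
    def scwm_coeffs(self) -> RationalSurfaceCoefficients:
        return coefficients_from_dict(self.raw["model"]["coefficients"]["scwm"], "Scwm")

    @property
    def system(self) -> BatchSystem:
        s = self.raw["system"]
        return BatchSystem(s["volume_L"], s["cwm_mass_mg"], s["total_pa_mg"])

    def schedule(self, ethanol_pct: float | None = None) -> RampSchedule:
        r = self.raw["ramp"]
        return RampSchedule(
            ethanol_pct=r["ethanol_pct"] if ethanol_pct is None else ethanol_pct,
            temperatures_C=tuple(r["temperatures_C"]),
        )

    @property
    def calibration(self) -> AssayCalibration:
        a = self.raw["assay"]
        return AssayCalibration(
            slope=a["slope"],
            intercept=a["intercept"],
            dilution_factor=a["dilution_factor"],
            background_scale=a["background_scale"],
        )

    def noise(self, seed: int | None = None) -> NoiseModel:
        n = self.raw["noise"]
        return NoiseModel(
            cv=n["cv"],
            seed=self.seed if seed is None else seed,
            replicates=int(n["replicates"]),
            placement=n["placement"],
        )

    @property
    def scenario_spec(self) -> ScenarioSpec:
        s = self.raw["scenario"]
        return ScenarioSpec(
            berries_per_L=s["berries_per_L"],
            cwm_mg_per_berry=s["cwm_mg_per_berry"],
            pa_mg_per_L=s["pa_mg_per_L"],
            volume_L=s["volume_L"],
            coldsoak_condition=Condition.from_celsius(
                s["coldsoak_temperature_C"], s["coldsoak_ethanol_pct"]
            ),
            final_condition=Condition.from_celsius(
                s["final_temperature_C"], s["final_ethanol_pct"]
            ),
            final_desorption_fraction=s["final_desorption_fraction"],
        )

    def path(self, key: str) -> Path | None:
        p = self.raw["paths"][key]
        return Path(p) if p else None


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults.

    Unknown keys are rejected with an error naming the key; every referenced
    file must exist at load time.
    """
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"config file not found: {p}")
        with open(p, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{p}: config must be a mapping, got {type(loaded).__name__}")
        user = loaded
    if overrides:
        user = _merge(_merge(_DEFAULTS, user), overrides)
    merged = _merge(_DEFAULTS, user)
    for key, value in merged["paths"].items():
        if value is not None and not Path(value).is_file():
            raise ConfigError(f"paths.{key}: file not found: {value}")
    return RunConfig(raw=merged)


# ---------------------------------------------------------------------------
# Quantification chain


def quantify_measurements(
    df: pd.DataFrame,
    cal: AssayCalibration,
    volume_L: float,
    cwm_mass_mg: float,
) -> pd.DataFrame:
    """Convert a measurement table to per-replicate adsorption and desorption.

    For each (condition, temperature step) the control mean concentration is
    subtracted from each trial replicate to give q (mg/mg); percent
    desorption is computed per replicate against that replicate's q at the
    first (lowest-temperature) step.

    Returns columns ``condition_id, ethanol_pct, temperature_C, replicate,
    conc_mg_per_L, q_mg_per_mg, percent_desorption``.
    """
    df = df.copy()
    if "conc_mg_per_L" not in df.columns:
        df["conc_mg_per_L"] = [
            concentration_from_absorbance(
                AbsorbanceReading(row.a_background, row.a_final), cal
            )
            for row in df.itertuples(index=False)
        ]
    out_rows = []
    for cid, sub in df.groupby("condition_id", sort=False):
        temps = sorted(sub["temperature_C"].unique())
        base_q: dict = {}
        for temp in temps:
            cell = sub[sub["temperature_C"] == temp]
            controls = cell[cell["role"] == "control"]["conc_mg_per_L"]
            trials = cell[cell["role"] == "trial"]
            if controls.empty or trials.empty:
                raise ValueError(f"condition {cid!r} at {temp} degC lacks control or trial rows")
            control_mean = float(controls.mean())
            for row in trials.itertuples(index=False):
                q = (control_mean - row.conc_mg_per_L) * volume_L / cwm_mass_mg
                if temp == temps[0]:
                    base_q[row.replicate] = q
                base = base_q.get(row.replicate)
                if base is None or base <= 0:
                    pct = np.nan if temp != temps[0] else 0.0
                else:
                    pct = 100.0 * (base - q) / base
                out_rows.append(
                    {
                        "condition_id": cid,
                        "ethanol_pct": row.ethanol_pct,
                        "temperature_C": temp,
                        "replicate": row.replicate,
                        "conc_mg_per_L": row.conc_mg_per_L,
                        "q_mg_per_mg": q,
                        "percent_desorption": pct,
                    }
                )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Pipeline commands


def _synth_truth(config: RunConfig, ethanol_pct: float):
    r = config.raw["ramp"]
    mode = r["mode"]
    fractions = r["fractions"]
    if mode == "empirical" and fractions is None:
        fractions = empirical_fractions(ethanol_pct)
    return simulate_ramp(
        config.system,
        config.schedule(ethanol_pct),
        config.keq_coeffs,
        config.scwm_coeffs,
        mode=mode,
        fractions=fractions,
        phi=r["phi"],
        withdrawal_uL=r["withdrawal_uL"],
    )


def _cmd_synth(config: RunConfig, out: Path) -> list[Path]:
    frames, truth = [], {}
    for i, eth in enumerate(config.raw["synth"]["ethanol_levels"]):
        result = _synth_truth(config, eth)
        noise = config.noise(seed=config.seed + i)
        frames.append(
            generate_measurements(
                result,
                config.calibration,
                noise,
                a_background=config.raw["synth"]["a_background"],
            )
        )
        truth[f"etoh{eth:g}"] = {
            "ethanol_pct": eth,
            "temperatures_C": list(result.schedule.temperatures_C),
            "percent_desorption": list(result.percent_desorption),
            "adsorbed_mg": list(result.adsorbed_series_mg),
            "mode": result.mode,
        }
    measurements = pd.concat(frames, ignore_index=True)
    write_measurements(measurements, out / "measurements.csv")
    cal = config.calibration
    conc = np.linspace(0.0, 150.0, 6)
    pd.DataFrame(
        {"conc_mg_per_L": conc, "absorbance": cal.slope * conc + cal.intercept}
    ).to_csv(out / "calibration.csv", index=False)
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return [out / "measurements.csv", out / "calibration.csv", out / "truth.json"]


def _measurements_for(config: RunConfig, out: Path) -> pd.DataFrame:
    path = config.path("measurements") or out / "measurements.csv"
    if not Path(path).is_file():
        raise ConfigError(f"no measurements file at {path}; run `synth` or set paths.measurements")
    return read_measurements(path)


def _cmd_quantify(config: RunConfig, out: Path) -> list[Path]:
    df = _measurements_for(config, out)
    s = config.raw["system"]
    quant = quantify_measurements(df, config.calibration, s["volume_L"], s["cwm_mass_mg"])
    quant.to_csv(out / "desorption.csv", index=False)
    return [out / "desorption.csv"]


def _cmd_stats(config: RunConfig, out: Path) -> list[Path]:
    path = out / "desorption.csv"
    if not path.is_file():
        _cmd_quantify(config, out)
    quant = pd.read_csv(path)
    later = quant[quant["temperature_C"] > quant["temperature_C"].min()].dropna(
        subset=["percent_desorption"]
    )
    summary = summarize_desorption(later)
    summary["letter_within_ethanol"] = ""
    summary["letter_within_temperature"] = ""
    for eth, sub in later.groupby("ethanol_pct"):
        groups = {
            t: g["percent_desorption"].to_numpy()
            for t, g in sub.groupby("temperature_C")
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            letters = anova_letters(groups)
            for t, letter in letters.items():
                sel = (summary["ethanol_pct"] == eth) & (summary["temperature_C"] == t)
                summary.loc[sel, "letter_within_ethanol"] = letter
    for temp, sub in later.groupby("temperature_C"):
        groups = {
            e: g["percent_desorption"].to_numpy() for e, g in sub.groupby("ethanol_pct")
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            letters = anova_letters(groups)
            for e, letter in letters.items():
                sel = (summary["ethanol_pct"] == e) & (summary["temperature_C"] == temp)
                summary.loc[sel, "letter_within_temperature"] = letter
    summary.to_csv(out / "stats.csv", index=False)
    return [out / "stats.csv"]


def _cmd_simulate_ramp(config: RunConfig, out: Path) -> list[Path]:
    result = _synth_truth(config, config.raw["ramp"]["ethanol_pct"])
    rows = [
        {
            "step": i + 1,
            "temperature_C": t,
            "ethanol_pct": result.schedule.ethanol_pct,
            "c_pa_mg_per_L": st.c_pa_mg_per_L,
            "q_pa_mg_per_mg": st.q_pa_mg_per_mg,
            "adsorbed_mg": st.adsorbed_mg,
            "percent_desorption": pct,
        }
        for i, (t, st, pct) in enumerate(
            zip(result.schedule.temperatures_C, result.states, result.percent_desorption)
        )
    ]
    pd.DataFrame(rows).to_csv(out / "ramp.csv", index=False)
    return [out / "ramp.csv"]


def _cmd_compare_model(config: RunConfig, out: Path) -> list[Path]:
    path = config.path("isotherm_points")
    if path is None:
        raise ConfigError("compare-model requires paths.isotherm_points")
    points = read_isotherm_points(path)
    report = model_error(points, config.keq_coeffs, config.scwm_coeffs)
    report.to_csv(out / "model_error.csv", index=False)
    return [out / "model_error.csv"]


def _cmd_scenario(config: RunConfig, out: Path) -> list[Path]:
    report = scenario_report(config.scenario_spec, config.keq_coeffs, config.scwm_coeffs)
    with open(out / "scenario.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    pd.DataFrame([report]).to_csv(out / "scenario.csv", index=False)
    return [out / "scenario.json", out / "scenario.csv"]


def _cmd_composition(config: RunConfig, out: Path) -> list[Path]:
    row: dict = {}
    sub_path = config.path("subunits")
    if sub_path is not None:
        profile = read_subunit_profile(sub_path)
        row.update(
            mdp=comp.mdp(profile),
            pct_galloylation=comp.percent_galloylation(profile),
            pct_gallo=comp.percent_gallo(profile),
            average_mw=comp.average_mw(profile),
        )
    gpc_path, cal_path = config.path("gpc"), config.path("gpc_cal")
    if gpc_path is not None and cal_path is not None:
        trace = read_gpc_trace(gpc_path, cal_path)
        row["mw_at_90pct_mass"] = comp.molar_mass_at_quantile(trace, 0.9)
    if not row:
        raise ConfigError(
            "composition requires paths.subunits and/or paths.gpc + paths.gpc_cal"
        )
    pd.DataFrame([row]).to_csv(out / "composition.csv", index=False)
    return [out / "composition.csv"]


_COMMANDS = {
    "synth": _cmd_synth,
    "quantify": _cmd_quantify,
    "stats": _cmd_stats,
    "simulate-ramp": _cmd_simulate_ramp,
    "compare-model": _cmd_compare_model,
    "scenario": _cmd_scenario,
    "composition": _cmd_composition,
}


def run_pipeline(config: RunConfig, command: str, out_dir="out") -> list[Path]:
    """Run one pipeline stage; returns the artifact paths it wrote.

    Stages are deterministic given the config seed.  A log of the run is
    appended to ``<out_dir>/run.log``.
    """
    if command not in _COMMANDS:
        raise ConfigError(f"unknown command {command!r}; expected one of {sorted(_COMMANDS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.raw["log_level"])
    try:
        logger.info("running %s (seed=%d)", command, config.seed)
        artifacts = _COMMANDS[command](config, out)
        logger.info("wrote %s", ", ".join(str(a) for a in artifacts))
        return artifacts
    except Exception:
        logger.exception("stage %s failed; outputs may be partial", command)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
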