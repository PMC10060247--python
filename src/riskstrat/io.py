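"""Reading and writing study inputs/outputs.

Cohort and outcome tables travel as delimited text (CSV, header row, UTF-8)
or Parquet, chosen by file extension.  Analysis settings live in a single
YAML or JSON config.  Rendered output tables carry provenance (config hash,
seed, package version) as ``#``-prefixed header lines so they re-parse with
``pandas.read_csv(..., comment="#")``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .simulate import OutcomeModel, SimulationScenario


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
        return
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(provenance or {}):
            fh.write(f"# {key}: {provenance[key]}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def scenario_to_dict(s: SimulationScenario) -> dict:
    return {
        "n": s.n,
        "bin_prevalences": list(s.bin_prevalences),
        "n_continuous": s.n_continuous,
        "treat_intercept": s.treat_intercept,
        "treat_coefs": dict(s.treat_coefs),
        "outcomes": [
            {
                "outcome_id": om.outcome_id,
                "log_rate": om.log_rate,
                "coefs": dict(om.coefs),
                "gamma0": om.gamma0,
                "gamma1": om.gamma1,
            }
            for om in s.outcomes
        ],
        "censor_rate": s.censor_rate,
        "admin_censor": s.admin_censor,
        "n_negative_controls": s.n_negative_controls,
        "nc_log_rate": s.nc_log_rate,
        "nc_intercept_sd": s.nc_intercept_sd,
        "nc_coef_scale": s.nc_coef_scale,
        "unmeasured_treat_coef": s.unmeasured_treat_coef,
        "nc_unmeasured_coef": s.nc_unmeasured_coef,
        "seed": s.seed,
    }


def scenario_from_dict(d: dict) -> SimulationScenario:
    try:
        outcomes = tuple(
            OutcomeModel(
                outcome_id=o["outcome_id"],
                log_rate=float(o["log_rate"]),
                coefs=tuple(o.get("coefs", {}).items()),
                gamma0=float(o.get("gamma0", 0.0)),
                gamma1=float(o.get("gamma1", 0.0)),
            )
            for o in d.get("outcomes", [])
        )
        return SimulationScenario(
            n=int(d["n"]),
            bin_prevalences=tuple(d.get("bin_prevalences", ())),
            n_continuous=int(d.get("n_continuous", 0)),
            treat_intercept=float(d.get("treat_intercept", 0.0)),
            treat_coefs=tuple(d.get("treat_coefs", {}).items()),
            outcomes=outcomes,
            censor_rate=float(d.get("censor_rate", 1.0 / 1825.0)),
            admin_censor=int(d.get("admin_censor", 1095)),
            n_negative_controls=int(d.get("n_negative_controls", 0)),
            nc_log_rate=float(d.get("nc_log_rate", -10.3)),
            nc_intercept_sd=float(d.get("nc_intercept_sd", 0.3)),
            nc_coef_scale=float(d.get("nc_coef_scale", 0.25)),
            unmeasured_treat_coef=float(d.get("unmeasured_treat_coef", 0.0)),
            nc_unmeasured_coef=float(d.get("nc_unmeasured_coef", 0.0)),
            seed=int(d.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError("bad_scenario", f"missing scenario field {exc}") from exc
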