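"""File I/O, configuration, and the end-to-end pipeline.

CSV schemas
-----------
Plate data (long format), one row per well and timepoint::

    drug,experiment_id,direction,inhibitor,compartment,time_min,conc_uM,sampled_volume_ml,well

Abundances::

    system,mean_pmol_per_mg,sd_pmol_per_mg,n,experiment_id

UV/MP observations::

    dyad_id,time_after_dose_h,uv_mg_per_l,mp_mg_per_l

Configuration is a single TOML file with per-section schemas and strict
unknown-key rejection. Every output directory receives exactly one
``manifest.json`` recording the command, config hash, input file hashes,
seeds and package version, so a rerun with identical inputs is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .pbpk import DoseRegimen, PbpkParameterSet
from .refscale import AbundanceMeasurement
from .transwell import (
    DonorSample,
    ReceiverSample,
    TranswellExperiment,
    efflux_ratio,
    pgp_mediated_er,
)

__all__ = [
    "load_plate_csv",
    "write_plate_csv",
    "load_abundances_csv",
    "load_observations_csv",
    "load_config",
    "params_from_config",
    "regimen_from_config",
    "write_example_config",
    "RunManifest",
    "write_manifest",
    "run_pipeline",
]

PLATE_COLUMNS = ["drug", "experiment_id", "direction", "inhibitor", "compartment",
                 "time_min", "conc_uM", "sampled_volume_ml", "well"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(PbpkParameterSet)}
_REGIMEN_KEYS = {f.name for f in dataclasses.fields(DoseRegimen)}


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def load_plate_csv(
    path: str | Path,
    *,
    insert_area_cm2: float = 1.12,
    apical_volume_ml: float = 0.5,
    basal_volume_ml: float = 1.0,
    average_wells: bool = True,
) -> list[TranswellExperiment]:
    """Parse a long-format plate CSV into typed experiments.

    Triplicate wells are averaged at the concentration level within each
    (drug, experiment, direction, inhibitor) group before any ER arithmetic.
    Hard validation errors name the offending CSV row (1-based, excluding
    the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    bad = df.index[df["conc_uM"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative concentration in row(s) {[i + 1 for i in bad]}")
    bad = df.index[~df["direction"].isin(["A2B", "B2A"])]
    if len(bad):
        raise ValueError(f"{path}: unknown direction token in row(s) {[i + 1 for i in bad]}")
    bad = df.index[~df["compartment"].isin(["donor", "receiver"])]
    if len(bad):
        raise ValueError(f"{path}: unknown compartment token in row(s) {[i + 1 for i in bad]}")

    experiments: list[TranswellExperiment] = []
    keys = ["drug", "experiment_id", "direction", "inhibitor"]
    for (drug, exp_id, direction, inhibitor), g in df.groupby(keys, sort=True):
        if average_wells:
            g = (g.groupby(["compartment", "time_min"], as_index=False)
                 .agg(conc_uM=("conc_uM", "mean"),
                      sampled_volume_ml=("sampled_volume_ml", "first")))
        donor_v = apical_volume_ml if direction == "A2B" else basal_volume_ml
        receiver_v = basal_volume_ml if direction == "A2B" else apical_volume_ml
        recv = g[g["compartment"] == "receiver"].sort_values("time_min")
        don = g[g["compartment"] == "donor"].sort_values("time_min")
        experiments.append(
            TranswellExperiment(
                drug_id=str(drug),
                direction=str(direction),  # type: ignore[arg-type]
                inhibitor=str(inhibitor),  # type: ignore[arg-type]
                insert_area_cm2=insert_area_cm2,
                donor_volume_ml=donor_v,
                receiver_volume_ml=receiver_v,
                receiver_samples=[
                    ReceiverSample(float(r.time_min), float(r.conc_uM),
                                   float(r.sampled_volume_ml))
                    for r in recv.itertuples()
                ],
                donor_samples=[
                    DonorSample(float(r.time_min), float(r.conc_uM),
                                float(r.sampled_volume_ml))
                    for r in don.itertuples()
                ],
                replicate_id=str(exp_id),
            )
        )
    return experiments


def write_plate_csv(
    experiments: list[TranswellExperiment], path: str | Path, *, well: str = "w1"
) -> Path:
    """Write experiments back to the long-format plate schema (round-trips
    with :func:`load_plate_csv`)."""
    rows = []
    for exp in experiments:
        for s in exp.donor_samples:
            rows.append([exp.drug_id, exp.replicate_id, exp.direction, exp.inhibitor,
                         "donor", s.time_min, s.conc_uM, s.sampled_volume_ml, well])
        for s in exp.receiver_samples:
            rows.append([exp.drug_id, exp.replicate_id, exp.direction, exp.inhibitor,
                         "receiver", s.time_min, s.conc_uM, s.sampled_volume_ml, well])
    path = Path(path)
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)
    return path


def load_abundances_csv(path: str | Path) -> list[AbundanceMeasurement]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["system", "mean_pmol_per_mg"], path)
    out = []
    for r in df.itertuples():
        out.append(AbundanceMeasurement(
            system=str(r.system),  # type: ignore[arg-type]
            mean=float(r.mean_pmol_per_mg),
            sd=float(getattr(r, "sd_pmol_per_mg", 0.0) or 0.0),
            n=int(getattr(r, "n", 1) or 1),
            experiment_id=str(getattr(r, "experiment_id", "") or "") or None,
        ))
    return out


def load_observations_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["dyad_id", "time_after_dose_h"], path)
    if "uvmp_ratio" not in df.columns:
        _require_columns(df, ["uv_mg_per_l", "mp_mg_per_l"], path)
    return df


# ---------------------------------------------------------------------------
# configuration

_KNOWN_SECTIONS = {"pbpk", "regimen", "er", "kpuu", "fit", "scale_ga", "meta"}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a TOML config; unknown top-level sections or unknown keys in the
    pbpk/regimen sections are rejected outright."""
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown config section(s) {sorted(unknown)}")
    if "pbpk" in cfg:
        bad = set(cfg["pbpk"]) - _PARAM_KEYS
        if bad:
            raise ValueError(f"{path}: unknown [pbpk] key(s) {sorted(bad)}")
    if "regimen" in cfg:
        bad = set(cfg["regimen"]) - _REGIMEN_KEYS
        if bad:
            raise ValueError(f"{path}: unknown [regimen] key(s) {sorted(bad)}")
    return cfg


def params_from_config(cfg: dict[str, Any]) -> PbpkParameterSet:
    if "pbpk" not in cfg:
        raise ValueError("config has no [pbpk] section")
    return PbpkParameterSet(**cfg["pbpk"])


def regimen_from_config(cfg: dict[str, Any]) -> DoseRegimen:
    if "regimen" not in cfg:
        raise ValueError("config has no [regimen] section")
    return DoseRegimen(**cfg["regimen"])


def write_example_config(path: str | Path, drug: str = "DRV") -> Path:
    """Write an example TOML config (units in comments) for ``drug``."""
    from .examples import example_parameter_set, example_regimen

    p = example_parameter_set(drug)
    r = example_regimen(drug)
    units = {
        "ka": "1/h", "tlag": "h", "f_oral": "fraction", "v_maternal": "l",
        "cl_maternal": "l/h", "fu_m": "fraction", "fu_f": "fraction",
        "q_placenta_maternal": "l/h", "q_umbilical": "l/h",
        "cl_int_pd_placenta": "l/h", "v_placenta": "l", "v_fetal": "l",
        "cl_pm": "l/h", "induction_scalar": "fold", "fu_placenta": "fraction",
        "fetal_cl": "l/h", "gw": "weeks",
    }
    lines = [f"# Example {drug.upper()}-like maternal-fetal PBPK configuration", "", "[pbpk]"]
    for f in dataclasses.fields(PbpkParameterSet):
        v = getattr(p, f.name)
        lines.append(f"{f.name} = {v!r}  # {units.get(f.name, '')}".rstrip())
    lines += ["", "[regimen]",
              f"dose_mg = {r.dose_mg!r}",
              f"interval_h = {r.interval_h!r}",
              f"n_doses = {r.n_doses}",
              'route = "oral"']
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# manifest + pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    input_hashes: dict[str, str]
    seed: int | None
    package_version: str
    timestamp: str


def write_manifest(
    out_dir: str | Path,
    command: str,
    *,
    config: dict[str, Any] | None = None,
    inputs: dict[str, str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config_hash=hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_hashes={str(k): _sha256(Path(v)) for k, v in (inputs or {}).items()},
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path


def reduce_plate_to_er(
    experiments: list[TranswellExperiment], *, control_er: float | None = None
) -> pd.DataFrame:
    """Pair directional runs and compute per-(drug, experiment, inhibitor) ER."""
    index: dict[tuple, dict[str, TranswellExperiment]] = {}
    for exp in experiments:
        index.setdefault((exp.drug_id, exp.replicate_id, exp.inhibitor), {})[exp.direction] = exp
    rows = []
    for (drug, exp_id, inhibitor), pair in sorted(index.items()):
        if set(pair) != {"A2B", "B2A"}:
            raise ValueError(
                f"experiment {drug}/{exp_id}/{inhibitor} lacks one direction"
            )
        res = efflux_ratio(pair["A2B"], pair["B2A"], control_er=control_er)
        rows.append({
            "drug": drug, "experiment_id": exp_id, "inhibitor": inhibitor,
            "papp_a2b_cm_per_s": res.papp_a2b, "papp_b2a_cm_per_s": res.papp_b2a,
            "er": res.er, "qc_ly_pass": res.qc_ly_pass,
            "qc_control_pass": res.qc_control_pass,
            "n_timepoints_used": res.n_timepoints_used,
        })
    return pd.DataFrame(rows)


def er_table_to_pgp(er_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot (no-inhibitor, +P-gp-inhibitor) ER pairs to ER_P-gp per experiment."""
    rows = []
    for (drug, exp_id), g in er_df.groupby(["drug", "experiment_id"]):
        by_inh = g.set_index("inhibitor")["er"]
        if "none" not in by_inh.index or "pgp_inhibitor" not in by_inh.index:
            continue
        pr = pgp_mediated_er(float(by_inh["none"]), float(by_inh["pgp_inhibitor"]))
        rows.append({"drug": drug, "experiment_id": exp_id,
                     "er_minus": pr.er_without_inhibitor,
                     "er_plus": pr.er_with_inhibitor, "er_pgp": pr.er_pgp})
    return pd.DataFrame(rows)


def run_pipeline(
    config: dict[str, Any],
    out_dir: str | Path,
    *,
    seed: int | None = None,
    base_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Execute er -> kpuu (-> simulate/fit -> scale-ga) per the config.

    Each stage failure aborts with a stage-tagged message. Relative input
    paths resolve against ``base_dir`` (e.g. the config file's directory).
    Returns the JSON-serializable report that is also written to
    ``report.json`` alongside the stage CSVs and the run manifest.
    """
    from .gestational import project_kpuu_at_ga, scalers_from_table
    from .refscale import ErRefModel
    from .fitting import UvMpEffluxModel
    from .pbpk import kpuu_from_simulation, simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(".")
    report: dict[str, Any] = {"seed": seed}
    inputs: dict[str, Path] = {}

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    try:
        er_cfg = config["er"]
        plate_path = _resolve(er_cfg["plate"])
        inputs["plate"] = plate_path
        experiments = load_plate_csv(
            plate_path,
            insert_area_cm2=float(er_cfg.get("insert_area_cm2", 1.12)),
        )
        er_df = reduce_plate_to_er(experiments, control_er=er_cfg.get("control_er"))
        er_df.to_csv(out / "er_results.csv", index=False)
        report["er"] = {"n_experiments": int(len(er_df))}
    except KeyError as e:
        raise RuntimeError(f"[stage er] missing config key: {e}") from e

    try:
        kp_cfg = config["kpuu"]
        pgp_df = er_table_to_pgp(er_df)
        if "abundances" in kp_cfg:
            ab_path = _resolve(kp_cfg["abundances"])
            inputs["abundances"] = ab_path
            vitro = [a for a in load_abundances_csv(ab_path) if a.system == "cell_line"]
            by_exp = {a.experiment_id: a.mean for a in vitro}
            pgp_df["in_vitro_abundance"] = [
                by_exp[e] for e in pgp_df["experiment_id"].astype(str)
            ]
        in_vivo = AbundanceMeasurement(
            system="placenta_term",
            mean=float(kp_cfg["in_vivo_mean"]),
            sd=float(kp_cfg.get("in_vivo_sd", 0.0)),
        )
        results = ErRefModel(pgp_df, in_vivo).fit(seed=seed)
        results.per_experiment.to_csv(out / "kpuu_predictions.csv", index=False)
        low, high = results.ci90
        report["kpuu"] = {
            "point": results.point_kpuu,
            "point_pooled": results.point_kpuu_pooled,
            "ci90_low": low, "ci90_high": high,
            "ft_pgp": results.ft_pgp,
        }
    except KeyError as e:
        raise RuntimeError(f"[stage kpuu] missing config key: {e}") from e

    if "pbpk" in config and "regimen" in config:
        params = params_from_config(config)
        regimen = regimen_from_config(config)
        sim = simulate(params, regimen, from_steady_state=True)
        pd.DataFrame({
            "time_h": sim.time_h,
            "maternal_mg_per_l": sim.maternal_mg_per_l,
            "placenta_mg_per_l": sim.placenta_mg_per_l,
            "uv_mg_per_l": sim.fetal_mg_per_l,
        }).to_csv(out / "simulation.csv", index=False)
        report["simulate"] = {
            "kpuu_sim": kpuu_from_simulation(sim),
            "auc_maternal_ss_mg_h_per_l": sim.auc_maternal_ss,
            "auc_fetal_ss_mg_h_per_l": sim.auc_fetal_ss,
        }

        if "fit" in config:
            try:
                obs_path = _resolve(config["fit"]["obs"])
                inputs["observations"] = obs_path
                obs = load_observations_csv(obs_path)
                bracket = tuple(config["fit"].get("bracket", (0.1, 1e5)))
                fit = UvMpEffluxModel(obs, params, regimen).fit(bracket)  # type: ignore[arg-type]
                report["fit"] = {
                    "cl_pm_lph": fit.cl_pm_hat,
                    "aafe_at_fit": fit.aafe_at_fit,
                    "aafe_passive_only": fit.aafe_passive_only,
                    "kpuu_invivo": fit.kpuu_invivo,
                    "convergence": fit.convergence,
                    "flags": list(fit.flags),
                }
            except KeyError as e:
                raise RuntimeError(f"[stage fit] missing config key: {e}") from e

        if "scale_ga" in config:
            try:
                ga = float(config["scale_ga"]["gw"])
                table = None
                if "ga_table" in config["scale_ga"]:
                    ga_path = _resolve(config["scale_ga"]["ga_table"])
                    inputs["ga_table"] = ga_path
                    table = pd.read_csv(ga_path)
                proj = project_kpuu_at_ga(params, regimen, scalers_from_table(ga, table))
                report["scale_ga"] = {
                    "gw": ga,
                    "kpuu": proj.kpuu,
                    "kpuu_term": proj.kpuu_term,
                    "auc_fetal_ratio_vs_term": proj.auc_fetal_ratio_vs_term,
                    "auc_maternal_ratio_vs_term": proj.auc_maternal_ratio_vs_term,
                }
            except KeyError as e:
                raise RuntimeError(f"[stage scale-ga] missing config key: {e}") from e

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default) + "\n")
    write_manifest(out, "run", config=config, inputs=inputs, seed=seed)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
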