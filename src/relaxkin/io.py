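"""Plain-text readers and writers for traces, curves, profiles and reports.

Trace files are comma-delimited with `# key=value` header comments:

    # ligand_uM=20.0
    # temp_K=288.15
    # dead_time_s=0.001
    time_s,signal
    0.001,0.9932
    ...

A `manifest.json` indexes the trace files of a batch together with the
provenance (model parameters, design, noise seed) that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from relaxkin.equilibrium_assays import DenaturationCurve, TitrationCurve
from relaxkin.global_fit import ArrheniusLaw, GlobalKineticModel, ThermoSummary
from relaxkin.kinetics_core import Trace
from relaxkin.trace_fitting import PROFILE_COLUMNS

__all__ = [
    "write_trace",
    "read_trace",
    "write_manifest",
    "read_manifest_traces",
    "write_profile",
    "read_profile",
    "model_to_dict",
    "model_from_dict",
    "write_report",
    "read_denaturation_curve",
    "write_denaturation_curve",
    "read_titration_curve",
    "write_titration_curve",
]


def _read_header(path: Path) -> tuple[dict[str, float], int]:
    meta: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = float(val)
    return meta, n_header


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ligand_uM={float(trace.ligand_conc)!r}\n")
        fh.write(f"# temp_K={float(trace.temperature)!r}\n")
        fh.write(f"# dead_time_s={float(trace.dead_time)!r}\n")
        fh.write("time_s,signal\n")
        for t, s in zip(trace.time, trace.signal):
            fh.write(f"{float(t)!r},{float(s)!r}\n")
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta, n_header = _read_header(path)
    for key in ("ligand_uM", "temp_K", "dead_time_s"):
        if key not in meta:
            raise ValueError(f"{path}: missing header line '# {key}='")
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    return Trace(
        time=df["time_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        ligand_conc=meta["ligand_uM"],
        temperature=meta["temp_K"],
        dead_time=meta["dead_time_s"],
    )


def write_manifest(
    directory: str | Path,
    traces: list[Trace],
    provenance: dict[str, Any] | None = None,
) -> Path:
    """Write each trace plus a manifest.json indexing them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trace in enumerate(traces):
        name = f"trace_{i:04d}.csv"
        write_trace(trace, directory / name)
        entries.append(
            {
                "file": name,
                "ligand_uM": trace.ligand_conc,
                "temp_K": trace.temperature,
                "dead_time_s": trace.dead_time,
                "n_points": len(trace),
            }
        )
    manifest = {"traces": entries, "provenance": provenance or {}}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest_traces(manifest_path: str | Path) -> list[Trace]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    return [read_trace(base / entry["file"]) for entry in manifest["traces"]]


def write_profile(profile: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile.to_csv(path, index=False)
    return path


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile file missing columns {sorted(missing)}")
    return df


def model_to_dict(model: GlobalKineticModel) -> dict[str, Any]:
    return {
        "kind": model.kind,
        "T0": model.T0,
        "laws": {
            name: {"k0": law.k0, "E": law.E} for name, law in model.laws.items()
        },
        "rss": model.rss,
        "dof": model.dof,
        "stderr": {k: list(v) for k, v in model.stderr.items()},
        "converged": model.converged,
    }


def model_from_dict(d: dict[str, Any]) -> GlobalKineticModel:
    laws = {
        name: ArrheniusLaw(k0=entry["k0"], E=entry["E"], T0=d["T0"])
        for name, entry in d["laws"].items()
    }
    return GlobalKineticModel(
        kind=d["kind"],
        laws=laws,
        rss=d.get("rss"),
        dof=d.get("dof"),
        stderr={k: tuple(v) for k, v in d.get("stderr", {}).items()},
        converged=d.get("converged", True),
    )


def write_report(
    model: GlobalKineticModel, thermo: ThermoSummary, path: str | Path
) -> Path:
    """Serialize fitted laws + derived thermodynamics as JSON (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": model_to_dict(model),
        "thermo": {
            "Kd_uM": thermo.Kd,
            "dG_kcal_mol": thermo.dG,
            "dH_kcal_mol": thermo.dH,
            "dS_cal_mol_K": thermo.dS,
            "T_K": thermo.T,
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def _read_two_column(path: Path, xcol: str) -> tuple[np.ndarray, np.ndarray, dict]:
    meta, n_header = _read_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    if xcol not in df.columns or "signal" not in df.columns:
        raise ValueError(f"{path}: expected columns '{xcol},signal'")
    return df[xcol].to_numpy(float), df["signal"].to_numpy(float), meta


def read_denaturation_curve(path: str | Path) -> DenaturationCurve:
    d, s, meta = _read_two_column(Path(path), "den_M")
    return DenaturationCurve(denaturant=d, signal=s, temperature=meta.get("temp_K", 293.15))


def write_denaturation_curve(curve: DenaturationCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# temp_K={float(curve.temperature)!r}\n")
        fh.write("den_M,signal\n")
        for d, s in zip(curve.denaturant, curve.signal):
            fh.write(f"{float(d)!r},{float(s)!r}\n")
    return path


def read_titration_curve(path: str | Path) -> TitrationCurve:
    c, s, _ = _read_two_column(Path(path), "na_mM")
    return TitrationCurve(concentration=c, signal=s)


def write_titration_curve(curve: TitrationCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("na_mM,signal\n")
        for c, s in zip(curve.concentration, curve.signal):
            fh.write(f"{float(c)!r},{float(s)!r}\n")
    return path
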