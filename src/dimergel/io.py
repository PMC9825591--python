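"""Delimited-table and config I/O shared by the library, the CLI and the drivers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import BindingDataset
from .fcs import CorrelationCurve, IntensityTrace
from .model_core import ModelParams
from .phase_diagram import Binodal

__all__ = [
    "SchemaError",
    "read_params",
    "write_params",
    "read_trace",
    "write_trace",
    "read_correlation",
    "write_correlation",
    "read_binding",
    "write_binding",
    "write_binodal_tables",
]

#: Flat parameter-file keys for the thermodynamic model.
PARAM_KEYS = {
    "L_R": ("L_R", int),
    "L_E": ("L_E", int),
    "Kd_uM": ("K_d", float),
    "Kb_uM": ("K_b", float),
    "dR_nm": ("d_R", float),
    "Rg_nm": ("R_g", float),
}

FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A table is missing a required column or has malformed values."""


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def read_params(path) -> ModelParams:
    """Model parameters from a flat key-value (YAML-compatible) file.

    Recognised keys: L_R, L_E, Kd_uM, Kb_uM, dR_nm, Rg_nm; missing keys keep their
    defaults, unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("parameter file must be a flat key-value mapping")
    unknown = set(raw) - set(PARAM_KEYS)
    if unknown:
        raise SchemaError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {attr: cast(raw[key]) for key, (attr, cast) in PARAM_KEYS.items() if key in raw}
    return ModelParams(**kwargs)


def write_params(p: ModelParams, path) -> None:
    inv = {attr: key for key, (attr, _) in PARAM_KEYS.items()}
    data = {inv[a]: getattr(p, a) for a in inv}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_trace(path) -> IntensityTrace:
    """Intensity trace from a CSV with columns time_s, counts."""
    df = pd.read_csv(path)
    _require(df, ["time_s", "counts"], "trace table")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise SchemaError("trace table needs at least two rows")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise SchemaError("trace time stamps must be uniformly spaced")
    return IntensityTrace(bin_width=float(dt[0]), counts=df["counts"].to_numpy())


def write_trace(trace: IntensityTrace, path) -> None:
    t = np.arange(len(trace.counts)) * trace.bin_width
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_correlation(path) -> CorrelationCurve:
    """Correlation curve from a CSV with columns lag_s, G[, sem]."""
    df = pd.read_csv(path)
    _require(df, ["lag_s", "G"], "correlation table")
    sem = df["sem"].to_numpy(float) if "sem" in df.columns else None
    return CorrelationCurve(df["lag_s"].to_numpy(float), df["G"].to_numpy(float), sem)


def write_correlation(curve: CorrelationCurve, path) -> None:
    data = {"lag_s": curve.lags, "G": curve.G}
    if curve.sem is not None:
        data["sem"] = curve.sem
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_binding(path) -> BindingDataset:
    """Binding titration from a CSV with columns rubisco_nM, epyc1_nM, D_um2_s[, sd]."""
    df = pd.read_csv(path)
    _require(df, ["rubisco_nM", "epyc1_nM", "D_um2_s"], "binding table")
    return BindingDataset(
        rubisco_nM=df["rubisco_nM"].to_numpy(float),
        epyc1_nM=df["epyc1_nM"].to_numpy(float),
        D_um2_s=df["D_um2_s"].to_numpy(float),
        sd=df["sd"].to_numpy(float) if "sd" in df.columns else None,
    )


def write_binding(data: BindingDataset, path) -> None:
    out = {
        "rubisco_nM": data.rubisco_nM,
        "epyc1_nM": data.epyc1_nM,
        "D_um2_s": data.D_um2_s,
    }
    if data.sd is not None:
        out["sd"] = data.sd
    pd.DataFrame(out).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_binodal_tables(binodal: Binodal, outdir) -> dict[str, Path]:
    """Write binodal.csv (branch polylines) and tielines.csv (endpoint pairs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for branch, pts in (
        ("dilute", binodal.dilute_branch),
        ("dense", binodal.dense_branch),
    ):
        for rho_R, rho_E in (pts if len(binodal) else []):
            rows.append({"branch": branch, "rho_R_uM": rho_R, "rho_E_uM": rho_E})
    binodal_path = outdir / "binodal.csv"
    pd.DataFrame(rows, columns=["branch", "rho_R_uM", "rho_E_uM"]).to_csv(
        binodal_path, index=False, float_format=FLOAT_FMT
    )
    tie_rows = [
        {
            "dilute_rho_R_uM": t.dilute.rho_R,
            "dilute_rho_E_uM": t.dilute.rho_E,
            "dense_rho_R_uM": t.dense.rho_R,
            "dense_rho_E_uM": t.dense.rho_E,
            "mu_R_kT": t.mu_R,
            "mu_E_kT": t.mu_E,
            "grand_potential_kT_uM": t.grand_potential,
        }
        for t in binodal.tie_lines
    ]
    tie_path = outdir / "tielines.csv"
    pd.DataFrame(
        tie_rows,
        columns=[
            "dilute_rho_R_uM",
            "dilute_rho_E_uM",
            "dense_rho_R_uM",
            "dense_rho_E_uM",
            "mu_R_kT",
            "mu_E_kT",
            "grand_potential_kT_uM",
        ],
    ).to_csv(tie_path, index=False, float_format=FLOAT_FMT)
    return {"binodal": binodal_path, "tielines": tie_path}
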