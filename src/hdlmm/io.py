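"""Delimited-text ingestion and serialization of data sets and fits.

Readers accept CSV/TSV with or without a header row (detected from the
first line) and never silently add an intercept column; writers emit
full-precision text so a write -> read round trip reproduces the arrays
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ClusteredData
from .simulate import SimDataset, SimSetting

__all__ = [
    "read_matrix",
    "read_vector",
    "read_clustered_data",
    "write_dataset",
    "read_dataset",
    "write_fit_outputs",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE double exactly


def _has_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline().strip()
    for tok in first.split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    return ","


def _read_table(path, numeric: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    header = 0 if _has_header(path, sep) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file (ragged rows?): {exc}")
    if numeric:
        try:
            df = df.astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric cell in numeric matrix: {exc}")
    return df


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Numeric matrix plus column names (None if the file had no header)."""
    df = _read_table(path, numeric=True)
    names = list(map(str, df.columns)) if df.columns.dtype == object else None
    return df.to_numpy(dtype=float), names


def read_vector(path, numeric: bool = True) -> np.ndarray:
    df = _read_table(path, numeric=numeric)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column, found {df.shape[1]}")
    return df.iloc[:, 0].to_numpy()


def _resolve_columns(spec, names: list[str] | None, p: int) -> list[int]:
    """Column spec entries may be 0-based integers or header names."""
    out = []
    for item in spec:
        if isinstance(item, (int, np.integer)):
            j = int(item)
            if not 0 <= j < p:
                raise ValueError(f"column index {j} out of range for p={p}")
        else:
            if names is None or item not in names:
                raise KeyError(f"unknown column name {item!r}")
            j = names.index(item)
        out.append(j)
    return out


def read_clustered_data(
    x_path,
    y_path,
    groups_path,
    z_path=None,
    z_columns=None,
    intercept_in_z: bool = False,
    nonpen=(),
) -> ClusteredData:
    """Assemble a validated ClusteredData from delimited files.

    Z is taken either from its own file (``z_path``) or as a subset of X
    columns (``z_columns``, indices or header names); with
    ``intercept_in_z`` a constant column is appended to Z only — X is
    never modified.
    """
    X, x_names = read_matrix(x_path)
    y = read_vector(y_path).astype(float)
    groups = read_vector(groups_path, numeric=False)
    if z_path is not None and z_columns is not None:
        raise ValueError("supply z_path or z_columns, not both")
    if z_path is not None:
        Z, _ = read_matrix(z_path)
    else:
        cols = _resolve_columns(z_columns or [], x_names, X.shape[1])
        parts = [X[:, cols]] if cols else []
        if intercept_in_z:
            parts.append(np.ones((X.shape[0], 1)))
        if not parts:
            raise ValueError("z_columns empty and no intercept requested")
        Z = np.hstack(parts)
    nonpen_idx = _resolve_columns(list(nonpen), x_names, X.shape[1])
    return ClusteredData(
        X=X, Z=Z, y=y, groups=groups, nonpen=frozenset(nonpen_idx)
    )


def _setting_to_json(setting: SimSetting) -> dict:
    d = asdict(setting)
    d["psi"] = np.asarray(setting.psi).tolist()
    d["beta_nonzero"] = list(setting.beta_nonzero)
    return d


def setting_from_json(d: dict) -> SimSetting:
    d = dict(d)
    d["psi"] = np.asarray(d["psi"], dtype=float)
    d["beta_nonzero"] = tuple(d["beta_nonzero"])
    return SimSetting(**d)


def write_dataset(sim: SimDataset, outdir) -> Path:
    """Serialize a simulated data set as delimited text plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = sim.data
    np.savetxt(outdir / "X.csv", d.X, delimiter=",", fmt=_FLOAT_FMT)
    np.savetxt(outdir / "Z.csv", d.Z, delimiter=",", fmt=_FLOAT_FMT)
    np.savetxt(outdir / "y.csv", d.y[:, None], delimiter=",", fmt=_FLOAT_FMT)
    np.savetxt(
        outdir / "groups.csv", d.group_labels[d.groups][:, None],
        delimiter=",", fmt="%s",
    )
    np.savetxt(
        outdir / "beta_true.csv", sim.beta_true[:, None],
        delimiter=",", fmt=_FLOAT_FMT,
    )
    sidecar = {
        "setting": _setting_to_json(sim.setting),
        "nonpen": sorted(int(j) for j in d.nonpen),
    }
    (outdir / "setting.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_dataset(indir) -> ClusteredData:
    """Read back a data set written by ``write_dataset``."""
    indir = Path(indir)
    sidecar = json.loads((indir / "setting.json").read_text())
    return read_clustered_data(
        x_path=indir / "X.csv",
        y_path=indir / "y.csv",
        groups_path=indir / "groups.csv",
        z_path=indir / "Z.csv",
        nonpen=sidecar["nonpen"],
    )


def write_fit_outputs(results, outdir, config: dict | None = None) -> Path:
    """Coefficient table, variance components and a JSON fit summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.coefficients().to_csv(outdir / "coefficients.csv", index=False)
    psi = np.atleast_2d(results.cov_re)
    np.savetxt(outdir / "psi_hat.csv", psi, delimiter=",", fmt=_FLOAT_FMT)
    summary = {
        "lam": results.lam,
        "penalty": results.model.penalty,
        "cov_structure": results.model.cov_structure,
        "sigma2": results.sigma2,
        "loglik": results.llf,
        "bic": None if not np.isfinite(results.bic) else results.bic,
        "df": results.df,
        "n_nonzero": int(np.count_nonzero(results.fe_params)),
        "converged": results.converged,
        "diverged_interpolating": results.diverged_interpolating,
        "n_iter": results.n_iter,
    }
    (outdir / "fit_summary.json").write_text(json.dumps(summary, indent=2))
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(config, indent=2, default=str))
    with open(outdir / "iterations.ndjson", "w") as fh:
        for rec in results.active_history:
            fh.write(json.dumps(rec) + "\n")
    return outdir
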