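"""Dataset CSV ingestion/writing and reproducible run reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Dataset

__all__ = ["read_dataset", "write_dataset", "run_report"]


def read_dataset(
    path: str | Path,
    outcome_col: str = "y",
    treatment_col: str = "a",
    treatment_coding: str = "pm1",
) -> Dataset:
    """Read a validated (X, A, Y) dataset from CSV.

    ``treatment_coding``: "pm1" expects A in {-1, +1}; "01" expects {0, 1}
    and maps 0 -> -1.  All remaining columns are covariates and must be
    numeric with no missing values (imputation is the caller's job).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (outcome_col, treatment_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    na = df.isna()
    if na.to_numpy().any():
        locs = [
            f"row {i}, column {c!r}"
            for i, c in zip(*np.nonzero(na.to_numpy()))
            for c in [df.columns[c]]
        ][:20]
        raise ValueError("missing values are not supported: " + "; ".join(locs))
    a_raw = df[treatment_col]
    levels = sorted(pd.unique(a_raw))
    if len(levels) > 2:
        raise ValueError(f"treatment column has {len(levels)} levels; expected 2")
    if treatment_coding == "01":
        if not set(levels) <= {0, 1}:
            raise ValueError(f"treatment coding '01' but levels are {levels}")
        A = np.where(a_raw.to_numpy() == 0, -1, 1)
    elif treatment_coding == "pm1":
        if not set(levels) <= {-1, 1}:
            raise ValueError(f"treatment coding 'pm1' but levels are {levels}")
        A = a_raw.to_numpy().astype(int)
    else:
        raise ValueError(f"unknown treatment_coding {treatment_coding!r}")
    xcols = [c for c in df.columns if c not in (outcome_col, treatment_col)]
    Xdf = df[xcols]
    bad = [c for c in xcols if not np.issubdtype(Xdf[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric covariate columns rejected: {bad}")
    return Dataset(
        X=Xdf.to_numpy(dtype=float),
        A=A,
        Y=df[outcome_col].to_numpy(dtype=float),
        column_names=xcols,
    )


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with header y,a,x1..xp at full float precision."""
    cols = {"y": data.Y, "a": data.A}
    for name, col in zip(data.column_names, data.X.T):
        cols[name] = col
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def run_report(
    fit_summary: dict | None,
    inference_table: pd.DataFrame | None,
    value_result: dict | None,
    path: str | Path,
) -> tuple[Path, Path]:
    """Write machine-readable (JSON) and human-readable (text) run reports.

    Regenerating the report from identical artifacts yields identical files
    (no timestamps); seeds and the config hash ride along in the fit summary.
    """
    path = Path(path)
    payload: dict = {}
    if fit_summary is not None:
        payload["fit"] = fit_summary
    if inference_table is not None:
        payload["inference"] = inference_table.to_dict(orient="records")
    if value_result is not None:
        payload["value"] = value_result
    json_path = path.with_suffix(".json")
    txt_path = path.with_suffix(".txt")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))

    lines = ["pearlitr run report", "=" * 40]
    if fit_summary is not None:
        lines.append("\n[estimation]")
        for key in ("config_hash", "seed", "K", "n", "p"):
            if key in fit_summary:
                lines.append(f"  {key}: {fit_summary[key]}")
        if "lambdas" in fit_summary:
            lines.append(f"  per-fold lambda: {fit_summary['lambdas']}")
        beta = fit_summary.get("beta")
        if beta is not None:
            nz = [(i + 1, round(float(b), 4)) for i, b in enumerate(beta) if b != 0]
            lines.append(f"  nonzero pooled coefficients (1-based): {nz[:25]}")
    if inference_table is not None:
        lines.append("\n[inference]")
        lines.append(inference_table.to_string(index=False))
    if value_result is not None:
        lines.append("\n[value]")
        for key, val in sorted(value_result.items()):
            lines.append(f"  {key}: {val}")
    txt_path.write_text("\n".join(lines) + "\n")
    return json_path, txt_path
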