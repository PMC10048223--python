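"""Long-format CSV ingestion and output.

One row per subject-visit.  A :class:`DataSchema` names the column roles; any
cell equal to the missing sentinel (or empty) is treated as unobserved.  The
declared covariate order puts the missing-prone covariates first, matching the
sequential factorization of their joint model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import LongitudinalData, ZERO_TOL

__all__ = ["DataSchema", "read_long_csv", "write_long_csv"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DataSchema:
    """Column roles for a long-format file.

    ``covariates`` lists the fixed-effect columns with the ``n_missing``
    missing-prone ones first (their order fixes the sequential covariate
    model).  ``random_effect_covariates`` empty means a random intercept.
    """

    id_col: str = "id"
    time_col: str = "t"
    response_col: str = "y"
    covariates: tuple = ("x1", "x2", "x3")
    n_missing: int = 2
    random_effect_covariates: tuple = ()
    sentinel: str = "NA"

    def __post_init__(self) -> None:
        if self.n_missing > len(self.covariates):
            raise ValueError("n_missing exceeds the number of covariates")


def _to_float(series: pd.Series, sentinel: str, colname: str):
    raw = series.astype(str).str.strip()
    missing = raw.isin([sentinel, "", "nan", "NaN", "NA"]) | series.isna()
    vals = pd.to_numeric(raw.where(~missing), errors="coerce")
    bad = vals.isna() & ~missing
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"non-numeric cells in column {colname!r} at file rows {rows}")
    return vals.to_numpy(dtype=float), missing.to_numpy(dtype=bool)


def read_long_csv(path, schema: DataSchema) -> LongitudinalData:
    """Read a long-format CSV into a :class:`LongitudinalData` container.

    Rows are grouped by subject (file order preserved) and ordered by time
    within subject.  Missing-prone covariate cells and response cells may be
    missing; everything else must be complete.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    needed = [schema.id_col, schema.time_col, schema.response_col, *schema.covariates,
              *schema.random_effect_covariates]
    unknown = [c for c in needed if c not in df.columns]
    if unknown:
        raise ValueError(f"columns {unknown} not found in {path} (has {list(df.columns)})")

    ids = df[schema.id_col].astype(str).to_numpy()
    codes, uniques = pd.factorize(ids)
    time, tmiss = _to_float(df[schema.time_col], schema.sentinel, schema.time_col)
    if tmiss.any():
        raise ValueError("time column may not contain missing values")
    order = np.lexsort((time, codes))
    codes, time = codes[order], time[order]

    y, y_missing = _to_float(df[schema.response_col].iloc[order],
                             schema.sentinel, schema.response_col)
    if np.any(y[~y_missing] < -ZERO_TOL):
        rows = (np.flatnonzero((y < -ZERO_TOL) & ~y_missing) + 1).tolist()
        raise ValueError(f"negative responses at data rows {rows}")
    y = np.where(y_missing, np.nan, y)

    q = len(schema.covariates)
    X = np.zeros((len(df), q))
    x_missing = np.zeros((len(df), schema.n_missing), dtype=bool)
    for j, col in enumerate(schema.covariates):
        vals, miss_j = _to_float(df[col].iloc[order], schema.sentinel, col)
        if j >= schema.n_missing and miss_j.any():
            raise ValueError(f"column {col!r} is declared fully observed but has missing cells")
        X[:, j] = vals
        if j < schema.n_missing:
            x_missing[:, j] = miss_j

    if schema.random_effect_covariates:
        Z = np.column_stack([
            _to_float(df[c].iloc[order], schema.sentinel, c)[0]
            for c in schema.random_effect_covariates])
    else:
        Z = np.ones((len(df), 1))

    visit = np.zeros(len(df), dtype=int)
    for c in np.unique(codes):
        sel = codes == c
        visit[sel] = np.arange(sel.sum())

    data = LongitudinalData(
        subject=codes, visit=visit, t=time, y=np.nan_to_num(y, nan=0.0),
        X=np.nan_to_num(X, nan=0.0), Z=Z,
        y_missing=y_missing, x_missing=x_missing,
        n_missing_covariates=schema.n_missing,
        covariate_names=list(schema.covariates),
        subject_ids=np.asarray(uniques),
    )
    log.info(
        "read %d rows, %d subjects from %s; missing rates: y %.1f%%, %s",
        data.N, data.n_subjects, path, 100.0 * y_missing.mean(),
        ", ".join(f"{c} {100.0 * x_missing[:, j].mean():.1f}%%"
                  for j, c in enumerate(schema.covariates[: schema.n_missing])),
    )
    return data


def write_long_csv(data: LongitudinalData, path, schema: DataSchema | None = None,
                   masks: bool = True) -> None:
    """Write a container back to CSV, masking unobserved cells with the
    sentinel; optionally append indicator columns for the masks."""
    schema = schema or DataSchema(
        covariates=tuple(data.covariate_names or [f"x{j + 1}" for j in range(data.q)]),
        n_missing=data.m)
    ids = (data.subject_ids[data.subject]
           if data.subject_ids is not None else data.subject)
    out = pd.DataFrame({schema.id_col: ids, schema.time_col: data.t})
    yv = data.y.astype(object)
    yv[data.y_missing] = schema.sentinel
    out[schema.response_col] = yv
    for j, c in enumerate(schema.covariates):
        col = data.X[:, j].astype(object)
        if j < data.m:
            col[data.x_missing[:, j]] = schema.sentinel
        out[c] = col
    if masks:
        out["r_y"] = data.y_missing.astype(int)
        for j in range(data.m):
            out[f"r_{schema.covariates[j]}"] = data.x_missing[:, j].astype(int)
    out.to_csv(path, index=False)
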