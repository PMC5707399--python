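"""Serialization of series, feedback matrices and run metadata.

Time series travel as CSV (time index column, one column per series) and,
for gridded/NetCDF-style exchange, as xarray Datasets written through the
scipy NetCDF3 backend. Feedback matrices are CSV with a sidecar p-value CSV
and a JSON metadata file (lag, retained pair count, seed, season).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .core import FeedbackMatrix


def write_series_csv(path, series: np.ndarray, names=None) -> None:
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if arr.shape[0] == 1 and np.asarray(series).ndim == 1:
        arr = arr.T
    names = names or [f"series{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=names).rename_axis("time").to_csv(path)


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="time")


def write_series_netcdf(path, series: np.ndarray, names=None, attrs=None) -> None:
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if arr.shape[0] == 1 and np.asarray(series).ndim == 1:
        arr = arr.T
    names = names or [f"series{i}" for i in range(arr.shape[1])]
    ds = xr.Dataset(
        {n: ("time", arr[:, j]) for j, n in enumerate(names)},
        coords={"time": np.arange(arr.shape[0])},
        attrs=attrs or {},
    )
    ds.to_netcdf(path, engine="scipy")


def read_series_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def write_feedback(fb: FeedbackMatrix, outdir, stem: str = "feedback", extra_meta=None) -> None:
    """FeedbackMatrix -> <stem>.csv, <stem>_pvalues.csv, <stem>_meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bdf = pd.DataFrame(fb.B, index=fb.response_names, columns=fb.forcing_names)
    bdf.rename_axis("response").to_csv(outdir / f"{stem}.csv")
    if fb.p_values is not None:
        pdf = pd.DataFrame(fb.p_values, index=fb.response_names, columns=fb.forcing_names)
        pdf.rename_axis("response").to_csv(outdir / f"{stem}_pvalues.csv")
    meta = {"tau": fb.tau, "L_effective": fb.L_effective}
    meta.update(extra_meta or {})
    (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_feedback(outdir, stem: str = "feedback") -> FeedbackMatrix:
    outdir = Path(outdir)
    bdf = pd.read_csv(outdir / f"{stem}.csv", index_col="response")
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    p = None
    ppath = outdir / f"{stem}_pvalues.csv"
    if ppath.exists():
        p = pd.read_csv(ppath, index_col="response").to_numpy()
    return FeedbackMatrix(
        B=bdf.to_numpy(), tau=int(meta["tau"]), L_effective=int(meta["L_effective"]),
        forcing_names=list(bdf.columns), response_names=list(bdf.index), p_values=p,
    )
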