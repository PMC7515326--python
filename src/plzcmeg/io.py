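"""HDF5 / TSV persistence for cohorts and complexity maps.

Cohort HDF5 layout::

    /subjects/<id>/data       float32 [source, epoch, sample]  (attrs: group)
    /grid/positions           float   [source, 3]  (mm)
    /grid/region_id           int     [source]
    /grid/region_names        str     [n_regions]
    root attrs: fs, epoch_len_s, pad_s, spacing_mm, band

Covariates are a TSV with columns ``subject_id, group, age, hipp_left_mm3,
hipp_right_mm3, icv_mm3``.  Complexity maps are long-format TSV
(``subject_id, source_idx, band, plzc``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .grid import SourceGrid
from .pipeline import ComplexityMap
from .preprocessing import BandSpec, SourceEpochData, get_band
from .synthetic import Cohort

COVARIATE_COLUMNS = ["subject_id", "group", "age", "hipp_left_mm3",
                     "hipp_right_mm3", "icv_mm3"]


def _band_tag(band: Union[str, BandSpec]) -> str:
    return band if isinstance(band, str) else band.name


def write_cohort(cohort: Cohort, h5_path: str | Path,
                 covariates_path: str | Path | None = None) -> None:
    """Write epoch data + grid to HDF5 and (optionally) the covariate TSV."""
    first = cohort.data[cohort.subject_ids[0]]
    with h5py.File(h5_path, "w") as f:
        f.attrs["fs"] = float(first.fs)
        f.attrs["epoch_len_s"] = first.epoch_len_samples / first.fs
        f.attrs["pad_s"] = first.pad_samples / first.fs
        f.attrs["spacing_mm"] = cohort.grid.spacing
        f.attrs["band"] = _band_tag(first.band)
        g = f.create_group("grid")
        g.create_dataset("positions", data=cohort.grid.positions)
        g.create_dataset("region_id", data=cohort.grid.region_id)
        g.create_dataset("region_names",
                         data=np.array(cohort.grid.region_names, dtype="S"))
        subs = f.create_group("subjects")
        table = cohort.table.set_index("subject_id")
        for sid in cohort.subject_ids:
            d = cohort.data[sid]
            grp = subs.create_group(sid)
            ds = grp.create_dataset("data", data=d.values.astype(np.float32),
                                    compression="gzip", compression_opts=1)
            ds.attrs["group"] = str(table.loc[sid, "group"])
    if covariates_path is not None:
        write_covariates(cohort.table, covariates_path)


def read_cohort(h5_path: str | Path, covariates_path: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    table = read_covariates(covariates_path)
    with h5py.File(h5_path, "r") as f:
        fs = float(f.attrs["fs"])
        pad = int(round(float(f.attrs["pad_s"]) * fs))
        band_tag = str(f.attrs.get("band", "raw"))
        band: Union[str, BandSpec] = "raw" if band_tag == "raw" else get_band(band_tag)
        grid = SourceGrid(
            positions=np.asarray(f["grid/positions"], dtype=float),
            spacing=float(f.attrs["spacing_mm"]),
            region_id=np.asarray(f["grid/region_id"], dtype=np.int64),
            region_names=tuple(n.decode() for n in f["grid/region_names"][()]),
        )
        data = {}
        for sid in table["subject_id"]:
            values = np.asarray(f[f"subjects/{sid}/data"], dtype=np.float32)
            data[sid] = SourceEpochData(values=values, fs=fs, band=band,
                                        pad_samples=pad)
    return Cohort(grid=grid, table=table, data=data)


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, COVARIATE_COLUMNS].to_csv(path, sep="\t", index=False,
                                           float_format="%.10g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table is missing columns {missing}")
    return table


def write_complexity_map(cmap: ComplexityMap, path: str | Path) -> None:
    n_subj, n_src = cmap.values.shape
    df = pd.DataFrame({
        "subject_id": np.repeat(cmap.subject_ids, n_src),
        "source_idx": np.tile(np.arange(n_src), n_subj),
        "band": cmap.band.name,
        "plzc": cmap.values.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_complexity_map(path: str | Path, grid: SourceGrid) -> ComplexityMap:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    bands = df["band"].unique()
    if len(bands) != 1:
        raise ValueError(f"expected a single band per map file, found {bands}")
    ids = list(dict.fromkeys(df["subject_id"]))
    values = (df.pivot(index="subject_id", columns="source_idx", values="plzc")
                .loc[ids].to_numpy())
    if values.shape[1] != grid.n_sources:
        raise ValueError("map source count does not match the grid")
    return ComplexityMap(values=values, band=get_band(bands[0]),
                         subject_ids=tuple(ids), grid=grid)


def read_grid(h5_path: str | Path) -> SourceGrid:
    with h5py.File(h5_path, "r") as f:
        return SourceGrid(
            positions=np.asarray(f["grid/positions"], dtype=float),
            spacing=float(f.attrs["spacing_mm"]),
            region_id=np.asarray(f["grid/region_id"], dtype=np.int64),
            region_names=tuple(n.decode() for n in f["grid/region_names"][()]),
        )
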