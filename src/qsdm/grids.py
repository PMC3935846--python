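"""Gridded environmental layers and their plain-text serialization.

An :class:`EnvironmentalRaster` bundles the two hydrodynamic covariates the
biomass models are conditioned on — maximal tidal current velocity (m s⁻¹,
peak value over a full tidal cycle) and inundation time (% of the tidal
cycle a cell is submerged) — on a common grid with a shared nodata mask and
a uniform cell surface area.  Cells with inundation time strictly below
100% are intertidal; cells at exactly 100% are subtidal.

Layers are read and written as ESRI ASCII grids (``.asc``), the plain-text
raster interchange format: a six-line header (ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value) followed by whitespace-separated rows,
north row first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")

OBSERVATION_COLUMNS = ["sample_id", "velocity", "inundation", "biomass"]


@dataclass
class EnvironmentalRaster:
    """Velocity and inundation layers on a shared grid.

    Parameters
    ----------
    velocity : 2-D array, m s⁻¹, non-negative on valid cells.
    inundation : 2-D array, % of tidal cycle submerged, in [0, 100].
    cell_area : surface area S of one grid cell, m².
    mask : 2-D boolean array, True where the cell is valid (not nodata).
    """

    velocity: np.ndarray
    inundation: np.ndarray
    cell_area: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.inundation = np.asarray(self.inundation, dtype=float)
        if self.velocity.ndim != 2:
            raise ValueError("raster layers must be 2-D")
        if self.velocity.shape != self.inundation.shape:
            raise ValueError(
                f"velocity shape {self.velocity.shape} != inundation shape "
                f"{self.inundation.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.velocity) & np.isfinite(self.inundation)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.velocity.shape:
            raise ValueError("mask shape does not match layer shape")
        if not self.cell_area > 0:
            raise ValueError(f"cell_area must be positive, got {self.cell_area}")
        v = self.velocity[self.mask]
        i = self.inundation[self.mask]
        if v.size and (v < 0).any():
            raise ValueError("velocity must be non-negative on valid cells")
        if i.size and ((i < 0) | (i > 100)).any():
            raise ValueError("inundation must lie in [0, 100] on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.velocity.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def intertidal_mask(self) -> np.ndarray:
        """Valid cells submerged for strictly less than the full tidal cycle."""
        return self.mask & (self.inundation < 100.0)

    @property
    def subtidal_mask(self) -> np.ndarray:
        """Valid cells that are permanently submerged (inundation = 100%)."""
        return self.mask & (self.inundation >= 100.0)


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; nodata cells become NaN.

    Returns the data array (north row first) and the header as a dict.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, header


def write_esri_ascii(
    path: str | Path,
    data: np.ndarray,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata_value: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (NaN → nodata)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D")
    out = np.where(np.isfinite(data), data, nodata_value)
    nrows, ncols = data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata_value}\n")
        np.savetxt(fh, out, fmt="%.8g")


def write_raster(
    raster: EnvironmentalRaster,
    velocity_path: str | Path,
    inundation_path: str | Path,
) -> None:
    """Write both layers of a raster as ESRI ASCII grids.

    The cell size is derived from the cell area (square cells assumed).
    """
    cellsize = float(np.sqrt(raster.cell_area))
    vel = np.where(raster.mask, raster.velocity, np.nan)
    inu = np.where(raster.mask, raster.inundation, np.nan)
    write_esri_ascii(velocity_path, vel, cellsize=cellsize)
    write_esri_ascii(inundation_path, inu, cellsize=cellsize)


def read_raster(
    velocity_path: str | Path,
    inundation_path: str | Path,
    cell_area: float | None = None,
) -> EnvironmentalRaster:
    """Load velocity and inundation ESRI ASCII grids into a raster.

    If ``cell_area`` is not given it is taken as cellsize² from the header.
    """
    vel, vhead = read_esri_ascii(velocity_path)
    inu, ihead = read_esri_ascii(inundation_path)
    if vel.shape != inu.shape:
        raise ValueError("velocity and inundation grids have different shapes")
    if cell_area is None:
        cell_area = float(vhead.get("cellsize", 1.0)) ** 2
    mask = np.isfinite(vel) & np.isfinite(inu)
    vel = np.where(mask, vel, np.nan)
    inu = np.where(mask, inu, np.nan)
    return EnvironmentalRaster(vel, inu, cell_area=cell_area, mask=mask)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table against its invariants.

    One row per benthic sample: ``sample_id``, covariates ``velocity``
    (m s⁻¹, ≥0) and ``inundation`` (%, in [0, 100]), and response
    ``biomass`` (g AFDW m⁻², ≥0).  Missing values are rejected.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    df = df[OBSERVATION_COLUMNS]
    num = df[["velocity", "inundation", "biomass"]]
    if num.isna().any().any():
        raise ValueError("observation table contains missing values")
    if (num["velocity"] < 0).any():
        raise ValueError("velocity must be non-negative")
    if ((num["inundation"] < 0) | (num["inundation"] > 100)).any():
        raise ValueError("inundation must lie in [0, 100]")
    if (num["biomass"] < 0).any():
        raise ValueError("biomass must be non-negative")
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation CSV (``sample_id,velocity,inundation,biomass``)."""
    return validate_observations(pd.read_csv(path))


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    validate_observations(df).to_csv(path, index=False)
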