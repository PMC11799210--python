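"""Gridded summer sea-surface-temperature fields and operations on them.

A :class:`TemperatureField` is a regular lon-lat grid of summer mean SST for
one paleogeography/pCO2 scenario, with NaN marking land (missing) cells.
Operations cover point sampling with a nearest-unmasked coastal fallback,
bilinear downscaling to a finer grid, and field-to-field comparison
(rank correlation, RMSE, difference map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy import stats

PLAUSIBLE_SST = (-5.0, 60.0)


@dataclass
class TemperatureField:
    """Summer mean SST (°C) on a regular lon-lat grid, NaN over land.

    ``values`` has shape (len(lat_axis), len(lon_axis)); axes hold strictly
    monotone increasing cell-center coordinates in decimal degrees.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    values: np.ndarray
    geography_tag: str = "180Ma"
    scenario_tag: str = ""

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lat_axis.size, self.lon_axis.size):
            raise ValueError("values shape must be (n_lat, n_lon)")
        for ax in (self.lon_axis, self.lat_axis):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < PLAUSIBLE_SST[0] or finite.max() > PLAUSIBLE_SST[1]):
            raise ValueError(
                f"SST values outside plausibility window {PLAUSIBLE_SST} °C"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is missing (land)."""
        return ~np.isfinite(self.values)

    def copy(self) -> "TemperatureField":
        return TemperatureField(
            self.lon_axis.copy(),
            self.lat_axis.copy(),
            self.values.copy(),
            self.geography_tag,
            self.scenario_tag,
        )

    # ---- I/O -----------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"sst": (("lat", "lon"), self.values)},
            coords={"lon": self.lon_axis, "lat": self.lat_axis},
            attrs={"geography_tag": self.geography_tag, "scenario_tag": self.scenario_tag},
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_csv(self, path: str | Path) -> None:
        lon, lat = np.meshgrid(self.lon_axis, self.lat_axis)
        pd.DataFrame(
            {"lon": lon.ravel(), "lat": lat.ravel(), "sst": self.values.ravel()}
        ).to_csv(path, index=False)

    @classmethod
    def from_netcdf(
        cls,
        path: str | Path,
        var: str = "sst",
        lon_name: str = "lon",
        lat_name: str = "lat",
    ) -> "TemperatureField":
        with xr.open_dataset(path, engine="scipy") as ds:
            da = ds[var].transpose(lat_name, lon_name)
            fld = cls(
                ds[lon_name].values,
                ds[lat_name].values,
                da.values.astype(float),
                str(ds.attrs.get("geography_tag", "180Ma")),
                str(ds.attrs.get("scenario_tag", "")),
            )
        return fld

    @classmethod
    def from_csv(cls, path: str | Path, **tags: str) -> "TemperatureField":
        df = pd.read_csv(path)
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        grid = (
            df.pivot_table(index="lat", columns="lon", values="sst", dropna=False)
            .reindex(index=lats, columns=lons)
            .values
        )
        return cls(lons, lats, grid, **tags)


def _nearest_index(axis: np.ndarray, coord: float) -> int:
    return int(np.argmin(np.abs(axis - coord)))


def _great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def sample_temperature(
    fld: TemperatureField,
    lon: float,
    lat: float,
    max_search_cells: int = 2,
) -> float:
    """SST at (lon, lat): the containing grid cell, or — if that cell is
    land-masked — the nearest unmasked cell within ``max_search_cells`` of
    the containing cell (great-circle nearest; ties broken by smaller |dlat|
    then smaller |dlon|). Returns NaN when no unmasked cell is in reach.
    """
    i = _nearest_index(fld.lat_axis, lat)
    j = _nearest_index(fld.lon_axis, lon)
    v = fld.values[i, j]
    if np.isfinite(v):
        return float(v)
    r = max_search_cells
    i0, i1 = max(i - r, 0), min(i + r + 1, fld.lat_axis.size)
    j0, j1 = max(j - r, 0), min(j + r + 1, fld.lon_axis.size)
    sub = fld.values[i0:i1, j0:j1]
    ok = np.isfinite(sub)
    if not ok.any():
        return float("nan")
    ii, jj = np.nonzero(ok)
    cand_lat = fld.lat_axis[i0:i1][ii]
    cand_lon = fld.lon_axis[j0:j1][jj]
    d = _great_circle_km(lon, lat, cand_lon, cand_lat)
    # Deterministic tie-break: distance, then |dlat|, then |dlon|.
    order = np.lexsort((np.abs(cand_lon - lon), np.abs(cand_lat - lat), np.round(d, 9)))
    best = order[0]
    return float(sub[ii[best], jj[best]])


def sample_temperatures(
    fld: TemperatureField,
    lons: np.ndarray,
    lats: np.ndarray,
    max_search_cells: int = 2,
) -> np.ndarray:
    """Vectorised :func:`sample_temperature` over paired coordinate arrays."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    out = np.empty(lons.shape, dtype=float)
    # Fast path: direct cell hits resolved with one gather.
    ii = np.abs(lats[:, None] - fld.lat_axis[None, :]).argmin(axis=1)
    jj = np.abs(lons[:, None] - fld.lon_axis[None, :]).argmin(axis=1)
    out[:] = fld.values[ii, jj]
    miss = ~np.isfinite(out) & np.isfinite(lons) & np.isfinite(lats)
    for k in np.nonzero(miss)[0]:
        out[k] = sample_temperature(fld, lons[k], lats[k], max_search_cells)
    out[~np.isfinite(lons) | ~np.isfinite(lats)] = np.nan
    return out


def downscale_bilinear(
    coarse: TemperatureField,
    target_lon_axis: np.ndarray,
    target_lat_axis: np.ndarray,
) -> TemperatureField:
    """Bilinear interpolation of a coarse field onto finer cell-center axes.

    Each target cell uses its four surrounding coarse cell centers; masked
    corners are dropped and the remaining weights renormalised, so only
    targets with all four corners masked stay masked. Bilinear weights are
    nonnegative and sum to one, so the result never overshoots the coarse
    field's min/max.
    """
    tlon = np.asarray(target_lon_axis, dtype=float)
    tlat = np.asarray(target_lat_axis, dtype=float)
    if tlon.min() < coarse.lon_axis.min() or tlon.max() > coarse.lon_axis.max():
        raise ValueError("target longitudes outside the coarse field bounding box")
    if tlat.min() < coarse.lat_axis.min() or tlat.max() > coarse.lat_axis.max():
        raise ValueError("target latitudes outside the coarse field bounding box")

    jx = np.clip(np.searchsorted(coarse.lon_axis, tlon) - 1, 0, coarse.lon_axis.size - 2)
    iy = np.clip(np.searchsorted(coarse.lat_axis, tlat) - 1, 0, coarse.lat_axis.size - 2)
    fx = (tlon - coarse.lon_axis[jx]) / (coarse.lon_axis[jx + 1] - coarse.lon_axis[jx])
    fy = (tlat - coarse.lat_axis[iy]) / (coarse.lat_axis[iy + 1] - coarse.lat_axis[iy])

    FX, FY = np.meshgrid(fx, fy)
    JX, IY = np.meshgrid(jx, iy)
    corners = np.stack(
        [
            coarse.values[IY, JX],
            coarse.values[IY, JX + 1],
            coarse.values[IY + 1, JX],
            coarse.values[IY + 1, JX + 1],
        ]
    )
    weights = np.stack(
        [(1 - FX) * (1 - FY), FX * (1 - FY), (1 - FX) * FY, FX * FY]
    )
    valid = np.isfinite(corners)
    weights = np.where(valid, weights, 0.0)
    wsum = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            wsum > 0,
            np.nansum(np.where(valid, corners, 0.0) * weights, axis=0) / wsum,
            np.nan,
        )
    return TemperatureField(tlon, tlat, out, coarse.geography_tag, coarse.scenario_tag)


def compare_fields(
    a: TemperatureField, b: TemperatureField, mean_centered_rmse: bool = False
) -> tuple[float, float, np.ndarray]:
    """Compare two fields on identical axes.

    Returns (rho, rmse, difference_map): Spearman rank correlation and
    root-mean-square difference over jointly unmasked cells, and the a - b
    grid with the union mask. By default RMSE is the plain RMS of the
    differences; ``mean_centered_rmse=True`` removes the mean offset first
    (the residual-SD variant).
    """
    if a.values.shape != b.values.shape or not (
        np.allclose(a.lon_axis, b.lon_axis) and np.allclose(a.lat_axis, b.lat_axis)
    ):
        raise ValueError("fields must share axes; resample first")
    diff = a.values - b.values
    joint = np.isfinite(a.values) & np.isfinite(b.values)
    if joint.sum() < 3:
        raise ValueError("comparison undefined: fewer than 3 jointly unmasked cells")
    d = diff[joint]
    if mean_centered_rmse:
        d = d - d.mean()
    rmse = float(np.sqrt(np.mean(d**2)))
    av, bv = a.values[joint], b.values[joint]
    if np.allclose(av, av[0]) and np.allclose(bv, bv[0]):
        rho = 1.0 if np.allclose(av - bv, (av - bv)[0]) else float("nan")
    elif np.ptp(av) == 0 or np.ptp(bv) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(av, bv).statistic)
        # Identical rankings can lose exactness to floating noise; snap.
        if np.array_equal(np.argsort(av, kind="stable"), np.argsort(bv, kind="stable")) and np.isclose(rho, 1.0):
            rho = 1.0
    return rho, rmse, np.where(joint, diff, np.nan)


# Default pCO2 configuration per time bin: (main ppm, secondary ppm).
DEFAULT_SCENARIOS: dict[str, tuple[float, float]] = {
    "Bifrons": (750, 750),
    "Falciferum": (750, 1000),
    "Exaratum": (1000, 1500),
    "Tenuicostatum": (500, 500),
    "Spinatum": (400, 300),
    "Margaritatus": (400, 300),
}


@dataclass
class ScenarioTable:
    """pCO2 scenario (ppm) and paleogeography per time bin.

    The default table carries the study configuration: a main and a
    secondary (more extreme) pCO2 estimate per ammonite (sub)zone, with a
    single paleogeography per analytical series (Toarcian 180 Ma primary,
    Pliensbachian 185 Ma secondary) so that one series never switches maps.
    """

    scenarios: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS)
    )
    geography_tag: str = "180Ma"

    def main(self, time_bin: str) -> float:
        return self.scenarios[time_bin][0]

    def secondary(self, time_bin: str) -> float:
        return self.scenarios[time_bin][1]

    def pco2(self, time_bin: str, which: str = "main") -> float:
        return self.main(time_bin) if which == "main" else self.secondary(time_bin)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "geography_tag": self.geography_tag,
            "scenarios": {
                k: {"main_ppm": float(v[0]), "secondary_ppm": float(v[1])}
                for k, v in self.scenarios.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioTable":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            scenarios={
                k: (float(v["main_ppm"]), float(v["secondary_ppm"]))
                for k, v in payload["scenarios"].items()
            },
            geography_tag=str(payload.get("geography_tag", "180Ma")),
        )
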