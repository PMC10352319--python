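"""Study-domain grid: cell-centred lat/lon frame with West/East split and cell areas.

The analysis layer never cares where concentration fields come from, only that
they live on a common grid with a two-region partition and positive cell areas,
so regional aggregates can be area-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four months used to represent the annual cycle; annual means are the
#: arithmetic mean over these.
MONTHS: tuple[str, ...] = ("Jan", "Apr", "Jul", "Oct")

#: Integer codes used in ``region_mask``.
REGION_CODES = {"West": 0, "East": 1, "outside": 2}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

_EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DomainGrid:
    """Cell-centred lat/lon(/level) grid with region labels and cell areas.

    Attributes
    ----------
    lat, lon:
        Strictly increasing cell-centre coordinates in degrees.
    level:
        Vertical layer indices, 1-based, 1 = surface.
    region_mask:
        ``(n_lat, n_lon)`` int array of :data:`REGION_CODES` (levels share the
        same mask).
    cell_area:
        ``(n_lat, n_lon)`` cell areas in km², all positive.
    """

    lat: np.ndarray
    lon: np.ndarray
    region_mask: np.ndarray
    cell_area: np.ndarray
    level: np.ndarray = field(default_factory=lambda: np.array([1]))
    months: tuple[str, ...] = MONTHS

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lat) > 0):
            raise ValueError("lat must be strictly increasing")
        if not np.all(np.diff(self.lon) > 0):
            raise ValueError("lon must be strictly increasing")
        if not np.all(self.cell_area > 0):
            raise ValueError("cell_area must be positive everywhere")
        if self.region_mask.shape != (self.lat.size, self.lon.size):
            raise ValueError("region_mask shape must be (n_lat, n_lon)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def n_level(self) -> int:
        return self.level.size

    def region_cells(self, region: str | None = None) -> np.ndarray:
        """Boolean mask of in-domain cells, optionally restricted to a region."""
        if region is None:
            return self.region_mask != REGION_CODES["outside"]
        if region not in REGION_CODES:
            raise ValueError(f"unknown region {region!r}")
        return self.region_mask == REGION_CODES[region]

    def area_weighted_mean(
        self, fld: np.ndarray, region: str | None = None
    ) -> float | np.ndarray:
        """Area-weighted mean of a field whose trailing dims are (lat, lon).

        NaNs in ``fld`` are ignored (their weight is dropped).  Leading
        dimensions (month, level, ...) are preserved.
        """
        return self._area_stat(fld, region, stat="mean")

    def area_weighted_std(
        self, fld: np.ndarray, region: str | None = None
    ) -> float | np.ndarray:
        """Area-weighted (spatial) standard deviation; NaNs ignored."""
        return self._area_stat(fld, region, stat="std")

    def _area_stat(self, fld: np.ndarray, region: str | None, stat: str):
        fld = np.asarray(fld, dtype=float)
        cells = self.region_cells(region)
        if not cells.any():
            raise ValueError(f"region {region!r} selects no cells")
        w = np.where(cells, self.cell_area, 0.0)
        valid = ~np.isnan(fld)
        wfull = np.broadcast_to(w, fld.shape) * valid
        x = np.where(valid, fld, 0.0)
        axes = (-2, -1)
        wsum = wfull.sum(axis=axes)
        mean = np.where(wsum > 0, (wfull * x).sum(axis=axes) / np.maximum(wsum, 1e-300), np.nan)
        if stat == "mean":
            out = mean
        else:
            dev = (x - np.expand_dims(mean, axes)) ** 2
            var = (wfull * dev).sum(axis=axes) / np.maximum(wsum, 1e-300)
            out = np.where(wsum > 0, np.sqrt(var), np.nan)
        return float(out) if out.ndim == 0 else out


def generate_domain(
    n_lat: int,
    n_lon: int,
    n_level: int = 1,
    seed: int = 0,
    lat_span: tuple[float, float] = (36.0, 68.0),
    lon_span: tuple[float, float] = (-8.0, 38.0),
) -> DomainGrid:
    """Build a deterministic synthetic European-like domain.

    The West/East split runs along a fixed longitude (the column boundary at
    ``n_lon // 2``), guaranteeing both regions are non-empty for any
    ``n_lon >= 2``.  The same grid is returned for the same arguments; ``seed``
    is accepted for interface symmetry with the stochastic generators.
    """
    if n_lat < 2 or n_lon < 2:
        raise ValueError(f"grid needs n_lat, n_lon >= 2, got ({n_lat}, {n_lon})")
    if n_level < 1:
        raise ValueError(f"n_level must be >= 1, got {n_level}")

    lat = np.linspace(*lat_span, n_lat)
    lon = np.linspace(*lon_span, n_lon)

    # West = everything west of the fixed split longitude.
    split = n_lon // 2
    region = np.full((n_lat, n_lon), REGION_CODES["East"], dtype=np.int8)
    region[:, :split] = REGION_CODES["West"]

    dlat = np.deg2rad(lat[1] - lat[0]) if n_lat > 1 else np.deg2rad(1.0)
    dlon = np.deg2rad(lon[1] - lon[0]) if n_lon > 1 else np.deg2rad(1.0)
    phi = np.deg2rad(lat)
    band = _EARTH_RADIUS_KM**2 * dlon * (np.sin(phi + dlat / 2) - np.sin(phi - dlat / 2))
    cell_area = np.repeat(band[:, None], n_lon, axis=1)

    return DomainGrid(
        lat=lat,
        lon=lon,
        region_mask=region,
        cell_area=cell_area,
        level=np.arange(1, n_level + 1),
    )
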