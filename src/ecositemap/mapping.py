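"""Categorical ecosite rasters from continuous regime rasters.

Every 10 m x 10 m cell (the footprint of a single field plot) gets an
ecosite by projecting its continuous (SNR, SMR) pair onto the edatopic
grid of its ecoregion, exactly as plots are classified.  The raw map is
then cleaned by a sieve: connected components of like-labelled cells
smaller than a minimum area (default 25 ha, i.e. 2,500 cells at 10 m) are
merged into the neighbouring component sharing the longest border,
smallest components first, until none remain below the threshold.
Ecoregion boundaries are hard barriers — merging never crosses them — and
nodata cells are never touched.

Raster I/O uses the ESRI ASCII grid format (plain text, row-major from
the top-left corner) with the nodata value honoured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .edatopic import EdatopicGrid, classify_point

__all__ = [
    "RasterError",
    "RegimeRaster",
    "EcositeRaster",
    "map_ecosites",
    "eliminate_small_polygons",
    "raster_summary",
    "read_ascii_grid",
    "write_ascii_grid",
]

NODATA_LABEL = -1


class RasterError(ValueError):
    pass


@dataclass(frozen=True)
class RegimeRaster:
    """Gridded continuous class-unit values (NaN marks nodata)."""

    values: np.ndarray  # 2-D float array, row-major from top-left
    cell_size: float = 10.0  # meters
    origin: tuple[float, float] = (0.0, 0.0)  # (xll, yll) of the lower-left corner

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise RasterError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be > 0")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """True where data is valid."""
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class EcositeRaster:
    """Gridded categorical ecosite labels with a per-cell ecoregion map."""

    labels: np.ndarray  # 2-D int array; NODATA_LABEL marks nodata
    region_map: np.ndarray  # 2-D int array of region codes
    regions: dict[int, str] = field(default_factory=dict)  # code -> region name
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        region_map = np.asarray(self.region_map, dtype=int)
        if labels.shape != region_map.shape:
            raise RasterError("labels and region_map shapes differ")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "region_map", region_map)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels != NODATA_LABEL


def _check_aligned(a: RegimeRaster, b: RegimeRaster, name_a: str, name_b: str) -> None:
    if a.shape != b.shape:
        raise RasterError(f"{name_a}/{name_b} shape mismatch: {a.shape} vs {b.shape}")
    if a.cell_size != b.cell_size:
        raise RasterError(
            f"{name_a}/{name_b} cell_size mismatch: {a.cell_size} vs {b.cell_size}"
        )
    if a.origin != b.origin:
        raise RasterError(f"{name_a}/{name_b} origin mismatch: {a.origin} vs {b.origin}")


def map_ecosites(
    smr: RegimeRaster,
    snr: RegimeRaster,
    region_map: np.ndarray,
    grids: dict[str, EdatopicGrid],
    regions: dict[int, str] | None = None,
) -> EcositeRaster:
    """Per-cell ecosite classification of aligned SMR/SNR rasters.

    ``region_map`` holds integer region codes; ``regions`` maps codes to
    the region names keying ``grids`` (default: code 0 -> acadian, 1 ->
    maritime_boreal).  Nodata (NaN) in either regime raster, or a
    negative region code, yields nodata in the output.
    """
    _check_aligned(smr, snr, "smr", "snr")
    region_map = np.asarray(region_map, dtype=int)
    if region_map.shape != smr.shape:
        raise RasterError(
            f"smr/region_map shape mismatch: {smr.shape} vs {region_map.shape}"
        )
    if regions is None:
        regions = {0: "acadian", 1: "maritime_boreal"}
    labels = np.full(smr.shape, NODATA_LABEL, dtype=int)
    valid = smr.mask & snr.mask & (region_map >= 0)
    for code in np.unique(region_map[valid]):
        name = regions.get(int(code))
        if name is None or name not in grids:
            raise RasterError(f"region code {code} has no edatopic grid")
        grid = grids[name]
        sel = valid & (region_map == code)
        x = np.clip(snr.values[sel], *grid.domain[0])
        y = np.clip(smr.values[sel], *grid.domain[1])
        out = np.full(x.shape, NODATA_LABEL, dtype=int)
        unassigned = np.ones(x.shape, dtype=bool)
        for rect in grid.rectangles:
            (xlo, xhi), (ylo, yhi) = rect.snr_interval, rect.smr_interval
            in_x = (x >= xlo) & ((x < xhi) | (xhi >= grid.domain[0][1]) & (x == xhi))
            in_y = (y >= ylo) & ((y < yhi) | (yhi >= grid.domain[1][1]) & (y == yhi))
            hit = unassigned & in_x & in_y
            out[hit] = rect.ecosite_id
            unassigned &= ~hit
        for i in np.flatnonzero(unassigned):  # nearest-rectangle fallback
            out[i] = classify_point(grid, float(x[i]), float(y[i]))[0]
        labels[sel] = out
    return EcositeRaster(
        labels=labels,
        region_map=region_map,
        regions=dict(regions),
        cell_size=smr.cell_size,
        origin=smr.origin,
    )


# -- small-polygon elimination (sieve) ----------------------------------

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _label_components(
    labels: np.ndarray, region_map: np.ndarray, structure: np.ndarray
) -> np.ndarray:
    """Connected components of same (ecosite, region); 0 marks nodata."""
    comp = np.zeros(labels.shape, dtype=int)
    next_id = 1
    valid = labels != NODATA_LABEL
    keys = np.unique(
        np.stack([labels[valid], region_map[valid]], axis=1), axis=0
    ) if valid.any() else []
    for lab, reg in keys:
        m = (labels == lab) & (region_map == reg)
        lab_arr, n = ndimage.label(m, structure=structure)
        comp[m] = lab_arr[m] + next_id - 1
        next_id += n
    return comp


def _border_counts(comp: np.ndarray, region_map: np.ndarray) -> dict:
    """Shared-border lengths (cell-edge counts) between component pairs
    within the same region."""
    borders: dict[tuple[int, int], int] = {}

    def scan(a, b, ra, rb):
        ok = (a > 0) & (b > 0) & (a != b) & (ra == rb)
        pairs = np.stack([a[ok], b[ok]], axis=1)
        if len(pairs) == 0:
            return
        pairs.sort(axis=1)
        uniq, cnt = np.unique(pairs, axis=0, return_counts=True)
        for (c1, c2), k in zip(uniq, cnt):
            key = (int(c1), int(c2))
            borders[key] = borders.get(key, 0) + int(k)

    scan(comp[:, :-1], comp[:, 1:], region_map[:, :-1], region_map[:, 1:])
    scan(comp[:-1, :], comp[1:, :], region_map[:-1, :], region_map[1:, :])
    return borders


def eliminate_small_polygons(
    raster: EcositeRaster,
    min_area_ha: float = 25.0,
    connectivity: int = 4,
) -> EcositeRaster:
    """Sieve: merge sub-threshold components into their longest-border
    neighbour, smallest first, until none remain below the threshold.

    The threshold in cells is ``min_area_ha * 1e4 / cell_size**2`` (2,500
    cells for 25 ha at 10 m).  Ties on border length go to the larger
    neighbour, then to the lower ecosite id.  A region whose entire extent
    is below the threshold is left intact (nothing to merge into).
    Idempotent: a second application is a no-op.
    """
    if min_area_ha <= 0:
        raise RasterError("min_area_ha must be > 0")
    if connectivity not in (4, 8):
        raise RasterError("connectivity must be 4 or 8")
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    threshold = min_area_ha * 1e4 / raster.cell_size**2

    labels = raster.labels.copy()
    region_map = raster.region_map

    for _ in range(labels.size):  # outer passes; converges long before this
        comp = _label_components(labels, region_map, structure)
        if comp.max() == 0:
            break
        sizes = np.bincount(comp.ravel())
        comp_label = {}
        comp_region = {}
        flat_c, flat_l, flat_r = comp.ravel(), labels.ravel(), region_map.ravel()
        order = np.argsort(flat_c)
        cs, starts = np.unique(flat_c[order], return_index=True)
        for c, s in zip(cs, starts):
            if c == 0:
                continue
            comp_label[int(c)] = int(flat_l[order[s]])
            comp_region[int(c)] = int(flat_r[order[s]])
        borders = _border_counts(comp, region_map)
        neigh: dict[int, dict[int, int]] = {}
        for (c1, c2), k in borders.items():
            neigh.setdefault(c1, {})[c2] = k
            neigh.setdefault(c2, {})[c1] = k

        # union-find over components; size/label/members tracked at the root
        parent = {int(c): int(c) for c in cs if c != 0}
        root_size = {c: int(sizes[c]) for c in parent}
        members_of = {c: [c] for c in parent}

        def find(c: int) -> int:
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        small = sorted(
            (c for c in parent if root_size[c] < threshold),
            key=lambda c: (root_size[c], c),
        )
        merged_any = False
        for c in small:
            rc = find(c)
            if root_size[rc] >= threshold:
                continue
            # aggregate border lengths of the current blob by neighbour root
            agg: dict[int, int] = {}
            for m in members_of[rc]:
                for nb, k in neigh.get(m, {}).items():
                    rn = find(nb)
                    if rn == rc:
                        continue
                    agg[rn] = agg.get(rn, 0) + k
            if not agg:
                continue  # isolated: whole region below threshold
            target = min(
                agg,
                key=lambda rn: (-agg[rn], -root_size[rn], comp_label[rn], rn),
            )
            parent[rc] = target
            root_size[target] += root_size[rc]
            members_of[target].extend(members_of.pop(rc))
            merged_any = True
        if not merged_any:
            break
        # rebuild the label raster from the union-find result
        new_label_of = {c: comp_label[find(c)] for c in parent}
        lut = np.zeros(int(comp.max()) + 1, dtype=int)
        lut[0] = NODATA_LABEL
        for c, lab in new_label_of.items():
            lut[c] = lab
        new_labels = np.where(comp > 0, lut[comp], labels)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return replace(raster, labels=labels)


def raster_summary(raster: EcositeRaster) -> pd.DataFrame:
    """Per-ecosite cell counts and area in hectares, by region."""
    rows = []
    for code in np.unique(raster.region_map[raster.mask]):
        name = raster.regions.get(int(code), str(code))
        sel = raster.mask & (raster.region_map == code)
        ids, counts = np.unique(raster.labels[sel], return_counts=True)
        for eid, cnt in zip(ids, counts):
            rows.append(
                {
                    "region": name,
                    "ecosite": int(eid),
                    "cells": int(cnt),
                    "area_ha": float(cnt) * raster.cell_size**2 / 1e4,
                }
            )
    return pd.DataFrame(rows)


# -- ESRI ASCII grid I/O -------------------------------------------------


def write_ascii_grid(
    path,
    values: np.ndarray,
    cell_size: float = 10.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row-major from top-left)."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.isnan(values), float(nodata), values)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        f"xllcorner {origin[0]}\n"
        f"yllcorner {origin[1]}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN.

    Returns ``(values, cell_size, (xllcorner, yllcorner))``.
    """
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterError(f"ASCII grid missing header field {key!r}")
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError(
            f"ASCII grid data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return values, float(header["cellsize"]), origin
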