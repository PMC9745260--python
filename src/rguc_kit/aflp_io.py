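"""Data model and I/O for band matrices, population metadata, and rasters.

A *band matrix* scores every individual at every locus as band presence (1)
or absence (0) — the standard representation of dominant markers such as
AFLPs, where heterozygotes cannot be distinguished from band-carrying
homozygotes. Populations partition the individuals; all downstream
statistics (diversity, rarity, coancestry, turnover models) consume this
container.

Rasters are regular lon/lat grids read and written as ESRI ASCII grids, a
plain-text exchange format understood by every desktop GIS. A
:class:`ClimateStack` holds several co-registered layers with a shared
nodata mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "ClimateStack",
    "band_frequencies",
    "read_band_matrix",
    "read_population_frame",
    "read_raster",
    "read_raster_stack",
    "write_band_matrix",
    "write_raster",
]


@dataclass
class BandMatrix:
    """Individuals x binary loci with a population partition.

    Parameters
    ----------
    values
        ``(n_individuals, n_loci)`` array with entries in ``{0, 1}``.
    individual_ids
        Unique identifier per row.
    locus_ids
        Unique identifier per column.
    populations
        Population label per individual (row-aligned). Every population
        must contain at least two individuals.
    """

    values: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.populations = [str(p) for p in self.populations]
        if self.values.ndim != 2:
            raise ValueError("band matrix must be 2-dimensional")
        n, L = self.values.shape
        if L < 1:
            raise ValueError("band matrix needs at least one locus")
        if len(self.individual_ids) != n or len(self.populations) != n:
            raise ValueError("individual ids / population labels must match row count")
        if len(self.locus_ids) != L:
            raise ValueError("locus ids must match column count")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.int8)
        sizes = pd.Series(self.populations).value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"populations with fewer than 2 individuals: {list(small.index)}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def population_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.populations:
            out[p] = out.get(p, 0) + 1
        return out

    def rows_of(self, population: str) -> np.ndarray:
        """Boolean row mask for one population."""
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def subset_populations(self, keep: Iterable[str]) -> "BandMatrix":
        keep = list(keep)
        mask = np.array([p in keep for p in self.populations])
        return BandMatrix(
            self.values[mask],
            [i for i, m in zip(self.individual_ids, mask) if m],
            list(self.locus_ids),
            [p for p, m in zip(self.populations, mask) if m],
        )


def read_band_matrix(path: str | Path, *, impute_missing: bool = False) -> BandMatrix:
    """Read a delimited band-matrix file.

    Layout: header row of locus ids after two leading columns
    (individual id, population label); one row per individual with 0/1
    cells. Comma- or tab-delimited, auto-detected.

    Missing cells are rejected unless ``impute_missing`` is set, in which
    case they are replaced by the rounded population-mean band frequency
    (and the replacements are printed to stderr).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    delim = "\t" if sample.split("\n", 1)[0].count("\t") >= sample.split("\n", 1)[0].count(",") else ","
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("band matrix file needs individual, population, and locus columns")
    ind_col, pop_col = df.columns[:2]
    locus_ids = [str(c) for c in df.columns[2:]]
    individual_ids = df[ind_col].astype(str).tolist()
    populations = df[pop_col].astype(str).tolist()
    raw = df[df.columns[2:]].to_numpy()

    values = np.full(raw.shape, -1, dtype=np.int8)
    missing = np.zeros(raw.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(raw):
        s = str(cell).strip()
        if s in ("0", "1"):
            values[i, j] = int(s)
        elif s in ("", "NA", "?", "-"):
            missing[i, j] = True
        else:
            raise ValueError(
                f"non-binary cell at individual {individual_ids[i]!r}, "
                f"locus {locus_ids[j]!r}: {s!r}"
            )
    if missing.any():
        if not impute_missing:
            i, j = np.argwhere(missing)[0]
            raise ValueError(
                f"missing cell at individual {individual_ids[i]!r}, locus "
                f"{locus_ids[j]!r}; pass impute_missing=True to fill from "
                "population means"
            )
        import sys

        pops = np.asarray(populations)
        for j in range(values.shape[1]):
            col_missing = missing[:, j]
            for i in np.flatnonzero(col_missing):
                same = (pops == pops[i]) & ~missing[:, j]
                fill = int(round(values[same, j].mean())) if same.any() else 0
                values[i, j] = fill
                print(
                    f"rguc-kit: imputed {individual_ids[i]}/{locus_ids[j]} -> {fill}",
                    file=sys.stderr,
                )
    return BandMatrix(values, individual_ids, locus_ids, populations)


def write_band_matrix(bm: BandMatrix, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a band matrix in the dialect :func:`read_band_matrix` accepts."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["individual", "population", *bm.locus_ids])
        for i in range(bm.n_individuals):
            w.writerow([bm.individual_ids[i], bm.populations[i], *bm.values[i].tolist()])


def read_population_frame(path: str | Path) -> pd.DataFrame:
    """Read population metadata CSV.

    Expected columns: ``population``, ``longitude``, ``latitude`` and
    optionally ``cluster`` (integer labels ``1..K`` with no gaps).
    """
    pf = pd.read_csv(path)
    required = {"population", "longitude", "latitude"}
    missing = required - set(pf.columns)
    if missing:
        raise ValueError(f"population metadata missing columns: {sorted(missing)}")
    pf["population"] = pf["population"].astype(str)
    return validate_population_frame(pf)


def validate_population_frame(pf: pd.DataFrame) -> pd.DataFrame:
    lon = pf["longitude"].to_numpy(float)
    lat = pf["latitude"].to_numpy(float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("non-finite coordinates")
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("coordinates outside WGS84 bounds")
    if pf["population"].duplicated().any():
        raise ValueError("duplicate population labels")
    if "cluster" in pf.columns and pf["cluster"].notna().all():
        labels = sorted(set(int(c) for c in pf["cluster"]))
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"cluster labels must cover 1..K with no gaps, got {labels}")
    return pf


def band_frequencies(bm: BandMatrix) -> pd.DataFrame:
    """Per-population and overall band (carrier) frequencies.

    Returns a ``locus x population`` table in ``[0, 1]`` with an extra
    ``overall`` column: the carrier fraction over all individuals.
    """
    cols = {}
    for pop in bm.population_labels:
        rows = bm.rows_of(pop)
        cols[pop] = bm.values[rows].mean(axis=0)
    cols["overall"] = bm.values.mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(bm.locus_ids, name="locus"))


# ---------------------------------------------------------------------------
# Rasters


@dataclass
class ClimateStack:
    """Named raster layers on one shared regular lon/lat grid.

    The grid is cell-centered, row-major from the NW corner (row 0 is the
    northernmost). ``mask`` is True where ANY layer has nodata; it is the
    union of the per-layer masks and applies to all layers.
    """

    layers: dict[str, np.ndarray]
    xllcorner: float
    yllcorner: float
    cellsize: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty stack")
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree on grid shape: {shapes}")
        shape = shapes.pop()
        combined = np.zeros(shape, dtype=bool)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            combined |= ~np.isfinite(arr)
            self.layers[name] = arr
        if self.mask is not None:
            combined |= np.asarray(self.mask, dtype=bool)
        self.mask = combined
        for arr in self.layers.values():
            arr[self.mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def geometry(self) -> tuple[float, float, float, tuple[int, int]]:
        return (self.xllcorner, self.yllcorner, self.cellsize, self.shape)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a lon/lat point."""
        nrow, ncol = self.shape
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yllcorner) / self.cellsize))
        row = nrow - 1 - row_from_bottom
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def sample(self, lons: Sequence[float], lats: Sequence[float]) -> pd.DataFrame:
        """Layer values at point locations (one row per point)."""
        rows = [self.cell_of(lo, la) for lo, la in zip(lons, lats)]
        data = {
            name: [arr[r, c] for r, c in rows] for name, arr in self.layers.items()
        }
        return pd.DataFrame(data)

    def cell_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of every cell center, each shaped like the grid."""
        nrow, ncol = self.shape
        lon = self.xllcorner + (np.arange(ncol) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrow - 1 - np.arange(nrow) + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def table(self) -> pd.DataFrame:
        """Non-masked cells as a DataFrame (row, col, one column per layer)."""
        rows, cols = np.nonzero(~self.mask)
        data = {"row": rows, "col": cols}
        for name, arr in self.layers.items():
            data[name] = arr[rows, cols]
        return pd.DataFrame(data)


_NODATA = -9999.0


def read_raster(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read one ESRI ASCII grid: (array with NaN nodata, xll, yll, cellsize)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {data.shape} disagrees with header")
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    return data, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_raster(layer: np.ndarray, path: str | Path, *, xllcorner: float,
                 yllcorner: float, cellsize: float) -> None:
    """Write one layer as an ESRI ASCII grid (NaN -> nodata)."""
    layer = np.asarray(layer, dtype=float)
    nrow, ncol = layer.shape
    out = np.where(np.isfinite(layer), layer, _NODATA)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncol}\nnrows {nrow}\nxllcorner {xllcorner!r}\n"
            f"yllcorner {yllcorner!r}\ncellsize {cellsize!r}\nNODATA_value {_NODATA}\n"
        )
        np.savetxt(fh, out, fmt="%.10g")


def read_raster_stack(paths: Mapping[str, str | Path] | Sequence[str | Path] | str | Path) -> ClimateStack:
    """Assemble a :class:`ClimateStack` from ESRI ASCII grids.

    ``paths`` may be a mapping name -> file, a sequence of files (named by
    stem), or a directory containing ``*.asc``. All grids must share
    geometry; a mismatch is a hard error naming the offending layer.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        files = sorted(Path(paths).glob("*.asc"))
        if not files:
            raise ValueError(f"no .asc rasters in {paths}")
        named = {f.stem: f for f in files}
    elif isinstance(paths, Mapping):
        named = {str(k): Path(v) for k, v in paths.items()}
    else:
        named = {Path(p).stem: Path(p) for p in paths}  # type: ignore[union-attr]

    layers: dict[str, np.ndarray] = {}
    geom: tuple | None = None
    for name, f in named.items():
        arr, xll, yll, cs = read_raster(f)
        this = (round(xll, 9), round(yll, 9), round(cs, 9), arr.shape)
        if geom is None:
            geom = this
        elif this != geom:
            raise ValueError(f"raster {name!r} geometry {this} does not match {geom}")
        layers[name] = arr
    assert geom is not None
    return ClimateStack(layers, geom[0], geom[1], geom[2])


def write_raster_stack(stack: ClimateStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, arr in stack.layers.items():
        p = directory / f"{name}.asc"
        write_raster(arr, p, xllcorner=stack.xllcorner, yllcorner=stack.yllcorner,
                     cellsize=stack.cellsize)
        out.append(p)
    return out
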