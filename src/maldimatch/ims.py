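"""IMS dataset container, I/O, normalization, binning and ion images.

An IMS dataset is a collection of centroided peak lists, one per pixel of a
regular grid.  Pixel coordinates are 0-based with ``x`` the column and ``y``
the row, origin at the top left.  All downstream stages (segmentation,
deisotoping) consume either the dataset directly or the pixels x bins matrix
produced by :func:`bin_spectra`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class IMSDataset:
    """Per-pixel centroided spectra on a shared pixel grid.

    Attributes
    ----------
    coordinates : (n_pixels, 2) int array of (x, y) pixel indices, unique.
    mzs, intensities : lists of per-pixel arrays; each ``mzs[i]`` is sorted
        strictly increasing (duplicates within a pixel are summed on load).
    mass_range : (low, high) declared acquisition range in Da.
    spatial_resolution_um : grid spacing metadata (default 25 um).
    normalization : None or a string recording the applied normalization.
    """

    coordinates: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    mass_range: tuple[float, float]
    spatial_resolution_um: float = 25.0
    normalization: str | None = None
    flagged_pixels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_pixels(self) -> int:
        return len(self.mzs)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding pixel grid."""
        return (int(self.coordinates[:, 1].max()) + 1, int(self.coordinates[:, 0].max()) + 1)

    def total_ion_current(self) -> np.ndarray:
        return np.array([float(i.sum()) for i in self.intensities])

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        coords = np.asarray(self.coordinates)
        if len({(int(x), int(y)) for x, y in coords}) != len(coords):
            raise ValueError("pixel coordinates are not unique")
        if not any(len(m) for m in self.mzs):
            raise ValueError("dataset has no peaks in any pixel")
        lo, hi = self.mass_range
        for i, m in enumerate(self.mzs):
            if len(m) and (np.any(np.diff(m) <= 0)):
                raise ValueError(f"pixel {i}: peak list not strictly increasing in m/z")
            if len(m) and (m[0] < lo - 0.5 or m[-1] > hi + 0.5):
                raise ValueError(f"pixel {i}: peak outside declared mass range +/- 0.5 Da")


def _clean_peaks(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and sum duplicate m/z values within a pixel."""
    mz = np.asarray(mz, dtype=float)
    inten = np.asarray(inten, dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if len(mz) > 1:
        uniq, inv = np.unique(mz, return_inverse=True)
        if len(uniq) != len(mz):
            summed = np.zeros(len(uniq))
            np.add.at(summed, inv, inten)
            mz, inten = uniq, summed
    return mz, inten


# ---------------------------------------------------------------------------
# I/O

def write_ims(ds: IMSDataset, path, format: str = "imzml") -> None:
    """Write a dataset as processed-mode centroided imzML or a tabular dump.

    The tabular dump is a tab-separated file with columns
    ``pixel_x, pixel_y, mz, intensity`` plus ``# key=value`` metadata lines.
    """
    path = str(path)
    if format == "imzml":
        from pyimzml.ImzMLWriter import ImzMLWriter

        with ImzMLWriter(path, mode="processed") as w:
            for (x, y), mz, inten in zip(ds.coordinates, ds.mzs, ds.intensities):
                # imzML coordinates are 1-based
                w.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1, 1))
    elif format == "tabular":
        with open(path, "w") as fh:
            fh.write(f"# mass_range={ds.mass_range[0]},{ds.mass_range[1]}\n")
            fh.write(f"# spatial_resolution_um={ds.spatial_resolution_um}\n")
            fh.write("pixel_x\tpixel_y\tmz\tintensity\n")
            for (x, y), mz, inten in zip(ds.coordinates, ds.mzs, ds.intensities):
                for m, i in zip(mz, inten):
                    fh.write(f"{x}\t{y}\t{float(m)!r}\t{float(i)!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ims(path, format: str = "imzml", mass_range: tuple[float, float] | None = None) -> IMSDataset:
    """Read an IMS dataset from imzML or the tabular dump format.

    Unsorted peak lists are sorted and duplicate m/z within a pixel summed.
    Raises a parse error with context for malformed files and an explicit
    error for an empty dataset.
    """
    path = str(path)
    coords, mzs, intens = [], [], []
    meta: dict[str, str] = {}
    if format == "imzml":
        from pyimzml.ImzMLParser import ImzMLParser

        parser = ImzMLParser(path)
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(i)
            mz, inten = _clean_peaks(mz, inten)
            coords.append((int(x) - 1, int(y) - 1))
            mzs.append(mz)
            intens.append(inten)
    elif format == "tabular":
        with open(path) as fh:
            rows: dict[tuple[int, int], list[tuple[float, float]]] = {}
            header_seen = False
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "=" in line:
                        k, v = line[1:].split("=", 1)
                        meta[k.strip()] = v.strip()
                    continue
                if not header_seen:
                    if line.split("\t")[:2] != ["pixel_x", "pixel_y"]:
                        raise ValueError(f"{path}:{lineno}: expected header 'pixel_x\\tpixel_y\\tmz\\tintensity'")
                    header_seen = True
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
                try:
                    x, y, m, i = int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                rows.setdefault((x, y), []).append((m, i))
        for (x, y), peaks in rows.items():
            arr = np.array(peaks)
            mz, inten = _clean_peaks(arr[:, 0], arr[:, 1])
            coords.append((x, y))
            mzs.append(mz)
            intens.append(inten)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not coords or not any(len(m) for m in mzs):
        raise ValueError(f"{path}: no spectra")

    if mass_range is None:
        if "mass_range" in meta:
            lo, hi = (float(v) for v in meta["mass_range"].split(","))
            mass_range = (lo, hi)
        else:
            all_lo = min(m[0] for m in mzs if len(m))
            all_hi = max(m[-1] for m in mzs if len(m))
            mass_range = (float(np.floor(all_lo)), float(np.ceil(all_hi)))
    res = float(meta.get("spatial_resolution_um", 25.0))
    ds = IMSDataset(np.array(coords, dtype=int), mzs, intens, mass_range, spatial_resolution_um=res)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Normalization / binning / imaging

def tic_normalize(ds: IMSDataset) -> IMSDataset:
    """Scale each pixel so its total ion current equals the dataset mean TIC.

    Keeps intensities on the acquisition scale (normalization to the mean
    TIC rather than to 1).  Pixels with zero total intensity are left
    untouched and recorded in ``flagged_pixels``.
    """
    tic = ds.total_ion_current()
    positive = tic > 0
    mean_tic = tic[positive].mean() if positive.any() else 0.0
    new_int = []
    for i, inten in enumerate(ds.intensities):
        if positive[i]:
            new_int.append(inten * (mean_tic / tic[i]))
        else:
            new_int.append(inten.copy())
    return replace(
        ds,
        intensities=new_int,
        normalization="tic-mean",
        flagged_pixels=np.flatnonzero(~positive),
    )


@dataclass
class BinnedMatrix:
    """Pixels x m/z-bins intensity matrix with uniform bin width.

    Bins are half-open ``[lo, lo + w)``, left-inclusive, so a peak exactly
    on a boundary lands in the higher bin.  Stored sparse (CSR): with a
    0.1 Da width on a 600-3200 Da range there are 26,000 bins, nearly all
    empty for centroided data.
    """

    matrix: sp.csr_matrix
    bin_centers: np.ndarray
    width: float
    mass_range: tuple[float, float]
    coordinates: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def bin_spectra(ds: IMSDataset, width: float = 0.1) -> BinnedMatrix:
    """Accumulate peak intensities into uniform m/z bins of the given width."""
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    lo, hi = ds.mass_range
    n_bins = int(np.ceil((hi - lo) / width))
    centers = lo + (np.arange(n_bins) + 0.5) * width
    rows, cols, vals = [], [], []
    for i, (mz, inten) in enumerate(zip(ds.mzs, ds.intensities)):
        if not len(mz):
            continue
        # small epsilon keeps peaks sitting exactly on a boundary in the
        # higher (left-inclusive) bin despite float rounding of (mz-lo)/width
        idx = np.floor((mz - lo) / width + 1e-9).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)  # peaks in the +/-0.5 Da guard band
        rows.append(np.full(len(idx), i))
        cols.append(idx)
        vals.append(inten)
    if rows:
        rows_a = np.concatenate(rows)
        cols_a = np.concatenate(cols)
        vals_a = np.concatenate(vals)
    else:
        rows_a = cols_a = vals_a = np.zeros(0)
    mat = sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(ds.n_pixels, n_bins)).tocsr()
    return BinnedMatrix(mat, centers, width, ds.mass_range, ds.coordinates.copy())


@dataclass
class IonImage:
    """Per-pixel summed intensity in a narrow m/z window."""

    target_mz: float
    half_window: float
    grid: np.ndarray  # (n_rows, n_cols), NaN where no pixel was acquired
    values: np.ndarray  # per-pixel vector in dataset pixel order


def ion_image(ds: IMSDataset, mz: float, half_window: float = 0.1) -> IonImage:
    """Sum intensities of peaks with ``|peak mz - mz| <= half_window`` per pixel."""
    lo, hi = ds.mass_range
    if not (lo <= mz <= hi):
        raise ValueError(f"target m/z {mz} outside mass range [{lo}, {hi}]")
    vals = np.zeros(ds.n_pixels)
    for i, (m, inten) in enumerate(zip(ds.mzs, ds.intensities)):
        if len(m):
            a = np.searchsorted(m, mz - half_window, side="left")
            b = np.searchsorted(m, mz + half_window, side="right")
            vals[i] = inten[a:b].sum()
    n_rows, n_cols = ds.grid_shape
    grid = np.full((n_rows, n_cols), np.nan)
    grid[ds.coordinates[:, 1], ds.coordinates[:, 0]] = vals
    return IonImage(mz, half_window, grid, vals)
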