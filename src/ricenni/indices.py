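"""Vegetation indices from five-band canopy reflectance.

Bands: blue 450 nm, green 560 nm, red 650 nm, red edge 730 nm and
near-infrared 840 nm, all as reflectance fractions in [0, 1].  Nine
indices commonly used for canopy N diagnosis are provided; undefined
values (zero denominators) propagate as NaN markers rather than raising.

The NDRE row of the source index table is printed with the same formula
as NDVI; both that literal dialect (``as_printed``, default) and the
conventional red-edge form (NIR-RE)/(NIR+RE) (``red_edge``) are
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BandReflectance",
    "INDEX_NAMES",
    "BAND_COLUMNS",
    "compute_index",
    "compute_all_indices",
    "indices_table",
    "mask_soil",
    "zonal_mean_reflectance",
]

BAND_COLUMNS = ("b450", "g560", "r650", "re730", "nir840")

#: Fixed index order; used for deterministic tie-breaking downstream.
INDEX_NAMES = ("ndvi", "nnvi", "rvi", "nri", "rvi_minus_1", "sr", "ndre", "psnd_c", "savi")


@dataclass(frozen=True)
class BandReflectance:
    b450: float
    g560: float
    r650: float
    re730: float
    nir840: float

    def __post_init__(self) -> None:
        for name in BAND_COLUMNS:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} reflectance must lie in [0, 1], got {v}")


def _ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def _normdiff(x, y):
    return _ratio(np.asarray(x, dtype=float) - y, np.asarray(x, dtype=float) + y)


def compute_index(name: str, bands, ndre_dialect: str = "as_printed"):
    """Evaluate one vegetation index on a band record (or band arrays).

    ``bands`` is a :class:`BandReflectance`, mapping or DataFrame with
    the :data:`BAND_COLUMNS` fields.  Zero denominators yield NaN.
    """
    if ndre_dialect not in ("as_printed", "red_edge"):
        raise ValueError("ndre_dialect must be 'as_printed' or 'red_edge'")
    get = (lambda k: getattr(bands, k)) if isinstance(bands, BandReflectance) else (lambda k: bands[k])
    b, g, r = get("b450"), get("g560"), get("r650")
    re, nir = get("re730"), get("nir840")
    nir = np.asarray(nir, dtype=float)
    r = np.asarray(r, dtype=float)
    if name == "ndvi":
        out = _normdiff(nir, r)
    elif name == "nnvi":
        out = _normdiff(nir, r) * nir
    elif name == "rvi":
        out = _ratio(nir, r)
    elif name == "nri":
        out = _normdiff(g, r)
    elif name == "rvi_minus_1":
        out = _ratio(nir, r) - 1.0
    elif name == "sr":
        out = _ratio(nir, g)
    elif name == "ndre":
        out = _normdiff(nir, re) if ndre_dialect == "red_edge" else _normdiff(nir, r)
    elif name == "psnd_c":
        out = _normdiff(nir, b)
    elif name == "savi":
        out = 1.5 * _ratio(nir - r, nir + r + 0.5)
    else:
        raise ValueError(f"unknown vegetation index {name!r}")
    return float(out) if out.ndim == 0 else out


def compute_all_indices(bands, ndre_dialect: str = "as_printed") -> dict:
    """All nine indices of one band record as an ordered name -> value dict."""
    return {name: compute_index(name, bands, ndre_dialect) for name in INDEX_NAMES}


def indices_table(reflectance: pd.DataFrame, ndre_dialect: str = "as_printed") -> pd.DataFrame:
    """Append the nine index columns to a per-plot reflectance table."""
    missing = [c for c in BAND_COLUMNS if c not in reflectance.columns]
    if missing:
        raise ValueError(f"reflectance table lacks band columns: {missing}")
    out = reflectance.copy()
    for name in INDEX_NAMES:
        out[name] = compute_index(name, reflectance, ndre_dialect)
    return out


def mask_soil(pixels: pd.DataFrame, threshold: float = 0.3) -> tuple[pd.DataFrame, float]:
    """Drop soil-background records by an NDVI cut.

    Returns the kept records and the kept fraction.  Records whose NDVI
    is undefined are treated as soil.  An empty result triggers a
    warning, not an error.
    """
    if not -1 <= threshold < 1:
        raise ValueError("threshold must lie in [-1, 1)")
    ndvi = compute_index("ndvi", pixels)
    keep = np.asarray(ndvi >= threshold) & ~np.isnan(ndvi)
    kept = pixels.loc[keep]
    fraction = float(keep.mean()) if len(pixels) else 0.0
    if len(pixels) and not keep.any():
        warnings.warn("soil mask removed every record", stacklevel=2)
    return kept, fraction


def zonal_mean_reflectance(stack, windows: dict, soil_threshold: float | None = 0.3) -> pd.DataFrame:
    """Per-plot mean reflectance from a 5-band image stack.

    ``stack`` is an array of shape (5, rows, cols) in the
    :data:`BAND_COLUMNS` band order, or a path to a multi-band TIFF
    (read with tifffile).  ``windows`` maps plot id to a pixel-coordinate
    rectangle (row0, row1, col0, col1).  Soil pixels are removed by the
    NDVI cut before averaging (``soil_threshold=None`` disables it).
    """
    if isinstance(stack, (str, bytes)) or hasattr(stack, "__fspath__"):
        import tifffile

        stack = tifffile.imread(stack)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(BAND_COLUMNS):
        raise ValueError("stack must have shape (5, rows, cols)")
    rows = []
    for plot_id, (r0, r1, c0, c1) in windows.items():
        pix = stack[:, r0:r1, c0:c1].reshape(len(BAND_COLUMNS), -1)
        table = pd.DataFrame(pix.T, columns=list(BAND_COLUMNS))
        if soil_threshold is not None:
            table, _ = mask_soil(table, soil_threshold)
        if table.empty:
            warnings.warn(f"plot {plot_id!r}: no canopy pixels after masking", stacklevel=2)
            rows.append({"plot_id": plot_id, **{c: np.nan for c in BAND_COLUMNS}})
        else:
            rows.append({"plot_id": plot_id, **table.mean().to_dict()})
    return pd.DataFrame(rows)
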