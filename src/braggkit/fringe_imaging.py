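"""Finite-crystallite intensity maps on fractional-index grids.

A crystallite of N1 x N2 x N3 unit cells produces interference fringes
between Bragg peaks: along an axis of N cells the Laue factor has N-1 zeros
per unit interval of the fractional index and N-2 subsidiary maxima between
adjacent main peaks.  This module evaluates |F|^2 on an (h, k) grid at a
fixed l section and renders the result as an 8-bit grayscale raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crystal_model import CrystalStructure
from .direct_summation import CrystalliteExtent, sf_batch
from .errors import InputError, ResourceLimitError

__all__ = ["FractionalGrid", "IntensityImage", "fringe_intensity_map", "render_image"]

GRID_POINT_CAP = 10**6


@dataclass(frozen=True)
class FractionalGrid:
    """Plane section of reciprocal space: (h, k) ranges at fixed l.

    Ranges are (min, max, step) in reciprocal-lattice units; the grid is
    inclusive of min and of the last point <= max.
    """

    h_range: tuple[float, float, float]
    k_range: tuple[float, float, float]
    l_fixed: float = 0.0

    def __post_init__(self):
        for rng in (self.h_range, self.k_range):
            lo, hi, step = rng
            if step <= 0:
                raise InputError("grid step must be positive")
            if hi <= lo:
                raise InputError("grid max must exceed min")

    @staticmethod
    def _axis(rng) -> np.ndarray:
        lo, hi, step = rng
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    @property
    def h_axis(self) -> np.ndarray:
        return self._axis(self.h_range)

    @property
    def k_axis(self) -> np.ndarray:
        return self._axis(self.k_range)

    @property
    def n_points(self) -> int:
        return len(self.h_axis) * len(self.k_axis)


@dataclass
class IntensityImage:
    """2D |F|^2 map with its grid axes."""

    values: np.ndarray             # (n_h, n_k), >= 0
    h_axis: np.ndarray
    k_axis: np.ndarray
    l_fixed: float = 0.0
    scale: str = "linear"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.h_axis), len(self.k_axis)):
            raise InputError("values shape inconsistent with grid axes")
        if (self.values < 0).any():
            raise InputError("intensities must be non-negative")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# rows: h = " + " ".join(f"{h:.6g}" for h in self.h_axis) + "\n")
            fh.write("# cols: k = " + " ".join(f"{k:.6g}" for k in self.k_axis) + "\n")
            fh.write(f"# l = {self.l_fixed:.6g}\n")
            np.savetxt(fh, self.values, fmt="%.8e", delimiter="\t")


def fringe_intensity_map(
    structure: CrystalStructure,
    extent: CrystalliteExtent,
    grid: FractionalGrid,
) -> IntensityImage:
    """|F_finite(h, k, l_fixed)|^2 over the grid, via the factorized form."""
    if grid.n_points > GRID_POINT_CAP:
        raise ResourceLimitError(
            f"grid has {grid.n_points} points, exceeding the cap ({GRID_POINT_CAP})"
        )
    ha, ka = grid.h_axis, grid.k_axis
    hh, kk = np.meshgrid(ha, ka, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), np.full(hh.size, grid.l_fixed)], axis=-1)
    rs = sf_batch(structure, hkl, extent=extent)
    return IntensityImage(
        values=(rs.amplitudes**2).reshape(len(ha), len(ka)),
        h_axis=ha,
        k_axis=ka,
        l_fixed=grid.l_fixed,
    )


def render_image(
    img: IntensityImage,
    scale: str = "linear",
    gamma: float = 1.0,
    levels: tuple[float, float] | None = None,
) -> np.ndarray:
    """Map an intensity image to an 8-bit grayscale raster (uint8 array).

    linear: values normalized to [0, 1] by the map maximum, raised to
    ``gamma``.  log: levels = log10(I) clipped to ``levels`` = (lo, hi)
    decades; default window is (max-6, max) so that a global intensity
    rescale leaves the raster unchanged, while an explicit window turns a
    x10 rescale into a uniform level shift.  An all-zero map renders black.
    """
    if scale not in ("linear", "log"):
        raise InputError(f"scale must be 'linear' or 'log', got {scale!r}")
    v = img.values
    if not np.isfinite(v).all():
        raise InputError("intensity map contains non-finite values")
    vmax = v.max()
    if vmax <= 0:
        return np.zeros(v.shape, dtype=np.uint8)
    if scale == "linear":
        norm = (v / vmax) ** gamma
    else:
        with np.errstate(divide="ignore"):
            lv = np.log10(np.maximum(v, vmax * 1e-300))
        lo, hi = levels if levels is not None else (math.log10(vmax) - 6.0, math.log10(vmax))
        if hi <= lo:
            raise InputError("log level window must have hi > lo")
        norm = np.clip((lv - lo) / (hi - lo), 0.0, 1.0) ** gamma
    return np.round(norm * 255.0).astype(np.uint8)
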