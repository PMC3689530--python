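"""Bragg spot detection on pixel-array detector frames.

The per-frame pipeline follows the classic spotfinding sequence: classify
pixels as signal or noise against a robust local background, group signal
pixels into connected components (spots), reject ice/powder rings found as
over-occupied resolution shells, apply spot-quality heuristics, and report
per-image statistics (spot count, total intensity, resolution limit).

Background is estimated per square tile from the median and a MAD-derived
sigma of the active pixels, so a handful of bright spots cannot bias it.
All thresholds are explicit parameters.

Pixel convention: 0-based (slow, fast) indices; a pixel's centre sits at
(slow + 0.5, fast + 0.5) in pixel units, and the detector x axis runs along
fast, y along slow, both in mm from the image origin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError

__all__ = [
    "DetectorGeometry",
    "DetectorFrame",
    "Spot",
    "SpotStats",
    "SpotfinderParams",
    "estimate_background",
    "classify_pixels",
    "find_spots",
    "detect_rings",
    "filter_spots",
    "signal_strength_report",
    "format_report",
    "format_report_xml",
    "classify_lattice_overlap",
]

ICE_D_SPACINGS = (3.90, 3.67, 3.44)   # strongest hexagonal-ice rings, A

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# Geometry and frames
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector normal to the beam."""

    distance: float                  # crystal-to-detector, mm
    wavelength: float                # A
    beam_center: tuple[float, float]  # (x, y) mm; x along fast, y along slow
    pixel_size: float                # mm
    image_size: tuple[int, int]      # (slow, fast) pixels

    def __post_init__(self):
        if self.distance <= 0 or self.wavelength <= 0 or self.pixel_size <= 0:
            raise InputError("distance, wavelength and pixel size must be positive")
        if min(self.image_size) < 1:
            raise InputError("image size must be positive")

    def radius_mm(self, slow, fast):
        """Distance from beam centre to pixel centre(s), mm."""
        x = (np.asarray(fast, dtype=float) + 0.5) * self.pixel_size
        y = (np.asarray(slow, dtype=float) + 0.5) * self.pixel_size
        return np.hypot(x - self.beam_center[0], y - self.beam_center[1])

    def d_spacing(self, slow, fast):
        """Resolution d (A) of pixel(s): d = lambda / (2 sin(0.5 atan(r/D)))."""
        r = self.radius_mm(slow, fast)
        theta = 0.5 * np.arctan2(r, self.distance)
        with np.errstate(divide="ignore"):
            return self.wavelength / (2.0 * np.sin(theta))

    def d_star(self, slow, fast):
        return 1.0 / self.d_spacing(slow, fast)

    def d_star_map(self) -> np.ndarray:
        ns, nf = self.image_size
        slow, fast = np.meshgrid(np.arange(ns), np.arange(nf), indexing="ij")
        return self.d_star(slow, fast)


@dataclass
class DetectorFrame:
    """Pixel counts plus geometry and an active-pixel mask."""

    counts: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != tuple(self.geometry.image_size):
            raise InputError("counts shape does not match geometry.image_size")
        if (self.counts < 0).any():
            raise InputError("pixel counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise InputError("mask shape does not match counts")


@dataclass
class Spot:
    centroid: tuple[float, float]    # (slow, fast), fractional pixels
    n_pixels: int
    total_intensity: float           # background-subtracted ADU
    peak_height: float               # background-subtracted ADU
    d_spacing: float                 # A
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)   # slow0, slow1, fast0, fast1
    peak_snr: float = float("inf")   # peak_height / local background sigma

    @property
    def d_star(self) -> float:
        return 1.0 / self.d_spacing

    @property
    def elongation(self) -> float:
        h = max(self.bbox[1] - self.bbox[0], 1)
        w = max(self.bbox[3] - self.bbox[2], 1)
        return max(h, w) / min(h, w)


@dataclass
class SpotStats:
    n_spots: int
    total_intensity: float
    resolution_limit: float | None   # A; None when no spots accepted
    n_ring_rejected: int = 0
    n_quality_rejected: int = 0


@dataclass(frozen=True)
class SpotfinderParams:
    """All tunables of the per-frame pipeline."""

    n_sigma: float = 3.5
    tile: int = 64
    min_pixels: int = 2
    max_pixels: int = 400
    elongation_max: float = 4.0
    peak_fraction_max: float = 0.95
    peak_snr_min: float = 7.0
    ring_shell_width: float = 0.002   # A^-1
    ring_occupancy_cut: float = 0.25
    seed_ice_rings: bool = False
    resolution_percentile: float = 80.0


# --------------------------------------------------------------------------
# Background and pixel classification
# --------------------------------------------------------------------------

def estimate_background(frame: DetectorFrame, tile: int = 64):
    """Per-tile median and MAD-derived sigma of active pixels, as full maps."""
    if tile < 8:
        raise InputError("tile size must be >= 8")
    counts = frame.counts.astype(float)
    med = np.zeros_like(counts)
    sig = np.zeros_like(counts)
    ns, nf = counts.shape
    for s0 in range(0, ns, tile):
        for f0 in range(0, nf, tile):
            sl = (slice(s0, min(s0 + tile, ns)), slice(f0, min(f0 + tile, nf)))
            active = frame.mask[sl]
            if not active.any():
                continue
            vals = counts[sl][active]
            m = np.median(vals)
            sigma = 1.4826 * np.median(np.abs(vals - m))
            med[sl] = m
            sig[sl] = sigma
    return med, sig


def classify_pixels(
    frame: DetectorFrame, n_sigma: float = 3.5, tile: int = 64
) -> np.ndarray:
    """Boolean signal mask: active pixels exceeding median + n_sigma * sigma.

    Inactive pixels are never signal.  A fully masked frame yields an
    all-false mask (with a warning).
    """
    if n_sigma <= 0:
        raise InputError("n_sigma must be positive")
    if not frame.mask.any():
        warnings.warn("frame is fully masked; no pixels can be signal", stacklevel=2)
        return np.zeros(frame.counts.shape, dtype=bool)
    med, sig = estimate_background(frame, tile)
    return frame.mask & (frame.counts > med + n_sigma * sig)


# --------------------------------------------------------------------------
# Spot identification
# --------------------------------------------------------------------------

def find_spots(
    frame: DetectorFrame,
    signal_mask: np.ndarray,
    min_pixels: int = 2,
    tile: int = 64,
) -> list[Spot]:
    """8-connected signal components with >= min_pixels pixels.

    Centroids are intensity-weighted on background-subtracted counts; total
    intensity is the background-subtracted sum; d-spacing comes from the
    centroid radius through the detector geometry.
    """
    if signal_mask.shape != frame.counts.shape:
        raise InputError("signal mask shape does not match frame")
    labels, n_components = ndimage.label(signal_mask, structure=_EIGHT_CONNECTED)
    if n_components == 0:
        return []
    med, sig = estimate_background(frame, tile)
    net = np.maximum(frame.counts - med, 0.0)
    spots: list[Spot] = []
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n_components + 1)):
        comp = labels[obj_slice] == lab
        n_pix = int(comp.sum())
        if n_pix < min_pixels:
            continue
        w = net[obj_slice] * comp
        total = float(w.sum())
        if total <= 0:
            continue
        s_idx, f_idx = np.nonzero(comp)
        s0, f0 = obj_slice[0].start, obj_slice[1].start
        cs = float(((s_idx + s0) * w[s_idx, f_idx]).sum() / total)
        cf = float(((f_idx + f0) * w[s_idx, f_idx]).sum() / total)
        peak_flat = int(np.argmax(w))
        ps, pf = np.unravel_index(peak_flat, w.shape)
        sigma_local = float(sig[s0 + ps, f0 + pf])
        peak = float(w.max())
        spots.append(
            Spot(
                centroid=(cs, cf),
                n_pixels=n_pix,
                total_intensity=total,
                peak_height=peak,
                d_spacing=float(frame.geometry.d_spacing(cs, cf)),
                bbox=(s0, obj_slice[0].stop, f0, obj_slice[1].stop),
                peak_snr=peak / sigma_local if sigma_local > 0 else float("inf"),
            )
        )
    return spots


# --------------------------------------------------------------------------
# Ring detection and spot filtering
# --------------------------------------------------------------------------

def detect_rings(
    frame: DetectorFrame,
    signal_mask: np.ndarray,
    shell_width: float = 0.002,
    occupancy_cut: float = 0.25,
    min_shell_pixels: int = 50,
    seed_ice_rings: bool = False,
    ice_interval_halfwidth: float = 0.004,
) -> list[tuple[float, float]]:
    """Flag over-occupied d* shells as ring intervals.

    Signal-pixel occupancy (signal / active) is histogrammed in equal-width
    d* shells; shells above ``occupancy_cut`` are flagged and adjacent
    flagged shells merged into (d*_lo, d*_hi) intervals.  With
    ``seed_ice_rings`` the standard hexagonal-ice d-spacings pre-seed
    intervals regardless of occupancy.
    """
    if shell_width <= 0 or not 0 < occupancy_cut <= 1:
        raise InputError("shell_width must be > 0 and occupancy_cut in (0, 1]")
    ds_map = frame.geometry.d_star_map()
    active = frame.mask
    n_shells = int(math.ceil(ds_map[active].max() / shell_width)) if active.any() else 0
    flagged = np.zeros(n_shells, dtype=bool)
    if n_shells:
        shell_idx = np.minimum((ds_map / shell_width).astype(int), n_shells - 1)
        n_active = np.bincount(shell_idx[active], minlength=n_shells)
        n_signal = np.bincount(shell_idx[active & signal_mask], minlength=n_shells)
        with np.errstate(invalid="ignore", divide="ignore"):
            occupancy = np.where(n_active >= min_shell_pixels, n_signal / np.maximum(n_active, 1), 0.0)
        flagged = occupancy > occupancy_cut
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < n_shells:
        if flagged[i]:
            j = i
            while j + 1 < n_shells and flagged[j + 1]:
                j += 1
            intervals.append((i * shell_width, (j + 1) * shell_width))
            i = j + 1
        else:
            i += 1
    if seed_ice_rings:
        for d in ICE_D_SPACINGS:
            intervals.append((1.0 / d - ice_interval_halfwidth, 1.0 / d + ice_interval_halfwidth))
        intervals = _merge_intervals(intervals)
    return intervals


def _merge_intervals(intervals):
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def filter_spots(
    spots: list[Spot],
    rings: list[tuple[float, float]],
    max_pixels: int = 400,
    peak_fraction_max: float = 0.95,
    elongation_max: float = 4.0,
    peak_snr_min: float = 7.0,
) -> tuple[list[Spot], dict[str, int]]:
    """Drop spots inside ring intervals or failing the quality heuristics.

    Heuristics: pixel-count cap, peak-to-total concentration bound (a single
    pixel must not carry more than ``peak_fraction_max`` of the intensity for
    multi-pixel spots), bounding-box elongation bound, and peak significance
    (peak height must reach ``peak_snr_min`` local background sigmas — pairs
    of adjacent noise excursions clear the per-pixel threshold far more often
    than they produce a strong maximum).
    Returns (kept, {"ring": n, "quality": n}).
    """
    kept: list[Spot] = []
    rejections = {"ring": 0, "quality": 0}
    for spot in spots:
        if any(lo <= spot.d_star <= hi for lo, hi in rings):
            rejections["ring"] += 1
            continue
        bad = (
            spot.n_pixels > max_pixels
            or spot.elongation > elongation_max
            or spot.peak_snr < peak_snr_min
            or (spot.n_pixels > 1 and spot.peak_height / spot.total_intensity > peak_fraction_max)
        )
        if bad:
            rejections["quality"] += 1
            continue
        kept.append(spot)
    return kept, rejections


# --------------------------------------------------------------------------
# Per-image report
# --------------------------------------------------------------------------

def signal_strength_report(
    frame: DetectorFrame, params: SpotfinderParams | None = None
) -> tuple[SpotStats, list[Spot]]:
    """Full pipeline: classify -> find -> rings -> filter -> statistics.

    The resolution limit is the ``resolution_percentile``-th percentile of
    accepted-spot d* values, reported in A (a stable convention: adding
    higher-resolution spots can only extend it).
    """
    p = params or SpotfinderParams()
    signal = classify_pixels(frame, n_sigma=p.n_sigma, tile=p.tile)
    spots = find_spots(frame, signal, min_pixels=p.min_pixels, tile=p.tile)
    rings = detect_rings(
        frame,
        signal,
        shell_width=p.ring_shell_width,
        occupancy_cut=p.ring_occupancy_cut,
        seed_ice_rings=p.seed_ice_rings,
    )
    kept, rejections = filter_spots(
        spots,
        rings,
        max_pixels=p.max_pixels,
        peak_fraction_max=p.peak_fraction_max,
        elongation_max=p.elongation_max,
        peak_snr_min=p.peak_snr_min,
    )
    if kept:
        ds80 = float(np.percentile([s.d_star for s in kept], p.resolution_percentile))
        res_limit = 1.0 / ds80
    else:
        res_limit = None
    stats = SpotStats(
        n_spots=len(kept),
        total_intensity=float(sum(s.total_intensity for s in kept)),
        resolution_limit=res_limit,
        n_ring_rejected=rejections["ring"],
        n_quality_rejected=rejections["quality"],
    )
    return stats, kept


_REPORT_FIELDS = (
    ("Spot Total", lambda s: str(s.n_spots)),
    ("Ring Rejected", lambda s: str(s.n_ring_rejected)),
    ("Quality Rejected", lambda s: str(s.n_quality_rejected)),
    ("Total Intensity", lambda s: f"{s.total_intensity:.1f}"),
    ("Resolution Limit", lambda s: "none" if s.resolution_limit is None else f"{s.resolution_limit:.2f}"),
)


def format_report(stats: SpotStats) -> str:
    """Stable key : value text report (byte-identical for identical stats)."""
    return "\n".join(f"{key} : {fmt(stats)}" for key, fmt in _REPORT_FIELDS) + "\n"


def format_report_xml(stats: SpotStats) -> str:
    """Same fields as the text report, as XML elements."""
    from xml.etree import ElementTree as ET

    root = ET.Element("spotfinder")
    for key, fmt in _REPORT_FIELDS:
        el = ET.SubElement(root, key.lower().replace(" ", "_"))
        el.text = fmt(stats)
    return ET.tostring(root, encoding="unicode") + "\n"


# --------------------------------------------------------------------------
# Two-lattice overlap classification
# --------------------------------------------------------------------------

def classify_lattice_overlap(
    spots_a: np.ndarray,
    spots_b: np.ndarray,
    box: float,
) -> tuple[list[tuple[int, int, float, str]], dict[str, int]]:
    """Label cross-lattice centroid pairs against an integration-box size.

    A pair at centre distance d is "overlapping" when d <= box (the two
    peaks fall inside each other's integration box), "close" when
    box < d <= 2*box (one box impinges on the other), else "separated".
    Returns the pairs within 2*box as (i, j, distance, label) plus counts
    over all cross-lattice pairs.
    """
    if box <= 0:
        raise InputError("integration box size must be positive")
    a = np.atleast_2d(np.asarray(spots_a, dtype=float))
    b = np.atleast_2d(np.asarray(spots_b, dtype=float))
    counts = {"separated": 0, "close": 0, "overlapping": 0}
    pairs: list[tuple[int, int, float, str]] = []
    if a.size == 0 or b.size == 0:
        return pairs, counts
    tree = cKDTree(b)
    for i, pt in enumerate(a):
        for j in tree.query_ball_point(pt, 2.0 * box):
            dist = float(np.linalg.norm(pt - b[j]))
            label = "overlapping" if dist <= box else "close"
            pairs.append((i, int(j), dist, label))
            counts[label] += 1
    counts["separated"] = len(a) * len(b) - counts["close"] - counts["overlapping"]
    return pairs, counts
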