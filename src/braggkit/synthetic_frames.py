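"""Seeded generator of synthetic detector frames and frame streams.

These frames stand in for pixel-array-detector stills: a Poisson
background, planted pixel-integrated Gaussian spots, optional azimuthal
powder/ice rings, inactive (masked) regions and a saturation cap.  Every
frame carries its ground truth (planted spot centres and intensities, ring
d* intervals, per-frame hit label), which makes precision/recall of the
spotfinder and the hit-rate pipeline exactly checkable.

Determinism: one random generator per FrameSpec, seeded once; draws happen
in a fixed documented order (single Poisson draw over the summed expectation
map), so identical seeds give byte-identical frames on any platform.

The SMV (ADSC-style) reader/writer provides one concrete on-disk format:
a 512-byte ASCII header followed by little-endian unsigned 16-bit counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import FormatError, InputError, SaturationError, SpecificationError
from .spotfinder import DetectorFrame, DetectorGeometry

__all__ = [
    "FrameSpec",
    "GroundTruth",
    "StreamFrame",
    "default_geometry",
    "generate_frame",
    "place_spot_centers",
    "framespec_to_json",
    "framespec_from_json",
    "generate_stream",
    "sample_two_lattice_positions",
    "write_smv",
    "read_smv",
]


def default_geometry(
    image_size: tuple[int, int] = (256, 256),
    distance: float = 100.0,
    wavelength: float = 1.0,
    pixel_size: float = 0.1,
) -> DetectorGeometry:
    """Small PAD-like geometry used throughout the test bed."""
    ns, nf = image_size
    return DetectorGeometry(
        distance=distance,
        wavelength=wavelength,
        beam_center=((nf / 2) * pixel_size, (ns / 2) * pixel_size),
        pixel_size=pixel_size,
        image_size=image_size,
    )


@dataclass
class FrameSpec:
    """Everything needed to synthesize one frame deterministically."""

    geometry: DetectorGeometry
    background_mean: float = 10.0
    spots: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)
    # each spot: ((slow, fast) centre px, integrated intensity ADU, gaussian sigma px)
    rings: list[tuple[float, float, float]] = field(default_factory=list)
    # each ring: (d-spacing A, peak amplitude ADU, radial sigma px)
    masked_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # rectangles (slow0, slow1, fast0, fast1), half-open
    saturation: int = 65535
    seed: int = 0

    def __post_init__(self):
        if self.background_mean < 0:
            raise SpecificationError("background_mean must be >= 0")
        if self.saturation <= self.background_mean:
            raise SpecificationError("saturation must exceed background_mean")
        ns, nf = self.geometry.image_size
        for (cs, cf), intensity, sigma in self.spots:
            if sigma <= 0:
                raise SpecificationError("spot sigma must be positive")
            if intensity < 0:
                raise SpecificationError("spot intensity must be non-negative")
            if not (0 <= cs < ns and 0 <= cf < nf):
                raise SpecificationError(
                    f"spot centre ({cs}, {cf}) outside image {self.geometry.image_size}"
                )


@dataclass
class GroundTruth:
    """What was planted in a frame."""

    spot_centers: list[tuple[float, float]]
    spot_intensities: list[float]
    ring_intervals: list[tuple[float, float]]   # d* intervals, A^-1
    n_spots: int

    def is_hit(self, threshold: int) -> bool:
        return self.n_spots >= threshold


def _integrated_gaussian(center: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """Integral of a unit-area 1D Gaussian over pixels [i, i+1), i in [lo, hi)."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = 0.5 * (1.0 + erf((edges - center) / (sigma * math.sqrt(2.0))))
    return np.diff(cdf)


def generate_frame(spec: FrameSpec) -> tuple[DetectorFrame, GroundTruth]:
    """Render a frame: Poisson(background + spots + rings), clipped and masked.

    The expectation map is assembled first (background, pixel-integrated 2D
    Gaussian spots, azimuthal Gaussian ring profiles), then Poisson-sampled
    in a single draw, clipped at the saturation cap and zeroed on masked
    regions.  Identical seeds give identical frames.
    """
    geom = spec.geometry
    ns, nf = geom.image_size
    expected = np.full((ns, nf), float(spec.background_mean))

    for (cs, cf), intensity, sigma in spec.spots:
        half = int(math.ceil(6.0 * sigma)) + 1
        s_lo, s_hi = max(0, int(cs) - half), min(ns, int(cs) + half + 1)
        f_lo, f_hi = max(0, int(cf) - half), min(nf, int(cf) + half + 1)
        gs = _integrated_gaussian(cs + 0.5, sigma, s_lo, s_hi)
        gf = _integrated_gaussian(cf + 0.5, sigma, f_lo, f_hi)
        expected[s_lo:s_hi, f_lo:f_hi] += intensity * np.outer(gs, gf)

    ring_intervals: list[tuple[float, float]] = []
    if spec.rings:
        slow, fast = np.meshgrid(np.arange(ns), np.arange(nf), indexing="ij")
        r_px = geom.radius_mm(slow, fast) / geom.pixel_size
        for d, amplitude, width in spec.rings:
            theta = math.asin(geom.wavelength / (2.0 * d))
            r0 = geom.distance * math.tan(2.0 * theta) / geom.pixel_size
            expected += amplitude * np.exp(-0.5 * ((r_px - r0) / width) ** 2)
            r_lo, r_hi = r0 - 3.0 * width, r0 + 3.0 * width
            ds = []
            for r_edge in (max(r_lo, 0.5), r_hi):
                th = 0.5 * math.atan(r_edge * geom.pixel_size / geom.distance)
                ds.append(2.0 * math.sin(th) / geom.wavelength)
            ring_intervals.append((min(ds), max(ds)))

    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(np.int64)
    counts = np.minimum(counts, spec.saturation)

    mask = np.ones((ns, nf), dtype=bool)
    for s0, s1, f0, f1 in spec.masked_regions:
        mask[s0:s1, f0:f1] = False
    counts[~mask] = 0

    frame = DetectorFrame(counts=counts, geometry=geom, mask=mask)
    truth = GroundTruth(
        spot_centers=[c for c, _, _ in spec.spots],
        spot_intensities=[i for _, i, _ in spec.spots],
        ring_intervals=ring_intervals,
        n_spots=len(spec.spots),
    )
    return frame, truth


# --------------------------------------------------------------------------
# Spot placement and streams
# --------------------------------------------------------------------------

def place_spot_centers(
    rng: np.random.Generator,
    geometry: DetectorGeometry,
    n: int,
    min_separation: float,
    margin: int = 12,
) -> list[tuple[float, float]]:
    """Jittered-grid placement guaranteeing a minimum pairwise separation."""
    ns, nf = geometry.image_size
    cell = min_separation * 2.0
    g_s = int((ns - 2 * margin) // cell)
    g_f = int((nf - 2 * margin) // cell)
    if g_s * g_f < n:
        raise SpecificationError(
            f"cannot place {n} spots with separation {min_separation} on {geometry.image_size}"
        )
    slots = [(i, j) for i in range(g_s) for j in range(g_f)]
    chosen = rng.choice(len(slots), size=n, replace=False)
    jitter_max = (cell - min_separation) / 2.0
    centers = []
    for k in chosen:
        i, j = slots[k]
        cs = margin + (i + 0.5) * cell + rng.uniform(-jitter_max, jitter_max)
        cf = margin + (j + 0.5) * cell + rng.uniform(-jitter_max, jitter_max)
        centers.append((float(cs), float(cf)))
    return centers


@dataclass
class StreamFrame:
    """One stream entry: the spec plus its ground-truth label."""

    frame_id: int
    timestamp: float
    spec: FrameSpec
    n_spots: int
    is_hit: bool


def generate_stream(
    n_frames: int,
    hit_probability: float,
    spots_per_hit: int = 25,
    spots_per_miss: int = 5,
    rate_hz: float = 120.0,
    seed: int = 0,
    geometry: DetectorGeometry | None = None,
    spot_intensity: float = 600.0,
    spot_sigma: float = 1.5,
    background_mean: float = 10.0,
) -> list[StreamFrame]:
    """Bernoulli hit/miss stream at a fixed frame rate (timestamps i / rate_hz).

    Hits get ``spots_per_hit`` planted spots and misses ``spots_per_miss``;
    choosing these on either side of the monitoring threshold makes the
    ground-truth labels deterministic functions of the spot counts.
    """
    if not 0.0 <= hit_probability <= 1.0:
        raise InputError("hit_probability must be in [0, 1]")
    geom = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    frames: list[StreamFrame] = []
    for i in range(n_frames):
        is_hit = bool(rng.random() < hit_probability)
        n_spots = spots_per_hit if is_hit else spots_per_miss
        frame_seed = int(rng.integers(0, 2**31 - 1))
        centers = place_spot_centers(rng, geom, n_spots, min_separation=5.0 * spot_sigma)
        spec = FrameSpec(
            geometry=geom,
            background_mean=background_mean,
            spots=[(c, spot_intensity, spot_sigma) for c in centers],
            seed=frame_seed,
        )
        frames.append(
            StreamFrame(
                frame_id=i,
                timestamp=i / rate_hz,
                spec=spec,
                n_spots=n_spots,
                is_hit=is_hit,
            )
        )
    return frames


# --------------------------------------------------------------------------
# Two-lattice still diffraction
# --------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _lattice_spots(geometry, cell, orientation, d_min, tolerance):
    """Project one lattice's reflections onto the detector (still diffraction).

    Reflections whose excitation error | |q + s0| - 1/lambda | is below
    ``tolerance`` are considered recorded; q is the rotated reciprocal-lattice
    vector, the beam runs along +z and the detector sits at the crystal
    distance, normal to the beam.
    """
    from .crystal_model import UnitCell, d_star as _dstar
    from .direct_summation import enumerate_hkl

    hkl = enumerate_hkl(cell, d_min)
    bmat = np.linalg.inv(cell.orthogonalization_matrix()).T   # reciprocal basis, columns a* b* c*
    q = (orientation @ bmat @ hkl.T).T                        # (n, 3) A^-1
    k0 = 1.0 / geometry.wavelength
    s0 = np.array([0.0, 0.0, k0])
    kout = q + s0
    excitation = np.abs(np.linalg.norm(kout, axis=1) - k0)
    sel = (excitation < tolerance) & (kout[:, 2] > 0)
    kout = kout[sel]
    # intersect the outgoing ray with the detector plane z = distance
    scale = geometry.distance / kout[:, 2]
    x_mm = kout[:, 0] * scale + geometry.beam_center[0]
    y_mm = kout[:, 1] * scale + geometry.beam_center[1]
    fast = x_mm / geometry.pixel_size - 0.5
    slow = y_mm / geometry.pixel_size - 0.5
    ns, nf = geometry.image_size
    on = (slow >= 0) & (slow < ns) & (fast >= 0) & (fast < nf)
    return np.stack([slow[on], fast[on]], axis=-1)


def sample_two_lattice_positions(
    geometry: DetectorGeometry,
    cell_a,
    cell_b,
    orientations: tuple[np.ndarray, np.ndarray] | None = None,
    d_min: float = 3.0,
    seed: int = 0,
    tolerance: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted spot centroids (slow, fast px) for two crystals in one shot.

    With ``orientations`` omitted, two random orientations are drawn from the
    seed.  Identical cells and orientations give identical centroid lists.
    """
    if orientations is None:
        rng = np.random.default_rng(seed)
        orientations = tuple(
            _rotation_matrix(rng.normal(size=3), rng.uniform(0, 360)) for _ in range(2)
        )
    a = _lattice_spots(geometry, cell_a, orientations[0], d_min, tolerance)
    b = _lattice_spots(geometry, cell_b, orientations[1], d_min, tolerance)
    return a, b


# --------------------------------------------------------------------------
# SMV (ADSC-style) image I/O
# --------------------------------------------------------------------------

_SMV_HEADER_BYTES = 512
_SMV_REQUIRED = ("SIZE1", "SIZE2", "PIXEL_SIZE", "DISTANCE", "WAVELENGTH",
                 "BEAM_CENTER_X", "BEAM_CENTER_Y")


def write_smv(frame: DetectorFrame, path) -> None:
    """Write counts + geometry as SMV: 512-byte ASCII header, u16-LE payload.

    SIZE1 is the fast dimension (columns), SIZE2 the slow dimension (rows).
    Counts above 65535 raise SaturationError.
    """
    if frame.counts.max(initial=0) > 65535:
        raise SaturationError("counts exceed unsigned 16-bit range; cannot write SMV")
    ns, nf = frame.counts.shape
    g = frame.geometry
    header = (
        "{\n"
        f"HEADER_BYTES= {_SMV_HEADER_BYTES};\n"
        "DIM=2;\n"
        "BYTE_ORDER=little_endian;\n"
        "TYPE=unsigned_short;\n"
        f"SIZE1={nf};\n"
        f"SIZE2={ns};\n"
        f"PIXEL_SIZE={g.pixel_size:.6f};\n"
        f"DISTANCE={g.distance:.6f};\n"
        f"WAVELENGTH={g.wavelength:.6f};\n"
        f"BEAM_CENTER_X={g.beam_center[0]:.6f};\n"
        f"BEAM_CENTER_Y={g.beam_center[1]:.6f};\n"
        "}\n"
    ).encode("ascii")
    if len(header) > _SMV_HEADER_BYTES:
        raise FormatError("SMV header exceeds HEADER_BYTES")
    with open(path, "wb") as fh:
        fh.write(header.ljust(_SMV_HEADER_BYTES, b"\x00"))
        fh.write(frame.counts.astype("<u2").tobytes())


def read_smv(path) -> DetectorFrame:
    """Read an SMV file back into a DetectorFrame (all pixels active)."""
    with open(path, "rb") as fh:
        head = fh.read(_SMV_HEADER_BYTES)
        fields: dict[str, str] = {}
        for line in head.decode("ascii", errors="replace").splitlines():
            line = line.strip().rstrip(";")
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
        for key in _SMV_REQUIRED:
            if key not in fields:
                raise FormatError(f"SMV header missing required key {key}")
        header_bytes = int(fields.get("HEADER_BYTES", _SMV_HEADER_BYTES))
        fh.seek(header_bytes)
        nf, ns = int(fields["SIZE1"]), int(fields["SIZE2"])
        order = "<u2" if fields.get("BYTE_ORDER", "little_endian") == "little_endian" else ">u2"
        payload = np.frombuffer(fh.read(2 * ns * nf), dtype=order)
        if payload.size != ns * nf:
            raise FormatError("SMV payload truncated")
    geometry = DetectorGeometry(
        distance=float(fields["DISTANCE"]),
        wavelength=float(fields["WAVELENGTH"]),
        beam_center=(float(fields["BEAM_CENTER_X"]), float(fields["BEAM_CENTER_Y"])),
        pixel_size=float(fields["PIXEL_SIZE"]),
        image_size=(ns, nf),
    )
    return DetectorFrame(counts=payload.reshape(ns, nf).astype(np.int64), geometry=geometry)


# --------------------------------------------------------------------------
# JSON fixture I/O for FrameSpec
# --------------------------------------------------------------------------

def framespec_to_json(spec: FrameSpec) -> str:
    g = spec.geometry
    return json.dumps(
        {
            "geometry": {
                "distance": g.distance,
                "wavelength": g.wavelength,
                "beam_center": list(g.beam_center),
                "pixel_size": g.pixel_size,
                "image_size": list(g.image_size),
            },
            "background_mean": spec.background_mean,
            "spots": [[list(c), i, s] for c, i, s in spec.spots],
            "rings": [list(r) for r in spec.rings],
            "masked_regions": [list(m) for m in spec.masked_regions],
            "saturation": spec.saturation,
            "seed": spec.seed,
        },
        indent=1,
    )


def framespec_from_json(doc: str | dict) -> FrameSpec:
    data = json.loads(doc) if isinstance(doc, str) else doc
    try:
        g = data["geometry"]
        geometry = DetectorGeometry(
            distance=g["distance"],
            wavelength=g["wavelength"],
            beam_center=tuple(g["beam_center"]),
            pixel_size=g["pixel_size"],
            image_size=tuple(g["image_size"]),
        )
        return FrameSpec(
            geometry=geometry,
            background_mean=data.get("background_mean", 10.0),
            spots=[(tuple(c), i, s) for c, i, s in data.get("spots", [])],
            rings=[tuple(r) for r in data.get("rings", [])],
            masked_regions=[tuple(m) for m in data.get("masked_regions", [])],
            saturation=data.get("saturation", 65535),
            seed=data.get("seed", 0),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed frame spec JSON: {exc}") from exc
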