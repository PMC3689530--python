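"""Direct summation of structure factors over a finite crystallite.

The central quantity is

    F_H = sum_dU sum_S sum_n  w_n f_n(d*) exp(-2 pi^2 u_n d*^2)
                              exp(2 pi i H . (R_S x_n + T_S + dU))

with dU running over the unit-cell offsets of an N1 x N2 x N3 crystallite,
S over the space-group operators, and n over the asymmetric-unit scatterers.
Because the lattice phase separates, the sum over dU factorizes into a
per-axis geometric series (the Laue interference function); both the
explicit sum and the factorized form are provided and agree to rounding.

Direct summation is exact at fractional Miller indices, which is what makes
it suitable for simulating interference fringes from crystallites only a few
unit cells wide.  An FFT-based sampled-density reference is included purely
as an accuracy cross-check; it is an approximation, not the ground truth.

Precision: batches can be evaluated with 64-bit or 32-bit inner
accumulation.  The 32-bit path uses a fixed accumulation order (scatterers
innermost) with Kahan compensation so that results are independent of
chunking up to single-precision rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .crystal_model import (
    CrystalStructure,
    FormFactorCoefficients,
    UnitCell,
    d_star,
)
from .errors import (
    EmptyComparisonError,
    InputError,
    ResourceLimitError,
    UsageError,
)

__all__ = [
    "CrystalliteExtent",
    "ReflectionSet",
    "AmplitudeComparison",
    "sf_single_cell",
    "laue_interference",
    "sf_finite_crystal",
    "sf_batch",
    "enumerate_hkl",
    "fft_reference_sf",
    "compare_amplitudes",
]

EXPLICIT_CELL_CAP = 10**6          # max dU terms for method="explicit"
FFT_GRID_CAP = 512**3              # max grid points for the FFT reference


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrystalliteExtent:
    """Number of unit cells along each cell axis."""

    N1: int = 1
    N2: int = 1
    N3: int = 1

    def __post_init__(self):
        for n in (self.N1, self.N2, self.N3):
            if int(n) != n or n < 1:
                raise InputError("crystallite extents must be integers >= 1")

    @property
    def n_cells(self) -> int:
        return self.N1 * self.N2 * self.N3


@dataclass
class ReflectionSet:
    """Miller indices (possibly fractional) with complex structure factors."""

    indices: np.ndarray            # (n, 3) float
    f_values: np.ndarray           # (n,) complex
    precision_tag: str = "double"

    def __post_init__(self):
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=float))
        self.f_values = np.asarray(self.f_values)
        if len(self.indices) != len(self.f_values):
            raise InputError("indices and f_values must have equal length")

    def __len__(self) -> int:
        return len(self.f_values)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f_values)

    def write_tsv(self, path) -> None:
        """Plain-text columns: h k l Fabs phase_deg."""
        with open(path, "w") as fh:
            fh.write("h\tk\tl\tFabs\tphase\n")
            for (h, k, l), f in zip(self.indices, self.f_values):
                fh.write(
                    f"{h:.6g}\t{k:.6g}\t{l:.6g}\t{abs(f):.8e}\t{math.degrees(np.angle(f)):.6f}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "ReflectionSet":
        idx, fv = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("h\t"):
                raise InputError(f"not a reflection TSV: {path}")
            for line in fh:
                h, k, l, fabs, phase = line.split("\t")
                idx.append((float(h), float(k), float(l)))
                fv.append(float(fabs) * np.exp(1j * math.radians(float(phase))))
        return cls(np.array(idx), np.array(fv))


@dataclass(frozen=True)
class AmplitudeComparison:
    n_common: int
    mean_rel_err: float
    max_rel_err: float
    correlation: float


# --------------------------------------------------------------------------
# Core summation
# --------------------------------------------------------------------------

def _structure_arrays(structure: CrystalStructure):
    """Stack scatterer data into arrays (positions, occupancies, u_iso, ff table)."""
    pos = np.array([s.position for s in structure.scatterers])
    occ = np.array([s.occupancy for s in structure.scatterers])
    u = np.array([s.u_iso for s in structure.scatterers])
    ffs = [s.form_factor for s in structure.scatterers]
    return pos, occ, u, ffs


def _form_factor_matrix(ffs: list[FormFactorCoefficients], ds: np.ndarray) -> np.ndarray:
    """(n_hkl, n_atoms) matrix of f_n(d*), sharing work across identical coefficients."""
    out = np.empty((len(ds), len(ffs)))
    cache: dict[int, np.ndarray] = {}
    for j, ff in enumerate(ffs):
        key = id(ff)
        if key not in cache:
            cache[key] = np.asarray(ff.value(ds))
        out[:, j] = cache[key]
    return out


def sf_single_cell(structure: CrystalStructure, hkl) -> complex:
    """Structure factor of one unit cell at a single (fractional) Miller triple."""
    rs = sf_batch(structure, np.atleast_2d(np.asarray(hkl, dtype=float)))
    return complex(rs.f_values[0])


def _kahan_accumulate(total, comp, term):
    """One Kahan step on matching (complex) arrays; returns updated (total, comp)."""
    y = term - comp
    t = total + y
    comp = (t - total) - y
    return t, comp


def _batch_double(structure, hkl, chunk_size):
    pos, occ, u, ffs = _structure_arrays(structure)
    ds = d_star(structure.cell, hkl)
    fmat = _form_factor_matrix(ffs, ds)                       # (m, n)
    dw = np.exp(-2.0 * math.pi**2 * np.outer(ds**2, u))       # (m, n)
    coef = fmat * dw * occ[None, :]
    out = np.zeros(len(hkl), dtype=np.complex128)
    for op in structure.symops:
        xs = pos @ op.R.T + op.T                              # (n, 3)
        for j0 in range(0, coef.shape[1], chunk_size):
            sl = slice(j0, j0 + chunk_size)
            phase = np.exp(2j * math.pi * (hkl @ xs[sl].T))   # (m, chunk)
            out += np.einsum("mj,mj->m", coef[:, sl], phase)
    return out


def _batch_single(structure, hkl, chunk_size):
    # 32-bit inner arithmetic with Kahan-compensated accumulation,
    # scatterers innermost, so results are chunk-invariant to f32 rounding.
    pos, occ, u, ffs = _structure_arrays(structure)
    ds = d_star(structure.cell, hkl)
    fmat = _form_factor_matrix(ffs, ds)
    dw = np.exp(-2.0 * math.pi**2 * np.outer(ds**2, u))
    coef = (fmat * dw * occ[None, :]).astype(np.float32)
    hkl32 = hkl.astype(np.float32)
    out = np.zeros(len(hkl), dtype=np.complex64)
    comp = np.zeros(len(hkl), dtype=np.complex64)
    two_pi = np.float32(2.0 * math.pi)
    for op in structure.symops:
        xs = (pos @ op.R.T + op.T).astype(np.float32)
        for j0 in range(0, coef.shape[1], chunk_size):
            sl = slice(j0, j0 + chunk_size)
            arg = two_pi * (hkl32 @ xs[sl].T)
            terms = coef[:, sl] * (np.cos(arg) + np.complex64(1j) * np.sin(arg))
            for j in range(terms.shape[1]):
                out, comp = _kahan_accumulate(out, comp, terms[:, j])
    return out


def sf_batch(
    structure: CrystalStructure,
    hkl_list,
    extent: CrystalliteExtent | None = None,
    precision: str = "double",
    chunk_size: int = 64,
) -> ReflectionSet:
    """Structure factors for a batch of Miller triples, in input order.

    ``precision`` selects 64-bit ("double") or 32-bit ("single") inner
    accumulation; results are independent of ``chunk_size`` up to the chosen
    precision's rounding.  An ``extent`` multiplies each F by the Laue
    interference factor of the crystallite.
    """
    if precision not in ("single", "double"):
        raise UsageError(f"precision must be 'single' or 'double', got {precision!r}")
    hkl = np.atleast_2d(np.asarray(hkl_list, dtype=float))
    if hkl.size == 0:
        return ReflectionSet(np.empty((0, 3)), np.empty(0, dtype=complex), precision)
    if hkl.shape[1] != 3:
        raise InputError("hkl_list must be a sequence of Miller triples")
    if precision == "double":
        fv = _batch_double(structure, hkl, chunk_size)
    else:
        fv = _batch_single(structure, hkl, chunk_size)
    if extent is not None and extent.n_cells > 1:
        lat = laue_interference(extent, hkl)
        fv = fv * lat.astype(fv.dtype)
    return ReflectionSet(hkl, fv, precision)


# --------------------------------------------------------------------------
# Lattice (Laue) factor and finite crystals
# --------------------------------------------------------------------------

def _axis_sum(h: np.ndarray, n: int) -> np.ndarray:
    """sum_{u=0}^{n-1} exp(2 pi i h u), geometric-series closed form.

    Near-integer h (|sin(pi h)| < 1e-9) is the removable singularity; there
    the sum equals n * exp(i pi h (n-1)).
    """
    h = np.asarray(h, dtype=float)
    sin_pi_h = np.sin(math.pi * h)
    singular = np.abs(sin_pi_h) < 1e-9
    out = np.empty(h.shape, dtype=complex)
    hs = h[~singular]
    out[~singular] = (
        np.exp(1j * math.pi * hs * (n - 1)) * np.sin(math.pi * hs * n) / sin_pi_h[~singular]
    )
    hi = h[singular]
    out[singular] = n * np.exp(1j * math.pi * hi * (n - 1))
    return out


def laue_interference(extent: CrystalliteExtent, hkl):
    """Finite-lattice sum  prod_axis sum_u exp(2 pi i h u); |result| <= N1 N2 N3.

    Accepts one triple or an (m, 3) array.
    """
    h = np.asarray(hkl, dtype=float)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    out = (
        _axis_sum(h[:, 0], extent.N1)
        * _axis_sum(h[:, 1], extent.N2)
        * _axis_sum(h[:, 2], extent.N3)
    )
    return complex(out[0]) if scalar else out


def sf_finite_crystal(
    structure: CrystalStructure,
    extent: CrystalliteExtent,
    hkl,
    method: str = "factorized",
) -> complex:
    """Finite-crystallite structure factor at one (fractional) Miller triple.

    method="explicit" sums exp(2 pi i H . dU) * F_cell over every unit-cell
    offset dU; method="factorized" uses the separable geometric-series form.
    They agree to rounding; extent (1,1,1) reproduces the single-cell value
    exactly.
    """
    if method not in ("explicit", "factorized"):
        raise UsageError(f"method must be 'explicit' or 'factorized', got {method!r}")
    f_cell = sf_single_cell(structure, hkl)
    if extent.n_cells == 1:
        return f_cell
    h = np.asarray(hkl, dtype=float)
    if method == "factorized":
        return complex(laue_interference(extent, h)) * f_cell
    if extent.n_cells > EXPLICIT_CELL_CAP:
        raise ResourceLimitError(
            f"explicit summation over {extent.n_cells} cells exceeds the cap "
            f"({EXPLICIT_CELL_CAP}); use method='factorized'"
        )
    du = np.stack(
        np.meshgrid(
            np.arange(extent.N1), np.arange(extent.N2), np.arange(extent.N3), indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    lattice = np.exp(2j * math.pi * (du @ h)).sum()
    return complex(lattice) * f_cell


# --------------------------------------------------------------------------
# Reflection enumeration
# --------------------------------------------------------------------------

def enumerate_hkl(cell: UnitCell, d_min: float, friedel_unique: bool = False) -> np.ndarray:
    """All integer Miller triples with d >= d_min (origin excluded).

    With ``friedel_unique`` only one member of each (H, -H) pair is kept.
    """
    if d_min <= 0:
        raise InputError("d_min must be positive")
    smax = 1.0 / d_min
    # per-axis bounds: max |h_i| on the ellipsoid h G* h = smax^2 is smax * sqrt(G_ii)
    g = cell.metric_tensor()
    bounds = [int(math.floor(smax * math.sqrt(g[i, i]))) for i in range(3)]
    h, k, l = np.meshgrid(
        np.arange(-bounds[0], bounds[0] + 1),
        np.arange(-bounds[1], bounds[1] + 1),
        np.arange(-bounds[2], bounds[2] + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=-1).astype(float)
    ds = d_star(cell, hkl)
    keep = (ds > 0) & (ds <= smax)
    hkl = hkl[keep]
    if friedel_unique:
        first = (
            (hkl[:, 0] > 0)
            | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
            | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
        )
        hkl = hkl[first]
    return hkl


# --------------------------------------------------------------------------
# FFT-based reference
# --------------------------------------------------------------------------

def fft_reference_sf(
    structure: CrystalStructure,
    d_min: float,
    grid_factor: float = 3.0,
    b_extra: float | None = None,
) -> ReflectionSet:
    """Approximate integer-H structure factors by FFT of a sampled density.

    Each scatterer's sum-of-Gaussians density is placed on a real-space grid
    of spacing <= d_min / grid_factor.  The isotropic displacement is folded
    analytically into each Gaussian (b_i -> b_i + 8 pi^2 u_iso); the constant
    term c is carried as a Gaussian of width B = 8 pi^2 u_iso.  A fixed extra
    smearing B_extra (default 8 pi^2 (d_min/3)^2) keeps the density
    band-limited on the grid and is deconvolved exactly after the transform,
    so the residual error is pure grid aliasing and shrinks as grid_factor
    grows.

    Requires a P1 (or pre-expanded) structure.  This is a cross-check for the
    direct summation, not an exact method.
    """
    if d_min <= 0:
        raise InputError("d_min must be positive")
    if len(structure.symops) != 1:
        raise InputError("fft_reference_sf requires a P1 (expanded) structure")
    cell = structure.cell
    if b_extra is None:
        b_extra = 8.0 * math.pi**2 * (d_min / 3.0) ** 2

    spacing = d_min / grid_factor
    dims = [sp_fft.next_fast_len(max(4, math.ceil(L / spacing))) for L in (cell.a, cell.b, cell.c)]
    if dims[0] * dims[1] * dims[2] > FFT_GRID_CAP:
        raise ResourceLimitError(
            f"FFT grid {dims} exceeds the configured cap ({FFT_GRID_CAP} points)"
        )
    rho = np.zeros(dims)
    ortho = cell.orthogonalization_matrix()
    hkl = enumerate_hkl(cell, d_min)
    if not structure.scatterers:
        return ReflectionSet(hkl, np.zeros(len(hkl), dtype=complex))

    for sc in structure.scatterers:
        b_iso = 8.0 * math.pi**2 * sc.u_iso
        gaussians = [(a, b + b_iso + b_extra) for a, b in sc.form_factor.gaussians]
        if sc.form_factor.c:
            gaussians.append((sc.form_factor.c, b_iso + b_extra))
        # truncation radius: densest Gaussian falls to 1e-6 of its peak
        b_max = max(b for _, b in gaussians)
        sigma_max = math.sqrt(b_max / (8.0 * math.pi**2))
        r_cut = sigma_max * math.sqrt(2.0 * math.log(1e6))
        # local sub-grid around the atom, wrapped periodically
        centre = sc.position * dims
        half = [max(1, math.ceil(r_cut / (L / n))) for L, n in zip((cell.a, cell.b, cell.c), dims)]
        axes_idx = [np.arange(math.floor(c) - hw, math.floor(c) + hw + 1) for c, hw in zip(centre, half)]
        # actual (unwrapped) offsets: each periodic image enters once; the
        # mod-n index assignment below folds the window onto the cell grid
        fr = [idx / n - p for idx, n, p in zip(axes_idx, dims, sc.position)]
        fx, fy, fz = np.meshgrid(*fr, indexing="ij")
        dxyz = np.einsum("ij,jabc->iabc", ortho, np.stack([fx, fy, fz]))
        r2 = (dxyz**2).sum(axis=0)
        dens = np.zeros_like(r2)
        for a, b in gaussians:
            dens += a * (4.0 * math.pi / b) ** 1.5 * np.exp(-4.0 * math.pi**2 * r2 / b)
        dens *= sc.occupancy
        ix, iy, iz = (np.mod(idx, n) for idx, n in zip(axes_idx, dims))
        np.add.at(rho, np.ix_(ix, iy, iz), dens)

    f_grid = cell.volume * sp_fft.ifftn(rho)
    idx = np.mod(hkl.astype(int), dims)
    fv = f_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    # deconvolve the extra smearing
    s2 = (d_star(cell, hkl) / 2.0) ** 2
    fv = fv * np.exp(b_extra * s2)
    return ReflectionSet(hkl, fv)


# --------------------------------------------------------------------------
# Amplitude comparison
# --------------------------------------------------------------------------

def compare_amplitudes(
    a: ReflectionSet,
    b: ReflectionSet,
    floor_frac: float = 1e-8,
) -> AmplitudeComparison:
    """Relative amplitude discrepancy statistics between two reflection sets.

    Indices are matched exactly (rounded to 1e-9); reflections whose
    reference amplitude |F_a| falls below floor_frac * max|F_a| are excluded
    from the relative-error statistics to avoid division blow-ups on
    near-extinct reflections.
    """
    key = lambda arr: {tuple(np.round(ix, 9)): i for i, ix in enumerate(arr)}
    ka, kb = key(a.indices), key(b.indices)
    common = [(ia, kb[t]) for t, ia in ka.items() if t in kb]
    if not common:
        raise EmptyComparisonError("reflection sets share no Miller indices")
    ia, ib = map(np.array, zip(*common))
    fa = a.amplitudes[ia].astype(float)
    fb = b.amplitudes[ib].astype(float)
    floor = floor_frac * fa.max()
    sel = fa > floor
    if not sel.any():
        raise EmptyComparisonError("all common reflections fall below the amplitude floor")
    rel = np.abs(fa[sel] - fb[sel]) / fa[sel]
    corr = 1.0 if len(fa) < 2 else float(np.corrcoef(fa, fb)[0, 1])
    return AmplitudeComparison(
        n_common=len(fa),
        mean_rel_err=float(rel.mean()),
        max_rel_err=float(rel.max()),
        correlation=corr,
    )
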