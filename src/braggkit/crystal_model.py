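"""Crystallographic primitives: unit cells, space-group operators, scatterers.

Everything needed to evaluate the macromolecular structure factor by direct
summation lives here: unit-cell metrics (reciprocal spacing d*), a minimal
explicit space-group table, sum-of-Gaussians atomic form factors, the
isotropic Debye-Waller factor, and a minimal PDB reader/writer for
CRYST1/ATOM/HETATM records.

Conventions
-----------
* Fractional coordinates are reduced to [0, 1) on input.
* Isotropic displacement uses u_iso in A^2; the attenuation factor is
  exp(-2 pi^2 u_iso d*^2), equivalent to exp(-B s^2) with B = 8 pi^2 u_iso
  and s = sin(theta)/lambda = d*/2.
* The space-group table is deliberately minimal (P1, P21, C2, P212121, P63),
  each group stored as a literal operator list; a full symmetry engine is a
  non-goal.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .errors import (
    FormatError,
    InputError,
    InvalidCellError,
    UnknownElementError,
    UnsupportedSpaceGroupError,
)

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "FormFactorCoefficients",
    "Scatterer",
    "CrystalStructure",
    "FORM_FACTORS",
    "SPACE_GROUPS",
    "d_star",
    "form_factor_value",
    "debye_waller",
    "b_to_u_iso",
    "u_iso_to_b",
    "space_group_ops",
    "random_p1_structure",
    "parse_pdb_minimal",
    "write_pdb_minimal",
    "expand_to_p1",
    "structure_from_json",
    "structure_to_json",
]


# --------------------------------------------------------------------------
# Unit cell
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (A) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name} must be in (0, 180)")
        # positive-definite metric requires the parallelepiped volume factor
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 1e-12:
            raise InvalidCellError("degenerate cell: metric tensor not positive definite")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(v2)

    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix O mapping fractional -> orthogonal A coordinates.

        Standard PDB convention: a along x, b in the x-y plane.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix())

    def metric_tensor(self) -> np.ndarray:
        o = self.orthogonalization_matrix()
        return o.T @ o

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())


def d_star(cell: UnitCell, hkl) -> float:
    """Reciprocal-lattice spacing d* = 1/d in A^-1 for a (fractional) Miller triple.

    d*^2 = H^T G* H with G* the reciprocal metric tensor; accepts an (N, 3)
    array and returns an (N,) array in that case.
    """
    gstar = cell.reciprocal_metric_tensor()
    h = np.asarray(hkl, dtype=float)
    if h.ndim == 1:
        return float(math.sqrt(max(h @ gstar @ h, 0.0)))
    return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", h, gstar, h), 0.0))


# --------------------------------------------------------------------------
# Symmetry operations
# --------------------------------------------------------------------------

_XYZ_TERM = re.compile(r"([+-]?)(\d+(?:/\d+)?|\d*\.\d+)?\*?([xyz])?")


def _parse_xyz_component(expr: str) -> tuple[np.ndarray, Fraction]:
    row = np.zeros(3, dtype=int)
    trans = Fraction(0)
    expr = expr.replace(" ", "")
    pos = 0
    while pos < len(expr):
        m = _XYZ_TERM.match(expr, pos)
        if m is None or m.end() == pos:
            raise InputError(f"cannot parse symmetry term in {expr!r}")
        sign = -1 if m.group(1) == "-" else 1
        num, var = m.group(2), m.group(3)
        if var is not None:
            coef = sign * (int(Fraction(num)) if num else 1)
            row["xyz".index(var)] += coef
        elif num is not None:
            trans += sign * Fraction(num)
        pos = m.end()
    return row, trans


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operator: integer rotation R and rational translation T (mod 1)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=int).reshape(3, 3)
        T = np.mod(np.asarray(self.T, dtype=float).reshape(3), 1.0)
        det = round(float(np.linalg.det(R)))
        if det not in (-1, 1):
            raise InputError(f"rotation part has det {det}, expected +/-1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        """Build from a Jones-faithful triplet such as ``'-x,y+1/2,-z'``."""
        parts = triplet.split(",")
        if len(parts) != 3:
            raise InputError(f"symmetry triplet needs 3 components: {triplet!r}")
        rows, trans = zip(*(_parse_xyz_component(p) for p in parts))
        return cls(np.array(rows), np.array([float(t) for t in trans]))

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (no mod-1 reduction)."""
        return np.asarray(x, dtype=float) @ self.R.T + self.T

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.R, np.eye(3, dtype=int)) and np.allclose(self.T, 0.0))

    def triplet(self) -> str:
        out = []
        for i in range(3):
            s = ""
            for j, var in enumerate("xyz"):
                c = self.R[i, j]
                if c:
                    s += ("+" if c > 0 and s else "-" if c < 0 else "") + ("" if abs(c) == 1 else str(abs(c))) + var
            t = Fraction(self.T[i]).limit_denominator(12)
            if t:
                s += f"+{t}" if t > 0 else f"-{-t}"
            out.append(s or "0")
        return ",".join(out)


# Minimal explicit operator table.  Keys are canonical labels; lookup is
# whitespace/subscript tolerant (see _canonical_sg_label).
SPACE_GROUPS: dict[str, tuple[str, ...]] = {
    "P 1": ("x,y,z",),
    "P 21": ("x,y,z", "-x,y+1/2,-z"),
    "C 2": ("x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"),
    "P 21 21 21": (
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x,y+1/2,-z+1/2",
    ),
    "P 63": (
        "x,y,z",
        "-y,x-y,z",
        "-x+y,-x,z",
        "-x,-y,z+1/2",
        "y,-x+y,z+1/2",
        "x-y,x,z+1/2",
    ),
}

_SG_ALIASES = {
    "P1": "P 1",
    "P21": "P 21",
    "P1211": "P 21",
    "C2": "C 2",
    "C121": "C 2",
    "P212121": "P 21 21 21",
    "P63": "P 63",
}


def _canonical_sg_label(label: str) -> str:
    key = label.strip().replace(" ", "").upper()  # "P 1 21 1" -> "P1211"
    if key in _SG_ALIASES:
        return _SG_ALIASES[key]
    raise UnsupportedSpaceGroupError(
        f"space group {label!r} is not in the built-in table; "
        f"supported: {sorted(SPACE_GROUPS)}"
    )


def space_group_ops(label: str) -> list[SymmetryOp]:
    """Operators for one of the built-in space groups.

    Raises UnsupportedSpaceGroupError (listing the supported labels) for any
    other label.
    """
    canonical = _canonical_sg_label(label)
    return [SymmetryOp.from_xyz(t) for t in SPACE_GROUPS[canonical]]


# --------------------------------------------------------------------------
# Form factors and displacement
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FormFactorCoefficients:
    """Sum-of-Gaussians form factor f(s) = sum a_i exp(-b_i s^2) + c, s = d*/2."""

    gaussians: tuple[tuple[float, float], ...]
    c: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "gaussians", tuple((float(a), float(b)) for a, b in self.gaussians))

    def value(self, d_star_val) -> float | np.ndarray:
        return form_factor_value(self, d_star_val)

    @property
    def f0(self) -> float:
        return sum(a for a, _ in self.gaussians) + self.c


# 4-Gaussian + constant coefficients from the standard international tables
# (the same parametrization used by every macromolecular SF program).
FORM_FACTORS: dict[str, FormFactorCoefficients] = {
    "H": FormFactorCoefficients(
        ((0.493002, 10.5109), (0.322912, 26.1257), (0.140191, 3.14236), (0.040810, 57.7997)),
        0.003038,
    ),
    "C": FormFactorCoefficients(
        ((2.31000, 20.8439), (1.02000, 10.2075), (1.58860, 0.568700), (0.865000, 51.6512)),
        0.215600,
    ),
    "N": FormFactorCoefficients(
        ((12.2126, 0.005700), (3.13220, 9.89330), (2.01250, 28.9975), (1.16630, 0.582600)),
        -11.529,
    ),
    "O": FormFactorCoefficients(
        ((3.04850, 13.2771), (2.28680, 5.70110), (1.54630, 0.323900), (0.867000, 32.9089)),
        0.250800,
    ),
    "P": FormFactorCoefficients(
        ((6.43450, 1.90670), (4.17910, 27.1570), (1.78000, 0.526000), (1.49080, 68.1645)),
        1.11490,
    ),
    "S": FormFactorCoefficients(
        ((6.90530, 1.46790), (5.20340, 22.2151), (1.43790, 0.253600), (1.58630, 56.1720)),
        0.866900,
    ),
    "FE": FormFactorCoefficients(
        ((11.7695, 4.76110), (7.35730, 0.307200), (3.52220, 15.3535), (2.30450, 76.8805)),
        1.03690,
    ),
}


def form_factor_value(coeffs: FormFactorCoefficients, d_star_val) -> float | np.ndarray:
    """Evaluate f(s) = sum a_i exp(-b_i s^2) + c at s = d*/2."""
    ds = np.asarray(d_star_val, dtype=float)
    if np.any(ds < 0):
        raise InputError("d* must be non-negative")
    s2 = (ds / 2.0) ** 2
    out = np.full_like(s2, coeffs.c, dtype=float)
    for a, b in coeffs.gaussians:
        out += a * np.exp(-b * s2)
    return float(out) if np.isscalar(d_star_val) or ds.ndim == 0 else out


def debye_waller(u_iso: float, d_star_val) -> float | np.ndarray:
    """Isotropic displacement attenuation exp(-2 pi^2 u_iso d*^2), in (0, 1]."""
    if u_iso < 0:
        raise InputError("u_iso must be non-negative")
    ds = np.asarray(d_star_val, dtype=float)
    if np.any(ds < 0):
        raise InputError("d* must be non-negative")
    out = np.exp(-2.0 * math.pi**2 * u_iso * ds**2)
    return float(out) if np.isscalar(d_star_val) or ds.ndim == 0 else out


def b_to_u_iso(b_factor: float) -> float:
    """Convert a PDB B-factor (A^2) to u_iso = B / (8 pi^2)."""
    if b_factor < 0:
        raise InputError("B-factor must be non-negative")
    return b_factor / (8.0 * math.pi**2)


def u_iso_to_b(u_iso: float) -> float:
    if u_iso < 0:
        raise InputError("u_iso must be non-negative")
    return u_iso * 8.0 * math.pi**2


# --------------------------------------------------------------------------
# Scatterers and structures
# --------------------------------------------------------------------------

@dataclass
class Scatterer:
    """One atom of the asymmetric unit."""

    label: str
    element: str
    position: np.ndarray          # fractional, reduced to [0, 1)
    u_iso: float = 0.0            # A^2
    occupancy: float = 1.0
    form_factor: FormFactorCoefficients | None = None

    def __post_init__(self):
        self.position = np.mod(np.asarray(self.position, dtype=float).reshape(3), 1.0)
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(f"occupancy of {self.label!r} must be in [0, 1]")
        if self.u_iso < 0:
            raise InputError(f"u_iso of {self.label!r} must be non-negative")
        if self.form_factor is None:
            key = self.element.strip().upper()
            if key not in FORM_FACTORS:
                raise UnknownElementError(
                    f"no built-in form factor for element {self.element!r} (atom {self.label!r}); "
                    "supply FormFactorCoefficients explicitly"
                )
            self.form_factor = FORM_FACTORS[key]


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operators + asymmetric-unit scatterers."""

    cell: UnitCell
    symops: list[SymmetryOp]
    scatterers: list[Scatterer]
    space_group_label: str = "P 1"

    def __post_init__(self):
        if not self.symops:
            raise InputError("structure needs at least one symmetry operator")
        if not self.symops[0].is_identity:
            raise InputError("first symmetry operator must be the identity")

    @classmethod
    def p1(cls, cell: UnitCell, scatterers: list[Scatterer]) -> "CrystalStructure":
        return cls(cell, space_group_ops("P 1"), scatterers, "P 1")


def expand_to_p1(structure: CrystalStructure) -> CrystalStructure:
    """Apply every operator to every scatterer; return the P1 equivalent.

    Special positions are not merged: the output has exactly
    len(scatterers) * len(symops) atoms, positions reduced mod 1.
    """
    expanded: list[Scatterer] = []
    for op in structure.symops:
        for sc in structure.scatterers:
            expanded.append(
                Scatterer(
                    label=sc.label,
                    element=sc.element,
                    position=np.mod(op.apply(sc.position), 1.0),
                    u_iso=sc.u_iso,
                    occupancy=sc.occupancy,
                    form_factor=sc.form_factor,
                )
            )
    return CrystalStructure(structure.cell, space_group_ops("P 1"), expanded, "P 1")


def random_p1_structure(
    n_atoms: int = 500,
    cell: UnitCell | None = None,
    elements: tuple[str, ...] = ("C", "N", "O", "S"),
    u_range: tuple[float, float] = (0.02, 0.05),
    seed: int = 20130618,
) -> CrystalStructure:
    """Seeded random P1 structure: uniform positions, full occupancy.

    The default configuration (500 atoms, 40 x 50 x 60 A orthorhombic cell,
    protein-like elements, u_iso in [0.02, 0.05] A^2) is the benchmark
    structure used for precision and FFT cross-checks.
    """
    rng = np.random.default_rng(seed)
    cell = cell or UnitCell(40.0, 50.0, 60.0)
    els = rng.choice(list(elements), size=n_atoms)
    scatterers = [
        Scatterer(
            label=f"{el}{i}",
            element=str(el),
            position=rng.random(3),
            u_iso=float(rng.uniform(*u_range)),
            occupancy=1.0,
        )
        for i, el in enumerate(els)
    ]
    return CrystalStructure.p1(cell, scatterers)


# --------------------------------------------------------------------------
# Minimal PDB I/O
# --------------------------------------------------------------------------

def parse_pdb_minimal(text: str) -> CrystalStructure:
    """Read CRYST1 + ATOM/HETATM records into a CrystalStructure.

    Orthogonal A coordinates are fractionalized with the standard PDB
    orthogonalization convention; occupancy and B-factor columns map to
    w_n and u_iso = B/(8 pi^2).  The element is taken from columns 77-78,
    falling back to the first letter of the atom name.
    """
    cell = None
    sg_label = "P 1"
    records = []
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                cell = UnitCell(
                    float(line[6:15]), float(line[15:24]), float(line[24:33]),
                    float(line[33:40]), float(line[40:47]), float(line[47:54]),
                )
            except ValueError as exc:
                raise FormatError(f"malformed CRYST1 record: {line!r}") from exc
            sg_label = line[55:66].strip() or "P 1"
        elif rec in ("ATOM", "HETATM"):
            records.append(line)
    if cell is None:
        raise FormatError("PDB text has no CRYST1 record")
    if not records:
        raise FormatError("PDB text has no ATOM/HETATM records")

    symops = space_group_ops(sg_label)
    frac = cell.fractionalization_matrix()
    scatterers = []
    for line in records:
        name = line[12:16].strip()
        try:
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        except ValueError as exc:
            raise FormatError(f"malformed coordinate record: {line!r}") from exc
        element = line[76:78].strip() if len(line) >= 78 and line[76:78].strip() else name[:1]
        scatterers.append(
            Scatterer(
                label=name or element,
                element=element,
                position=frac @ xyz,
                u_iso=b_to_u_iso(bfac),
                occupancy=occ,
            )
        )
    return CrystalStructure(cell, symops, scatterers, _canonical_sg_label(sg_label))


def write_pdb_minimal(structure: CrystalStructure) -> str:
    """Write CRYST1 + ATOM records (synthetic-fixture writer; P1 column precision)."""
    cell = structure.cell
    lines = [
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {structure.space_group_label:<11s}"
    ]
    ortho = cell.orthogonalization_matrix()
    for i, sc in enumerate(structure.scatterers, start=1):
        x, y, z = ortho @ sc.position
        el = sc.element.strip().upper()
        name = sc.label[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} UNK A{(i % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{sc.occupancy:6.2f}{u_iso_to_b(sc.u_iso):6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# JSON fixture format
# --------------------------------------------------------------------------

def structure_from_json(doc: str | dict) -> CrystalStructure:
    """Native fixture format: {cell, space_group, scatterers:[{element,x,y,z,occ,u_iso}]}."""
    data = json.loads(doc) if isinstance(doc, str) else doc
    try:
        cell = UnitCell(*[float(v) for v in data["cell"]])
        sg = data.get("space_group", "P 1")
        scatterers = [
            Scatterer(
                label=s.get("label", s["element"]),
                element=s["element"],
                position=np.array([s["x"], s["y"], s["z"]], dtype=float),
                u_iso=float(s.get("u_iso", 0.0)),
                occupancy=float(s.get("occ", 1.0)),
            )
            for s in data["scatterers"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed structure JSON: missing {exc}") from exc
    return CrystalStructure(cell, space_group_ops(sg), scatterers, _canonical_sg_label(sg))


def structure_to_json(structure: CrystalStructure) -> str:
    cell = structure.cell
    return json.dumps(
        {
            "cell": [cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma],
            "space_group": structure.space_group_label,
            "scatterers": [
                {
                    "label": s.label,
                    "element": s.element,
                    "x": s.position[0],
                    "y": s.position[1],
                    "z": s.position[2],
                    "occ": s.occupancy,
                    "u_iso": s.u_iso,
                }
                for s in structure.scatterers
            ],
        },
        indent=1,
    )
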