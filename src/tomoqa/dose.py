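"""Dose-distribution containers, detector geometry, file I/O and measurement-side corrections.

Conventions
-----------
* All doses are in Gy internally; percent doses exist only inside the gamma
  computation.
* Coordinates are millimetres, continuous, axis-aligned; the grid origin is
  the position of the first sample.  Axis order is ``(y, x)`` for 2D grids
  and ``(z, y, x)`` for 3D grids.
* Measured detector doses live on the *unwrapped* cylinder plane with
  coordinates ``(u, v)``: ``u`` is arc length along the circumference
  (angle 0 at top, increasing clockwise as seen from the gantry) and ``v``
  is the axial position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DoseGrid",
    "DosePointSet",
    "DetectorGeometry",
    "DoseIOError",
    "read_dose_grid",
    "write_dose_grid",
    "read_dose_points",
    "write_dose_points",
    "sample_detector",
    "apply_output_correction",
]

#: Grid step (mm) of the treatment planning system's high-resolution dose export.
DEFAULT_GRID_SPACING_MM = 1.87


class DoseIOError(RuntimeError):
    """Raised for unreadable dose files or missing/inconsistent metadata."""


@dataclass(frozen=True)
class DoseGrid:
    """Planned dose on a regular, axis-aligned grid.

    Parameters
    ----------
    values
        Dose array in Gy, 2D ``(y, x)`` or 3D ``(z, y, x)``.
    spacing_mm
        Per-axis grid step, same order as ``values`` axes.
    origin_mm
        Position of the first sample on each axis.
    """

    values: np.ndarray
    spacing_mm: tuple[float, ...]
    origin_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if values.ndim not in (2, 3):
            raise ValueError(f"dose grid must be 2D or 3D, got ndim={values.ndim}")
        if len(spacing) != values.ndim or len(origin) != values.ndim:
            raise ValueError("spacing_mm/origin_mm length must match grid dimensionality")
        if any(n < 2 for n in values.shape):
            raise ValueError("grid needs at least 2 samples per axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("grid spacing must be positive on every axis")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite")
        if values.min() < 0:
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Sample positions (mm) along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def extent_mm(self, axis: int) -> tuple[float, float]:
        """(min, max) coordinate covered along one axis."""
        c = self.axis_coords(axis)
        return float(c[0]), float(c[-1])

    def interpolator(self) -> RegularGridInterpolator:
        """Multilinear interpolator over the grid (coords in axis order)."""
        axes = [self.axis_coords(i) for i in range(self.ndim)]
        return RegularGridInterpolator(axes, self.values, method="linear", bounds_error=True)


@dataclass(frozen=True)
class DosePointSet:
    """Measured detector point doses on the unwrapped 2D plane."""

    u_mm: np.ndarray
    v_mm: np.ndarray
    dose_gy: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        u = np.asarray(self.u_mm, dtype=float).ravel()
        v = np.asarray(self.v_mm, dtype=float).ravel()
        d = np.asarray(self.dose_gy, dtype=float).ravel()
        if not (u.size == v.size == d.size):
            raise ValueError("u_mm, v_mm and dose_gy must have equal length")
        if u.size == 0:
            raise ValueError("point set must contain at least one point")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("point coordinates must be finite")
        if not np.all(np.isfinite(d)) or d.min() < 0:
            raise ValueError("doses must be finite and non-negative")
        object.__setattr__(self, "u_mm", u)
        object.__setattr__(self, "v_mm", v)
        object.__setattr__(self, "dose_gy", d)

    def __len__(self) -> int:
        return self.u_mm.size

    @property
    def points(self) -> np.ndarray:
        """``(n, 3)`` array of ``(u_mm, v_mm, dose_Gy)`` rows."""
        return np.column_stack([self.u_mm, self.v_mm, self.dose_gy])


@dataclass(frozen=True)
class DetectorGeometry:
    """Cylindrical diode-array layout (ArcCHECK-like defaults).

    The vendor does not publish an open geometry; these defaults describe a
    cylinder of radius 105 mm with diodes every 10 mm along the axis and
    around the circumference over a 210 mm axial extent.  All downstream
    computations are valid for any positive geometry.
    """

    cylinder_radius_mm: float = 105.0
    axial_spacing_mm: float = 10.0
    circumferential_spacing_mm: float = 10.0
    axial_extent_mm: float = 210.0

    def __post_init__(self) -> None:
        if self.cylinder_radius_mm <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.axial_spacing_mm <= 0 or self.circumferential_spacing_mm <= 0:
            raise ValueError("diode spacing must be positive")
        if self.axial_extent_mm <= 0:
            raise ValueError("axial extent must be positive")

    @property
    def circumference_mm(self) -> float:
        return 2.0 * np.pi * self.cylinder_radius_mm

    def diode_positions_unwrapped(self) -> tuple[np.ndarray, np.ndarray]:
        """Unwrapped diode lattice: flat ``(u, v)`` coordinate arrays.

        ``u`` runs over ``[0, circumference)`` in circumferential steps,
        ``v`` over ``[0, axial_extent]`` in axial steps.
        """
        n_u = int(np.floor(self.circumference_mm / self.circumferential_spacing_mm))
        u = self.circumferential_spacing_mm * np.arange(n_u)
        n_v = int(np.floor(self.axial_extent_mm / self.axial_spacing_mm)) + 1
        v = self.axial_spacing_mm * np.arange(n_v)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        return uu.ravel(), vv.ravel()


# ---------------------------------------------------------------------------
# File I/O
#
# csv-grid dialect (2D only):
#   # spacing_mm: <sy> <sx>
#   # origin_mm: <oy> <ox>
#   row-major comma-separated dose values, 6 significant digits.
# csv-points dialect:
#   header "u_mm,v_mm,dose_Gy", one point per line.
# ---------------------------------------------------------------------------


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a 2D grid in the csv-grid dialect (6 significant digits)."""
    if grid.ndim != 2:
        raise DoseIOError("csv-grid files store 2D grids only")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spacing_mm: {grid.spacing_mm[0]:.6g} {grid.spacing_mm[1]:.6g}\n")
        fh.write(f"# origin_mm: {grid.origin_mm[0]:.6g} {grid.origin_mm[1]:.6g}\n")
        for row in grid.values:
            fh.write(",".join(f"{x:.6g}" for x in row) + "\n")


def _read_csv_grid(path: Path) -> DoseGrid:
    spacing = origin = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line.lstrip("# ").partition(":")
                vals = rest.split()
                if key.strip() == "spacing_mm":
                    spacing = tuple(float(x) for x in vals)
                elif key.strip() == "origin_mm":
                    origin = tuple(float(x) for x in vals)
                continue
            rows.append([float(x) for x in line.split(",")])
    if spacing is None:
        raise DoseIOError(f"{path}: missing '# spacing_mm:' header")
    if origin is None:
        raise DoseIOError(f"{path}: missing '# origin_mm:' header")
    if not rows:
        raise DoseIOError(f"{path}: no dose values")
    return DoseGrid(np.asarray(rows), spacing, origin)


def _read_dicom_rtdose(path: Path) -> DoseGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pragma: no cover - exercised via error test
        raise DoseIOError(f"{path}: unreadable DICOM file ({exc})") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise DoseIOError(f"{path}: DICOM modality is {getattr(ds, 'Modality', 'missing')!r}, expected RTDOSE")
    try:
        scaling = float(ds.DoseGridScaling)
        pixel_spacing = [float(x) for x in ds.PixelSpacing]  # (row=y, col=x)
        ipp = [float(x) for x in ds.ImagePositionPatient]  # (x, y, z)
    except AttributeError as exc:
        raise DoseIOError(f"{path}: missing spacing/scaling metadata ({exc})") from exc
    values = ds.pixel_array.astype(float) * scaling
    if values.ndim == 3:
        offsets = np.asarray([float(x) for x in ds.GridFrameOffsetVector])
        dz = np.diff(offsets)
        if offsets.size != values.shape[0] or not np.allclose(dz, dz[0]):
            raise DoseIOError(f"{path}: non-uniform frame offsets are not supported")
        spacing = (float(dz[0]), pixel_spacing[0], pixel_spacing[1])
        origin = (ipp[2] + offsets[0], ipp[1], ipp[0])
    else:
        spacing = (pixel_spacing[0], pixel_spacing[1])
        origin = (ipp[1], ipp[0])
    return DoseGrid(values, spacing, origin)


def read_dose_grid(path: str | Path, format: str = "csv-grid") -> DoseGrid:
    """Read a planned dose grid.

    ``format`` is ``"csv-grid"`` (plain-text dialect above) or
    ``"dicom-rtdose"`` (standard RT Dose attributes; dose-grid scaling
    applied so values come back in Gy).
    """
    path = Path(path)
    if not path.exists():
        raise DoseIOError(f"{path}: file does not exist")
    if format == "csv-grid":
        return _read_csv_grid(path)
    if format == "dicom-rtdose":
        return _read_dicom_rtdose(path)
    raise ValueError(f"unknown dose grid format {format!r}")


def write_dose_points(points: DosePointSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("u_mm,v_mm,dose_Gy\n")
        for u, v, d in points.points:
            fh.write(f"{u:.6g},{v:.6g},{d:.6g}\n")


def read_dose_points(path: str | Path) -> DosePointSet:
    path = Path(path)
    if not path.exists():
        raise DoseIOError(f"{path}: file does not exist")
    with path.open() as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "u_mm,v_mm,dose_Gy":
            raise DoseIOError(f"{path}: expected header 'u_mm,v_mm,dose_Gy', got {header!r}")
        data = [list(map(float, line.strip().split(","))) for line in fh if line.strip()]
    if not data:
        raise DoseIOError(f"{path}: no points")
    arr = np.asarray(data)
    return DosePointSet(arr[:, 0], arr[:, 1], arr[:, 2])


# ---------------------------------------------------------------------------
# Detector sampling & corrections
# ---------------------------------------------------------------------------


def sample_detector(grid: DoseGrid, geometry: DetectorGeometry | None = None) -> DosePointSet:
    """Read the planned dose at every diode position.

    For a 2D grid the grid is taken to *be* the unwrapped detector plane
    with axes ``(v, u)``; diode ``(u, v)`` positions are placed from the
    grid origin and sampled bilinearly.  For a 3D grid the cylinder axis
    runs along ``z``, centred transversally and axially on the grid, and
    diode doses are obtained by trilinear interpolation; angle 0 is at the
    top of the cylinder, increasing clockwise viewed from the gantry.
    """
    geometry = geometry or DetectorGeometry()
    u, v = geometry.diode_positions_unwrapped()

    if grid.ndim == 2:
        # axes (y, x) = (v, u); place the diode lattice at the grid origin
        u = u + grid.origin_mm[1]
        v = v + grid.origin_mm[0]
        for axis_name, coord, axis in (("u", u, 1), ("v", v, 0)):
            lo, hi = grid.extent_mm(axis)
            if coord.min() < lo - 1e-9 or coord.max() > hi + 1e-9:
                raise ValueError(
                    f"detector extends beyond the grid along axis {axis_name!r}: "
                    f"[{coord.min():.2f}, {coord.max():.2f}] vs grid [{lo:.2f}, {hi:.2f}]"
                )
        doses = grid.interpolator()(np.column_stack([v, u]))
        return DosePointSet(u, v, doses, meta={"source": "sampled-2d"})

    # 3D: cylinder centred on the grid
    r = geometry.cylinder_radius_mm
    theta = u / r  # 0 at top, clockwise from gantry view
    zc = 0.5 * (grid.extent_mm(0)[0] + grid.extent_mm(0)[1])
    yc = 0.5 * (grid.extent_mm(1)[0] + grid.extent_mm(1)[1])
    xc = 0.5 * (grid.extent_mm(2)[0] + grid.extent_mm(2)[1])
    z = zc + (v - 0.5 * geometry.axial_extent_mm)
    y = yc + r * np.cos(theta)
    x = xc + r * np.sin(theta)
    for axis_name, coord, axis in (("z", z, 0), ("y", y, 1), ("x", x, 2)):
        lo, hi = grid.extent_mm(axis)
        if coord.min() < lo - 1e-9 or coord.max() > hi + 1e-9:
            raise ValueError(
                f"detector extends beyond the grid along axis {axis_name!r}: "
                f"[{coord.min():.2f}, {coord.max():.2f}] vs grid [{lo:.2f}, {hi:.2f}]"
            )
    doses = grid.interpolator()(np.column_stack([z, y, x]))
    return DosePointSet(u, v, doses, meta={"source": "sampled-3d"})


def apply_output_correction(points: DosePointSet, factor: float) -> DosePointSet:
    """Scale measured doses by the daily machine-output correction factor.

    The factor comes from an independent output check and is expected to sit
    close to 1; values outside ``(0.5, 1.5)`` almost certainly indicate a
    unit mistake and are rejected.
    """
    factor = float(factor)
    if not (0.5 < factor < 1.5):
        raise ValueError(f"output correction factor {factor} outside sanity bound (0.5, 1.5)")
    meta = dict(points.meta)
    meta["output_correction_factor"] = meta.get("output_correction_factor", 1.0) * factor
    return replace(points, dose_gy=points.dose_gy * factor, meta=meta)
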