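"""Volumes, masks, displacement fields and the differentiable sampler.

Conventions used throughout the package:

* Arrays are stored in ``(z, y, x)`` axis order; ``spacing`` and ``origin``
  follow the same order and are expressed in millimetres.
* Voxel centres sit at integer coordinates, 0-based.  A sampling grid stores,
  for every output voxel, the *continuous source coordinate* it reads from,
  with the last axis ordered ``(x, y)`` in 2-D mode and ``(x, y, z)`` in 3-D
  mode (``x`` = column/width index, ``y`` = row/height index).
* Samples outside the source extent contribute zero — the tent-kernel sum
  simply has no terms there; there is no reflection or clamping.
* Displacements are stored in voxel units and converted to mm via ``spacing``
  only when distances are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AblamarkError",
    "GeometryError",
    "ValidationError",
    "ConfigurationError",
    "VolumeIOError",
    "Volume",
    "Mask",
    "SamplingGrid",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "field_to_grid",
    "identity_grid",
    "bilinear_sample",
    "trilinear_sample",
    "sample_bilinear",
    "sample_trilinear",
]


class AblamarkError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(AblamarkError):
    """Shapes, spacings or grids that do not fit together."""


class ValidationError(AblamarkError):
    """Invalid values passed to an operation."""


class ConfigurationError(AblamarkError):
    """A configuration that cannot be honoured."""


class VolumeIOError(AblamarkError):
    """A file could not be read or written as a volume."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


def _as_tuple3(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.atleast_1d(v))
    if len(t) != 3:
        raise ValidationError(f"{name} must have 3 entries (z, y, x), got {t!r}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """A scalar 3-D image with anisotropic voxel spacing.

    ``data`` is ``(z, y, x)``; ``spacing`` is mm per voxel along the same
    axes; ``origin`` is the world-frame mm offset of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValidationError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing entries must be > 0, got {self.spacing}")
        self.origin = _as_tuple3(self.origin, "origin")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_geometry(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class Mask:
    """A binary segmentation sharing the :class:`Volume` geometry contract."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask values must be in {{0, 1}}, found {vals[:5]!r}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValidationError(f"mask data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing entries must be > 0, got {self.spacing}")
        self.origin = _as_tuple3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    same_geometry = Volume.same_geometry


@dataclass
class SamplingGrid:
    """Continuous source coordinates for every output voxel.

    ``points`` has shape ``out_shape + (2,)`` (last axis ``(x, y)``, one slab
    of points per z-slice) in 2-D mode, or ``out_shape + (3,)`` (last axis
    ``(x, y, z)``) in 3-D mode.  Coordinates may lie outside the source
    extent; the sampler assigns such samples zero weight.
    """

    points: np.ndarray
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.shape = tuple(int(s) for s in self.shape)
        if self.points.shape[:-1] != self.shape:
            raise GeometryError(
                f"grid points shape {self.points.shape[:-1]} does not match output shape {self.shape}"
            )
        if self.points.shape[-1] not in (2, 3):
            raise GeometryError("grid points must carry 2 or 3 coordinates per voxel")

    @property
    def ndim_mode(self) -> int:
        return self.points.shape[-1]


# ---------------------------------------------------------------------------
# Control-lattice displacement field
# ---------------------------------------------------------------------------


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic convolution (Catmull-Rom for a=-0.5) interpolation kernel."""
    at = np.abs(t)
    w = np.zeros_like(at)
    m1 = at <= 1.0
    m2 = (at > 1.0) & (at < 2.0)
    w[m1] = (a + 2.0) * at[m1] ** 3 - (a + 3.0) * at[m1] ** 2 + 1.0
    w[m2] = a * at[m2] ** 3 - 5.0 * a * at[m2] ** 2 + 8.0 * a * at[m2] - 4.0 * a
    return w


def n_control_points(n_voxels: int, spacing_vox: float) -> int:
    """Number of lattice points needed to cover ``[0, n_voxels - 1]``."""
    return int(np.ceil((n_voxels - 1) / spacing_vox)) + 1


def interp_matrix(positions: np.ndarray, spacing_vox: float, n_ctrl: int) -> np.ndarray:
    """Dense (len(positions) x n_ctrl) cubic interpolation weight matrix.

    The lattice sits at ``j * spacing_vox`` for ``j = 0..n_ctrl-1``; kernel
    support reaching past either end is folded onto the edge points
    (replication padding), which preserves partition of unity.
    """
    positions = np.asarray(positions, dtype=np.float64)
    j_ext = np.arange(-2, n_ctrl + 2)
    t = (positions[:, None] - j_ext[None, :] * spacing_vox) / spacing_vox
    w_ext = _keys_kernel(t)
    j_fold = np.clip(j_ext, 0, n_ctrl - 1)
    W = np.zeros((len(positions), n_ctrl))
    for col, j in enumerate(j_fold):
        W[:, j] += w_ext[:, col]
    return W


@dataclass
class DisplacementField:
    """Per-voxel non-rigid displacement parameterized by a coarse lattice.

    ``control_grid`` has shape ``(ncz, ncy, ncx, 3)`` with displacement
    components ordered ``(dz, dy, dx)`` in voxel units; lattice points are
    ``control_spacing`` voxels apart along each axis.  ``dense``, when
    present, caches the materialized per-voxel field with the same component
    order.  A field may also be dense-only (``control_grid=None``), e.g. an
    analytically known ground-truth field.
    """

    control_grid: np.ndarray | None
    control_spacing: tuple[float, float, float] = (2.0, 8.0, 8.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dense: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.control_grid is not None:
            self.control_grid = np.asarray(self.control_grid, dtype=np.float64)
            if self.control_grid.ndim != 4 or self.control_grid.shape[-1] != 3:
                raise GeometryError("control_grid must have shape (ncz, ncy, ncx, 3)")
        self.control_spacing = _as_tuple3(self.control_spacing, "control_spacing")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if self.dense is not None:
            self.dense = np.asarray(self.dense, dtype=np.float64)
            if self.dense.ndim != 4 or self.dense.shape[-1] != 3:
                raise GeometryError("dense field must have shape (Z, Y, X, 3)")
        if self.control_grid is None and self.dense is None:
            raise ValidationError("a field needs a control grid or a dense array")

    @classmethod
    def zeros_for_shape(
        cls,
        shape: tuple[int, int, int],
        control_spacing=(2.0, 8.0, 8.0),
        spacing=(1.0, 1.0, 1.0),
    ) -> "DisplacementField":
        cs = _as_tuple3(control_spacing, "control_spacing")
        nc = tuple(n_control_points(n, s) for n, s in zip(shape, cs))
        return cls(np.zeros(nc + (3,)), cs, spacing)

    def interp_matrices(self, shape: tuple[int, int, int]) -> list[np.ndarray]:
        if self.control_grid is None:
            raise GeometryError("field has no control grid to interpolate")
        mats = []
        for ax in range(3):
            extent = (self.control_grid.shape[ax] - 1) * self.control_spacing[ax]
            if shape[ax] - 1 > extent + 1e-9:
                raise GeometryError(
                    f"control grid ({self.control_grid.shape[:3]} at spacing "
                    f"{self.control_spacing}) does not cover shape {shape}"
                )
            mats.append(
                interp_matrix(
                    np.arange(shape[ax], dtype=np.float64),
                    self.control_spacing[ax],
                    self.control_grid.shape[ax],
                )
            )
        return mats

    def materialize(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Dense ``(Z, Y, X, 3)`` displacement, caching the result."""
        if self.dense is not None:
            if self.dense.shape[:3] != tuple(shape):
                raise GeometryError(
                    f"cached dense field shape {self.dense.shape[:3]} != requested {tuple(shape)}"
                )
            return self.dense
        Wz, Wy, Wx = self.interp_matrices(shape)
        self.dense = lattice_to_dense(self.control_grid, (Wz, Wy, Wx))
        return self.dense

    def mean_magnitude_mm(self, shape: tuple[int, int, int]) -> float:
        d = self.materialize(shape) * np.asarray(self.spacing)
        return float(np.mean(np.linalg.norm(d, axis=-1)))


def lattice_to_dense(control: np.ndarray, mats: tuple[np.ndarray, ...]) -> np.ndarray:
    """Tensor-product interpolation of a control lattice to a dense field."""
    Wz, Wy, Wx = mats
    out = np.tensordot(Wz, control, axes=(1, 0))        # (Z, ncy, ncx, 3)
    out = np.tensordot(Wy, out, axes=(1, 1))            # (Y, Z, ncx, 3)
    out = np.tensordot(Wx, out, axes=(1, 2))            # (X, Y, Z, 3)
    return np.ascontiguousarray(np.moveaxis(out, (0, 1, 2), (2, 1, 0)))


def dense_grad_to_lattice(dense_grad: np.ndarray, mats: tuple[np.ndarray, ...]) -> np.ndarray:
    """Adjoint of :func:`lattice_to_dense`: pull a dense gradient back to the lattice."""
    Wz, Wy, Wx = mats
    g = np.moveaxis(dense_grad, (0, 1, 2), (2, 1, 0))   # (X, Y, Z, 3)
    g = np.tensordot(Wx.T, g, axes=(1, 0))              # (ncx, Y, Z, 3)
    g = np.tensordot(Wy.T, g, axes=(1, 1))              # (ncy, ncx, Z, 3)
    g = np.tensordot(Wz.T, g, axes=(1, 2))              # (ncz, ncy, ncx, 3)
    return np.ascontiguousarray(g)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine_from(spacing, origin) -> np.ndarray:
    # our (z, y, x) metadata -> NIfTI (x, y, z) affine
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[0, 3], aff[1, 3], aff[2, 3] = origin[2], origin[1], origin[0]
    return aff


def _geometry_from(img) -> tuple[tuple, tuple]:
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin - np.diag(np.diag(lin)), 0.0, atol=1e-4):
        raise VolumeIOError(
            "only axis-aligned (diagonal) NIfTI affines are supported; "
            f"got linear part {lin.tolist()}"
        )
    d = np.diag(lin)
    spacing = (abs(float(d[2])), abs(float(d[1])), abs(float(d[0])))
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return spacing, origin


def _load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing, origin = _geometry_from(img)
    return np.ascontiguousarray(data.T.astype(np.float64)), spacing, origin


def read_volume(path) -> Volume:
    """Read a NIfTI-1 scalar volume into ``(z, y, x)`` order."""
    data, spacing, origin = _load_nifti(path)
    return Volume(data, spacing, origin)


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(
        np.asfortranarray(volume.data.T.astype(np.float32)),
        _affine_from(volume.spacing, volume.origin),
    )
    nib.save(img, str(path))


def write_field(field: DisplacementField, path, shape: tuple[int, int, int] | None = None) -> None:
    """Write a displacement field as a 4-D multi-component NIfTI (vox units)."""
    if shape is None:
        if field.dense is None:
            raise GeometryError("need a shape (or a materialized dense field) to write")
        shape = field.dense.shape[:3]
    dense = field.materialize(tuple(shape))
    img = nib.Nifti1Image(
        np.asfortranarray(np.transpose(dense, (2, 1, 0, 3)).astype(np.float32)),
        _affine_from(field.spacing, (0.0, 0.0, 0.0)),
    )
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    """Read a dense displacement field written by :func:`write_field`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeIOError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise VolumeIOError(f"{path}: expected a 4-D field with 3 components, got shape {data.shape}")
    spacing, _ = _geometry_from(img)
    dense = np.ascontiguousarray(np.transpose(data, (2, 1, 0, 3)).astype(np.float64))
    return DisplacementField(None, spacing=spacing, dense=dense)


def read_mask(path) -> Mask:
    data, spacing, origin = _load_nifti(path)
    binary = data > 0.5
    return Mask(binary.astype(np.uint8), spacing, origin)


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(
        np.asfortranarray(mask.data.T.astype(np.uint8)),
        _affine_from(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Grid generation
# ---------------------------------------------------------------------------


def identity_grid(shape: tuple[int, ...], mode: str = "3d") -> SamplingGrid:
    """The grid whose point for every voxel is its own coordinate."""
    shape = tuple(int(s) for s in shape)
    if mode == "3d":
        zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)
    elif mode == "2d":
        zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
        pts = np.stack([xx, yy], axis=-1)
    else:
        raise ConfigurationError(f"mode must be '2d' or '3d', got {mode!r}")
    return SamplingGrid(pts, shape)


def field_to_grid(field: DisplacementField, shape: tuple[int, int, int], mode: str = "3d") -> SamplingGrid:
    """Sampling grid = identity + (interpolated) displacement.

    A zero field yields the identity grid exactly.  In 2-D mode only the
    in-plane components are used (through-plane displacement must be zero).
    """
    shape = tuple(int(s) for s in shape)
    dense = field.materialize(shape)
    grid = identity_grid(shape, mode=mode)
    if mode == "3d":
        grid.points[..., 0] += dense[..., 2]
        grid.points[..., 1] += dense[..., 1]
        grid.points[..., 2] += dense[..., 0]
    else:
        if np.max(np.abs(dense[..., 0])) > 1e-9:
            raise GeometryError("2-D slicewise mode requires zero through-plane displacement")
        grid.points[..., 0] += dense[..., 2]
        grid.points[..., 1] += dense[..., 1]
    return grid


# ---------------------------------------------------------------------------
# Differentiable samplers
# ---------------------------------------------------------------------------


def sample_bilinear(U: np.ndarray, x: np.ndarray, y: np.ndarray, with_grad: bool = False):
    """Tent-kernel sampling of a 2-D array at continuous ``(x, y)`` points.

    ``V_i = sum_n sum_m U[n, m] * max(0, 1-|x_i-m|) * max(0, 1-|y_i-n|)``
    with out-of-range terms contributing zero.  With ``with_grad`` also
    returns ``dV/dx`` and ``dV/dy``.
    """
    U = np.asarray(U, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    H, W = U.shape
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx, fy = x - x0, y - y0
    V = np.zeros(np.broadcast(x, y).shape)
    dVx = np.zeros_like(V) if with_grad else None
    dVy = np.zeros_like(V) if with_grad else None
    for dy_c, dx_c in product((0, 1), repeat=2):
        xi, yi = x0 + dx_c, y0 + dy_c
        valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        Uc = np.where(valid, U[np.clip(yi, 0, H - 1), np.clip(xi, 0, W - 1)], 0.0)
        wx = fx if dx_c else 1.0 - fx
        wy = fy if dy_c else 1.0 - fy
        V += Uc * wx * wy
        if with_grad:
            sx = 1.0 if dx_c else -1.0
            sy = 1.0 if dy_c else -1.0
            dVx += Uc * sx * wy
            dVy += Uc * wx * sy
    if with_grad:
        return V, dVx, dVy
    return V


def sample_trilinear(U: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray, with_grad: bool = False):
    """Separable 3-axis tent-kernel sampling of a 3-D ``(z, y, x)`` array."""
    U = np.asarray(U, dtype=np.float64)
    Z, H, W = U.shape
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    z0 = np.floor(z).astype(np.int64)
    fx, fy, fz = x - x0, y - y0, z - z0
    out_shape = np.broadcast(x, y, z).shape
    V = np.zeros(out_shape)
    if with_grad:
        dVx = np.zeros(out_shape)
        dVy = np.zeros(out_shape)
        dVz = np.zeros(out_shape)
    for dz_c, dy_c, dx_c in product((0, 1), repeat=3):
        xi, yi, zi = x0 + dx_c, y0 + dy_c, z0 + dz_c
        valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H) & (zi >= 0) & (zi < Z)
        Uc = np.where(
            valid,
            U[np.clip(zi, 0, Z - 1), np.clip(yi, 0, H - 1), np.clip(xi, 0, W - 1)],
            0.0,
        )
        wx = fx if dx_c else 1.0 - fx
        wy = fy if dy_c else 1.0 - fy
        wz = fz if dz_c else 1.0 - fz
        V += Uc * wx * wy * wz
        if with_grad:
            dVx += Uc * (1.0 if dx_c else -1.0) * wy * wz
            dVy += Uc * wx * (1.0 if dy_c else -1.0) * wz
            dVz += Uc * wx * wy * (1.0 if dz_c else -1.0)
    if with_grad:
        return V, dVx, dVy, dVz
    return V


def _check_grid_for(source_shape: tuple[int, ...], grid: SamplingGrid, mode_dims: int) -> None:
    if grid.ndim_mode != mode_dims:
        raise GeometryError(
            f"grid carries {grid.ndim_mode} coordinates per voxel, expected {mode_dims}"
        )


def bilinear_sample(source, grid: SamplingGrid):
    """Slicewise 2-D tent-kernel resampling.

    ``source`` may be a :class:`Volume` (each z-slice resampled through the
    matching slab of grid points, which must carry ``(x, y)`` coordinates) or
    a bare 2-D array.  Returns the same kind as given.
    """
    if isinstance(source, Volume):
        _check_grid_for(source.shape, grid, 2)
        if grid.shape[0] != source.shape[0]:
            raise GeometryError(
                f"grid has {grid.shape[0]} slices but the volume has {source.shape[0]}"
            )
        out = np.empty(grid.shape)
        for k in range(source.shape[0]):
            out[k] = sample_bilinear(source.data[k], grid.points[k, ..., 0], grid.points[k, ..., 1])
        return Volume(out, source.spacing, source.origin)
    U = np.asarray(source, dtype=np.float64)
    if U.ndim != 2:
        raise GeometryError("bilinear_sample expects a Volume or a 2-D array")
    _check_grid_for(U.shape, grid, 2)
    return sample_bilinear(U, grid.points[..., 0], grid.points[..., 1])


def trilinear_sample(source: Volume, grid: SamplingGrid) -> Volume:
    """3-D tent-kernel resampling of a :class:`Volume` through a grid."""
    if not isinstance(source, Volume):
        source = Volume(np.asarray(source, dtype=np.float64))
    _check_grid_for(source.shape, grid, 3)
    out = sample_trilinear(
        source.data, grid.points[..., 0], grid.points[..., 1], grid.points[..., 2]
    )
    return Volume(out, source.spacing, source.origin)
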