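"""Unsupervised per-pair deformable registration (STS-net).

The registration couples two pieces:

* an ST-net — a Siamese localization network whose regression head predicts
  the non-rigid transformation parameters (a coarse control lattice of
  displacements), a grid generator and the differentiable tent-kernel
  sampler from :mod:`ablamark.imaging_core`;
* an S-net — a convolutional feature pyramid applied to the warped moving
  image and to the fixed (post-ablation) image, whose block-wise normalized
  cross-correlation is the similarity.  The negative sum of per-block
  cosine similarities is the loss that is backpropagated to the lattice.

Everything runs on the CPU in numpy with hand-written backward passes: the
convolution stack, ReLU, max-pooling, the block partition and the NCC loss
all expose exact adjoints, so the gradient of the loss with respect to the
control-lattice displacements is analytic (and is verified against finite
differences in the test-suite).

The S-net weights are fixed random (seeded) multiscale filters by default:
this keeps the per-pair optimization unsupervised, deterministic and
desk-scale, while still providing a contrast-insensitive similarity basis.
A config flag allows the filters to be adapted jointly with the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np

from .imaging_core import (
    ConfigurationError,
    DisplacementField,
    GeometryError,
    Mask,
    ValidationError,
    Volume,
    dense_grad_to_lattice,
    identity_grid,
    interp_matrix,
    lattice_to_dense,
    n_control_points,
    sample_bilinear,
    sample_trilinear,
)

__all__ = [
    "RegistrationConfig",
    "FeatureBlocks",
    "RegistrationResult",
    "LandmarkSet",
    "LandmarkError",
    "OptimizationDivergedError",
    "DegenerateFeatureError",
    "ConvFeaturePyramid",
    "siamese_localize",
    "extract_features",
    "block_ncc_loss",
    "register_pair",
    "landmark_error",
]


class OptimizationDivergedError(Exception):
    """The registration loss became non-finite."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"registration loss became non-finite at iteration {iteration}")


class DegenerateFeatureError(Exception):
    """A feature block has zero norm (constant region collapsed by the filters)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Settings for the per-pair optimization.

    mode
        ``"3d"`` (default; trilinear warping, used for margin work) or
        ``"2d"`` (slice-wise in-plane warping, matching thick-slice
        acquisitions where through-plane accuracy is limited anyway).
    control_spacing
        Lattice spacing in voxels, ``(z, y, x)``.
    feature_levels
        Number of conv + max-pool stages in the similarity pyramid.
    block_partition
        Regions per axis for the block-wise NCC, ``(z, y, x)`` in 3-D or
        ``(y, x)`` per slice in 2-D.  ``None`` picks 2x4x4 (3-D) or 4x4.
    inplane_downsample
        Working-resolution factor for the optimization: images are
        block-averaged in-plane by this factor while the field is always
        returned (and the warped image produced) at full resolution.  The
        through-plane axis is never downsampled.
    learning_rate
        Step size in (working) voxels per iteration; gradients are
        normalized by their largest component before stepping.
    smoothness_weight
        Weight of the bending-energy penalty on the lattice (mm^2 units);
        0 recovers the bare block-NCC objective.
    """

    mode: str = "3d"
    control_spacing: tuple[float, float, float] = (2.0, 8.0, 8.0)
    feature_levels: int = 5
    block_partition: tuple[int, ...] | None = None
    max_iters: int = 200
    tolerance: float = 1e-5
    learning_rate: float = 0.1
    seed: int = 0
    smoothness_weight: float = 0.1
    momentum: float = 0.9
    optimizer: str = "adam"  # "adam" (per-parameter scaling) or "momentum"
    patience: int = 8  # iterations the relative-change criterion must hold
    base_channels: int = 8
    block_pool: str = "flat"  # "flat" keeps per-block spatial layout, "mean" pools it away
    ncc_center: bool = True  # zero-mean (Pearson) block NCC during optimization
    drop_zero_blocks: bool = False
    normalize: bool = True
    train_features: bool = False
    feature_learning_rate: float = 1e-3
    inplane_downsample: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ConfigurationError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.feature_levels < 1:
            raise ConfigurationError("feature_levels must be >= 1")
        if self.smoothness_weight < 0:
            raise ConfigurationError("smoothness_weight must be >= 0")
        if self.block_pool not in ("flat", "mean"):
            raise ConfigurationError("block_pool must be 'flat' or 'mean'")
        if self.inplane_downsample < 1:
            raise ConfigurationError("inplane_downsample must be >= 1")
        if self.block_partition is not None:
            bp = tuple(int(b) for b in self.block_partition)
            if any(b < 1 for b in bp):
                raise ConfigurationError("block_partition entries must be >= 1")
            self.block_partition = bp

    def resolved_partition(self) -> tuple[int, ...]:
        if self.block_partition is not None:
            return self.block_partition
        return (2, 4, 4) if self.mode == "3d" else (4, 4)


# ---------------------------------------------------------------------------
# Convolutional feature pyramid with explicit adjoints
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """'Same' zero-padded convolution; x is (Cin, *spatial), W (Cout, Cin, 3..)."""
    nd = x.ndim - 1
    xp = np.pad(x, [(0, 0)] + [(1, 1)] * nd)
    out = np.zeros((W.shape[0],) + x.shape[1:])
    for off in product(range(3), repeat=nd):
        sl = tuple(slice(o, o + s) for o, s in zip(off, x.shape[1:]))
        out += np.tensordot(W[(slice(None), slice(None)) + off], xp[(slice(None),) + sl], axes=(1, 0))
    return out


def _conv_backward_input(g: np.ndarray, W: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    nd = len(in_shape) - 1
    gp_shape = (in_shape[0],) + tuple(s + 2 for s in in_shape[1:])
    xg = np.zeros(gp_shape)
    for off in product(range(3), repeat=nd):
        sl = tuple(slice(o, o + s) for o, s in zip(off, in_shape[1:]))
        xg[(slice(None),) + sl] += np.tensordot(
            W[(slice(None), slice(None)) + off], g, axes=(0, 0)
        )
    interior = (slice(None),) + tuple(slice(1, s + 1) for s in in_shape[1:])
    return xg[interior]


def _conv_backward_weights(g: np.ndarray, x: np.ndarray, k: int = 3) -> np.ndarray:
    nd = x.ndim - 1
    xp = np.pad(x, [(0, 0)] + [(1, 1)] * nd)
    Wg = np.zeros((g.shape[0], x.shape[0]) + (k,) * nd)
    sp_axes = tuple(range(1, nd + 1))
    for off in product(range(k), repeat=nd):
        sl = tuple(slice(o, o + s) for o, s in zip(off, x.shape[1:]))
        Wg[(slice(None), slice(None)) + off] = np.tensordot(
            g, xp[(slice(None),) + sl], axes=(sp_axes, sp_axes)
        )
    return Wg


def _pool_forward(x: np.ndarray):
    """Max-pool by 2 along every spatial axis (odd trailing voxels dropped)."""
    nd = x.ndim - 1
    sp = x.shape[1:]
    even = tuple((s // 2) * 2 for s in sp)
    xc = x[(slice(None),) + tuple(slice(0, e) for e in even)]
    newshape = (x.shape[0],) + tuple(v for e in even for v in (e // 2, 2))
    xr = xc.reshape(newshape)
    perm = [0] + [1 + 2 * i for i in range(nd)] + [2 + 2 * i for i in range(nd)]
    xt = xr.transpose(perm)
    flat = xt.reshape(xt.shape[: 1 + nd] + (-1,))
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, (idx, even, x.shape, perm)


def _pool_backward(g: np.ndarray, cache) -> np.ndarray:
    idx, even, xshape, perm = cache
    nd = len(xshape) - 1
    flat = np.zeros(g.shape + (2**nd,))
    np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
    xt = flat.reshape(g.shape + (2,) * nd)
    xr = xt.transpose(np.argsort(perm))
    xc = xr.reshape((xshape[0],) + even)
    xg = np.zeros(xshape)
    xg[(slice(None),) + tuple(slice(0, e) for e in even)] = xc
    return xg


class ConvFeaturePyramid:
    """Stack of seeded random 3x3(x3) conv filters with ReLU and max-pooling.

    Channel counts double from ``base_channels`` across levels.  The
    per-level post-activation maps are the multiscale features; pooling
    feeds each level into the next.
    """

    def __init__(self, ndim: int, levels: int, base_channels: int, seed: int):
        if ndim not in (2, 3):
            raise ConfigurationError("feature pyramid supports 2-D or 3-D inputs")
        rng = np.random.default_rng(seed)
        self.ndim = ndim
        self.levels = levels
        self.weights: list[np.ndarray] = []
        cin = 1
        for lvl in range(levels):
            cout = base_channels * 2**lvl
            fan_in = cin * 3**ndim
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin) + (3,) * ndim)
            self.weights.append(W)
            cin = cout

    def forward(self, img: np.ndarray):
        """Returns (per-level activation maps, cache for backward)."""
        if img.ndim != self.ndim:
            raise GeometryError(f"expected a {self.ndim}-D image, got {img.ndim}-D")
        if any(s < 2**self.levels for s in img.shape):
            raise ConfigurationError(
                f"image shape {img.shape} too small for {self.levels} pooling levels"
            )
        x = img[None]
        feats, cache = [], []
        for lvl, W in enumerate(self.weights):
            pre = _conv_forward(x, W)
            act = np.maximum(pre, 0.0)
            feats.append(act)
            if lvl < self.levels - 1:
                pooled, pc = _pool_forward(act)
            else:
                pooled, pc = None, None
            cache.append((x, pre > 0, pc))
            x = pooled
        return feats, cache

    def backward(self, dfeats: list[np.ndarray], cache, want_weight_grads: bool = False):
        """Backpropagate per-level activation grads to the input image."""
        dpooled = None
        wgrads = [None] * self.levels if want_weight_grads else None
        for lvl in reversed(range(self.levels)):
            x_in, relu_mask, pc = cache[lvl]
            dact = np.array(dfeats[lvl], dtype=np.float64, copy=True)
            if dpooled is not None:
                dact += _pool_backward(dpooled, pc)
            dpre = dact * relu_mask
            if want_weight_grads:
                wgrads[lvl] = _conv_backward_weights(dpre, x_in)
            dpooled = _conv_backward_input(dpre, self.weights[lvl], x_in.shape)
        dimg = dpooled[0]
        return (dimg, wgrads) if want_weight_grads else dimg


# ---------------------------------------------------------------------------
# Feature blocks and the block-NCC loss
# ---------------------------------------------------------------------------


@dataclass
class FeatureBlocks:
    """Per-region fused multiscale feature vectors.

    ``blocks`` holds one flattened feature vector per image region;
    ``region_geometry`` records how the image was partitioned (so paired
    extractions can be checked for compatibility).
    """

    blocks: list[np.ndarray]
    region_geometry: dict

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValidationError("FeatureBlocks needs at least one block")
        for i, b in enumerate(self.blocks):
            b = np.asarray(b, dtype=np.float64)
            if b.ndim != 1 or b.size == 0:
                raise ValidationError(f"block {i} must be a non-empty vector")
            if not np.all(np.isfinite(b)):
                raise ValidationError(f"block {i} contains non-finite values")
            self.blocks[i] = b

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _partition_edges(size: int, parts: int) -> list[tuple[int, int]]:
    if size < parts:
        raise ConfigurationError(f"cannot split {size} voxels into {parts} blocks")
    cuts = [round(i * size / parts) for i in range(parts + 1)]
    return [(cuts[i], cuts[i + 1]) for i in range(parts)]


def _block_slices(map_shape: tuple[int, ...], partition: tuple[int, ...]):
    """Cartesian product of per-axis partition slices, z-major order."""
    per_axis = [_partition_edges(s, p) for s, p in zip(map_shape, partition)]
    for combo in product(*per_axis):
        yield tuple(slice(a, b) for a, b in combo)


def _gather_blocks(feats: list[np.ndarray], partition: tuple[int, ...], pool: str) -> list[np.ndarray]:
    """Fuse the multiscale maps into one vector per region.

    Each level's map is partitioned proportionally; with ``pool="flat"`` the
    per-region slices are flattened and concatenated across levels (keeping
    the within-block spatial layout, which is what gives the loss a dense
    gradient), with ``pool="mean"`` each level contributes its per-channel
    block means only.
    """
    per_level_slices = [list(_block_slices(f.shape[1:], partition)) for f in feats]
    n = len(per_level_slices[0])
    blocks = []
    for i in range(n):
        pieces = []
        for lvl, f in enumerate(feats):
            region = f[(slice(None),) + per_level_slices[lvl][i]]
            if pool == "mean":
                pieces.append(region.mean(axis=tuple(range(1, region.ndim))))
            else:
                pieces.append(region.ravel())
        blocks.append(np.concatenate(pieces))
    return blocks


def _scatter_block_grads(
    dblocks: list[np.ndarray],
    feats: list[np.ndarray],
    partition: tuple[int, ...],
    pool: str,
) -> list[np.ndarray]:
    """Adjoint of :func:`_gather_blocks`."""
    per_level_slices = [list(_block_slices(f.shape[1:], partition)) for f in feats]
    dfeats = [np.zeros_like(f) for f in feats]
    for i, db in enumerate(dblocks):
        ofs = 0
        for lvl, f in enumerate(feats):
            sl = (slice(None),) + per_level_slices[lvl][i]
            region_shape = f[sl].shape
            if pool == "mean":
                c = region_shape[0]
                count = int(np.prod(region_shape[1:]))
                g = db[ofs : ofs + c] / count
                dfeats[lvl][sl] += g.reshape((c,) + (1,) * (len(region_shape) - 1))
                ofs += c
            else:
                cnt = int(np.prod(region_shape))
                dfeats[lvl][sl] += db[ofs : ofs + cnt].reshape(region_shape)
                ofs += cnt
    return dfeats


def _min_max_normalize(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1e-12:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def extract_features(image: Volume, config: RegistrationConfig) -> FeatureBlocks:
    """S-net features: block-partitioned multiscale conv features of a volume."""
    data = _min_max_normalize(image.data) if config.normalize else image.data
    partition = config.resolved_partition()
    if config.mode == "3d":
        net = ConvFeaturePyramid(3, config.feature_levels, config.base_channels, config.seed)
        feats, _ = net.forward(data)
        blocks = _gather_blocks(feats, partition, config.block_pool)
    else:
        net = ConvFeaturePyramid(2, config.feature_levels, config.base_channels, config.seed)
        blocks = []
        for k in range(data.shape[0]):
            feats, _ = net.forward(data[k])
            blocks.extend(_gather_blocks(feats, partition, config.block_pool))
    geometry = {
        "mode": config.mode,
        "partition": partition,
        "image_shape": image.shape,
        "levels": config.feature_levels,
        "pool": config.block_pool,
    }
    return FeatureBlocks(blocks, geometry)


def _ncc_terms(Fw: list[np.ndarray], Fa: list[np.ndarray], drop_zero: bool, center: bool = False):
    """Per-block NCC values, their grads w.r.t. Fw and Fa, and kept indices.

    With ``center`` the block vectors are mean-subtracted first (zero-mean
    NCC, i.e. a Pearson correlation per block); gradients are projected
    accordingly.
    """
    sims, grads_w, grads_a, kept = [], [], [], []
    for i, (w0, a0) in enumerate(zip(Fw, Fa)):
        w = w0 - w0.mean() if center else w0
        a = a0 - a0.mean() if center else a0
        nw = float(np.sqrt(w @ w))
        na = float(np.sqrt(a @ a))
        if nw == 0.0 or na == 0.0:
            if drop_zero:
                continue
            raise DegenerateFeatureError(
                f"feature block {i} has zero norm; the region is constant under the "
                "feature maps (set drop_zero_blocks to skip such blocks)"
            )
        dot = float(w @ a)
        sim = dot / (nw * na)
        sims.append(sim)
        gw = a / (nw * na) - (dot / (nw**3 * na)) * w
        ga = w / (nw * na) - (dot / (na**3 * nw)) * a
        if center:
            gw = gw - gw.mean()
            ga = ga - ga.mean()
        grads_w.append(gw)
        grads_a.append(ga)
        kept.append(i)
    if not kept:
        raise DegenerateFeatureError("all feature blocks have zero norm")
    return sims, grads_w, grads_a, kept


def block_ncc_loss(
    warped_feats: FeatureBlocks,
    fixed_feats: FeatureBlocks,
    drop_zero_blocks: bool = False,
) -> float:
    """Negative sum over blocks of the NCC (cosine) of paired feature vectors.

    ``LOSS = - sum_i D(F_wi, F_ai) / sqrt(D(F_wi, F_wi) * D(F_ai, F_ai))``
    where ``D`` is the dot product, ranging over ``[-N, N]`` for ``N``
    blocks (equal to ``-N`` iff every pair is positively proportional).
    """
    if warped_feats.n_blocks != fixed_feats.n_blocks:
        raise ValidationError(
            f"block count mismatch: {warped_feats.n_blocks} vs {fixed_feats.n_blocks}"
        )
    for i, (w, a) in enumerate(zip(warped_feats.blocks, fixed_feats.blocks)):
        if w.shape != a.shape:
            raise ValidationError(f"block {i} dimension mismatch: {w.shape} vs {a.shape}")
    sims, _, _, _ = _ncc_terms(warped_feats.blocks, fixed_feats.blocks, drop_zero_blocks)
    return -float(np.sum(sims))


# ---------------------------------------------------------------------------
# Siamese localization
# ---------------------------------------------------------------------------


def siamese_localize(
    moving: Volume, fixed: Volume, config: RegistrationConfig
) -> DisplacementField:
    """Twin-branch localization: shared conv encoder + linear regression head.

    The two branches apply identical (seeded) weights to the moving and the
    fixed image; global per-channel summaries of both branches and of their
    difference feed a regression head that outputs the control-lattice
    displacements.  The head is zero-initialized, so a freshly constructed
    localizer predicts the identity field — the per-pair optimization in
    :func:`register_pair` then refines the lattice directly.
    """
    if not moving.same_geometry(fixed):
        raise GeometryError("moving and fixed volumes must share geometry")
    ndim = 3 if config.mode == "3d" else 2
    net = ConvFeaturePyramid(ndim, config.feature_levels, config.base_channels, config.seed)

    def _embed(vol: Volume) -> np.ndarray:
        data = _min_max_normalize(vol.data) if config.normalize else vol.data
        if ndim == 3:
            feats, _ = net.forward(data)
            return np.concatenate([f.mean(axis=tuple(range(1, f.ndim))) for f in feats])
        per_slice = []
        for k in range(data.shape[0]):
            feats, _ = net.forward(data[k])
            per_slice.append(np.concatenate([f.mean(axis=tuple(range(1, f.ndim))) for f in feats]))
        return np.mean(per_slice, axis=0)

    em, ef = _embed(moving), _embed(fixed)
    features = np.concatenate([em, ef, em - ef])
    nc = tuple(n_control_points(n, s) for n, s in zip(moving.shape, config.control_spacing))
    n_out = int(np.prod(nc)) * 3
    head_w = np.zeros((n_out, features.size))  # zero-initialized regression layer
    head_b = np.zeros(n_out)
    theta = (head_w @ features + head_b).reshape(nc + (3,))
    return DisplacementField(theta, config.control_spacing, moving.spacing)


# ---------------------------------------------------------------------------
# Bending-energy regularizer on the lattice
# ---------------------------------------------------------------------------


def _bending_energy(theta_mm: np.ndarray):
    """Mean squared second difference of the lattice displacements (mm^2)."""
    val = 0.0
    grad = np.zeros_like(theta_mm)
    n_terms = 0
    for ax in range(3):
        if theta_mm.shape[ax] < 3:
            continue
        sl = [slice(None)] * 4
        sl_m, sl_c, sl_p = list(sl), list(sl), list(sl)
        sl_m[ax] = slice(0, -2)
        sl_c[ax] = slice(1, -1)
        sl_p[ax] = slice(2, None)
        d2 = theta_mm[tuple(sl_p)] - 2.0 * theta_mm[tuple(sl_c)] + theta_mm[tuple(sl_m)]
        val += float(np.sum(d2**2))
        grad[tuple(sl_p)] += 2.0 * d2
        grad[tuple(sl_c)] += -4.0 * d2
        grad[tuple(sl_m)] += 2.0 * d2
        n_terms += d2.size
    if n_terms == 0:
        return 0.0, grad
    return val / n_terms, grad / n_terms


# ---------------------------------------------------------------------------
# The optimization loop
# ---------------------------------------------------------------------------


def _fill_excluded_lattice(
    theta: np.ndarray, free: np.ndarray, spacing_arr: np.ndarray
) -> np.ndarray:
    """Replace lattice nodes in a no-data region by the bending-energy minimizer.

    Solves the (linear, positive-definite) normal equations of the bending
    quadratic for the ``free`` nodes with the remaining nodes held fixed —
    biharmonic interpolation of the surrounding displacement field.
    """
    if not free.any():
        return theta
    free4 = np.broadcast_to(free[..., None], theta.shape)

    def bend_grad(th: np.ndarray) -> np.ndarray:
        _, g = _bending_energy(th * spacing_arr)
        return g * spacing_arr

    # residual for current interior values; CG on the restricted Hessian
    theta = theta.copy()
    x = theta[free4].copy()
    base = theta.copy()
    base[free4] = 0.0

    def apply_a(v: np.ndarray) -> np.ndarray:
        th = np.zeros_like(theta)
        th[free4] = v
        return bend_grad(th)[free4]

    b = -bend_grad(base)[free4]
    r = b - apply_a(x)
    p = r.copy()
    rs = float(r @ r)
    for _ in range(200):
        if rs < 1e-18:
            break
        ap = apply_a(p)
        alpha = rs / max(float(p @ ap), 1e-30)
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(r @ r)
        p = r + (rs_new / max(rs, 1e-30)) * p
        rs = rs_new
    theta[free4] = x
    return theta


@dataclass
class RegistrationResult:
    """Outcome of :func:`register_pair`.

    ``loss_trace`` holds one total-loss value per iteration (the first entry
    is the identity-field loss); the returned ``field``/``warped`` pair is
    the best-loss state encountered (earliest on ties), so the final
    accepted loss never exceeds the initial one.
    """

    field: DisplacementField
    warped: Volume
    loss_trace: list[float]
    iterations_run: int
    converged: bool
    best_loss: float = dc_field(default=np.nan)
    initial_loss: float = dc_field(default=np.nan)


def _downsample_inplane(data: np.ndarray, f: int) -> np.ndarray:
    """Block-average in-plane by ``f`` (edge-replicating to a multiple of f)."""
    if f == 1:
        return data
    Z, Y, X = data.shape
    Yp, Xp = -Y % f, -X % f
    d = np.pad(data, ((0, 0), (0, Yp), (0, Xp)), mode="edge")
    return d.reshape(Z, (Y + Yp) // f, f, (X + Xp) // f, f).mean(axis=(2, 4))


def _work_lattice_counts(work_shape, full_shape, cs_work, cs_full):
    """Lattice counts covering both the working and the full-resolution grid."""
    counts = []
    for ax in range(3):
        n = n_control_points(work_shape[ax], cs_work[ax])
        while (n - 1) * cs_full[ax] < full_shape[ax] - 1:
            n += 1
        counts.append(n)
    return tuple(counts)


def register_pair(
    moving: Volume,
    fixed: Volume,
    config: RegistrationConfig,
    exclude: "Mask | None" = None,
) -> RegistrationResult:
    """Align the moving (pre-ablation) image to the fixed (post-ablation) one.

    Iterates: materialize the lattice to a dense field, warp the moving
    image through the tent-kernel sampler, extract block features of the
    warped image, evaluate the block-NCC loss plus the bending penalty, and
    take a gradient step on the lattice — until the relative loss change
    stays below ``tolerance`` or ``max_iters`` is reached.  Reproducible
    bit-for-bit for a given config.

    ``exclude`` marks a fixed-frame region with no valid correspondence —
    typically the ablation zone, whose tissue has been destroyed and whose
    post-ablation appearance has nothing to match in the pre-ablation image.
    Features there are zero-weighted in both images, so the displacement
    inside the region comes from the smoothness-regularized lattice
    interpolating the surrounding anatomy.
    """
    if not moving.same_geometry(fixed):
        raise GeometryError("moving and fixed volumes must share geometry")
    if not (np.all(np.isfinite(moving.data)) and np.all(np.isfinite(fixed.data))):
        raise ValidationError("inputs must have finite intensities")
    if exclude is not None and exclude.shape != fixed.shape:
        raise GeometryError("exclusion mask geometry does not match the fixed image")

    mode2d = config.mode == "2d"
    f = config.inplane_downsample
    mov = _min_max_normalize(moving.data) if config.normalize else moving.data.astype(float)
    fix = _min_max_normalize(fixed.data) if config.normalize else fixed.data.astype(float)
    mov_w = _downsample_inplane(mov, f)
    fix_w = _downsample_inplane(fix, f)
    work_shape = mov_w.shape
    full_shape = moving.shape
    cs_full = config.control_spacing
    cs_work = (cs_full[0], max(cs_full[1] / f, 1.0), max(cs_full[2] / f, 1.0))
    work_spacing = (moving.spacing[0], moving.spacing[1] * f, moving.spacing[2] * f)

    nc = _work_lattice_counts(work_shape, full_shape, cs_work, cs_full)
    mats = tuple(
        interp_matrix(np.arange(work_shape[ax], dtype=np.float64), cs_work[ax], nc[ax])
        for ax in range(3)
    )

    ndim_net = 2 if mode2d else 3
    net = ConvFeaturePyramid(ndim_net, config.feature_levels, config.base_channels, config.seed)
    partition = config.resolved_partition()

    if config.train_features and mode2d:
        raise ConfigurationError("joint feature adaptation is only supported in 3-D mode")

    drop_zero = config.drop_zero_blocks or exclude is not None
    keep_w = None
    if exclude is not None:
        from scipy import ndimage as _ndi

        # blank the no-correspondence region (dilated to cover its edge) in
        # BOTH images: its content then contributes neither similarity nor
        # gradient, and the field inside it is interpolated by the bending
        # regularizer from the surrounding anatomy
        keep = ~_ndi.binary_dilation(exclude.data.astype(bool), iterations=2)
        keep_w = _downsample_inplane(keep.astype(np.float64), f)
        fix_w = fix_w * keep_w

    # with fixed filters the fixed-image features are constant across iterations
    fixed_blocks: list[np.ndarray] = []
    if mode2d:
        for k in range(work_shape[0]):
            feats, _ = net.forward(fix_w[k])
            fixed_blocks.extend(_gather_blocks(feats, partition, config.block_pool))
    elif not config.train_features:
        feats_f, _ = net.forward(fix_w)
        fixed_blocks = _gather_blocks(feats_f, partition, config.block_pool)

    spacing_arr = np.asarray(work_spacing)
    idz, idy, idx = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in work_shape], indexing="ij"
    )

    def _warp_with_grad(dense):
        x = idx + dense[..., 2]
        y = idy + dense[..., 1]
        if mode2d:
            V = np.empty(work_shape)
            gx = np.empty(work_shape)
            gy = np.empty(work_shape)
            for k in range(work_shape[0]):
                V[k], gx[k], gy[k] = sample_bilinear(mov_w[k], x[k], y[k], with_grad=True)
            return V, gx, gy, None
        z = idz + dense[..., 0]
        V, gx, gy, gz = sample_trilinear(mov_w, x, y, z, with_grad=True)
        return V, gx, gy, gz

    def _loss_and_grad(theta):
        dense = lattice_to_dense(theta, mats)
        V, gx, gy, gz = _warp_with_grad(dense)
        if keep_w is not None:
            V = V * keep_w
        wgrads = None
        if mode2d:
            dimg = np.empty(work_shape)
            warped_blocks, caches = [], []
            for k in range(work_shape[0]):
                feats, cache = net.forward(V[k])
                warped_blocks.extend(_gather_blocks(feats, partition, config.block_pool))
                caches.append((feats, cache))
            sims, gblocks, _, kept = _ncc_terms(
                warped_blocks, fixed_blocks, drop_zero, config.ncc_center
            )
            gmap = dict(zip(kept, gblocks))
            nb_per = len(warped_blocks) // work_shape[0]
            for k in range(work_shape[0]):
                feats, cache = caches[k]
                dblocks = [
                    -gmap.get(k * nb_per + j, np.zeros_like(warped_blocks[k * nb_per + j]))
                    for j in range(nb_per)
                ]
                dfeats = _scatter_block_grads(dblocks, feats, partition, config.block_pool)
                dimg[k] = net.backward(dfeats, cache)
        else:
            feats, cache = net.forward(V)
            warped_blocks = _gather_blocks(feats, partition, config.block_pool)
            if config.train_features:
                feats_fx, cache_fx = net.forward(fix_w)
                ref_blocks = _gather_blocks(feats_fx, partition, config.block_pool)
            else:
                ref_blocks = fixed_blocks
            sims, gblocks_w, gblocks_a, kept = _ncc_terms(
                warped_blocks, ref_blocks, drop_zero, config.ncc_center
            )
            gmap = dict(zip(kept, gblocks_w))
            dblocks = [
                -gmap.get(j, np.zeros_like(warped_blocks[j])) for j in range(len(warped_blocks))
            ]
            dfeats = _scatter_block_grads(dblocks, feats, partition, config.block_pool)
            if config.train_features:
                dimg, wg_moving = net.backward(dfeats, cache, want_weight_grads=True)
                gmap_a = dict(zip(kept, gblocks_a))
                dblocks_a = [
                    -gmap_a.get(j, np.zeros_like(ref_blocks[j])) for j in range(len(ref_blocks))
                ]
                dfeats_a = _scatter_block_grads(dblocks_a, feats_fx, partition, config.block_pool)
                _, wg_fixed = net.backward(dfeats_a, cache_fx, want_weight_grads=True)
                wgrads = [gm + gf for gm, gf in zip(wg_moving, wg_fixed)]
            else:
                dimg = net.backward(dfeats, cache)
        if keep_w is not None:
            dimg = dimg * keep_w
        ncc = -float(np.sum(sims))

        ddense = np.zeros(work_shape + (3,))
        ddense[..., 2] = dimg * gx
        ddense[..., 1] = dimg * gy
        if not mode2d:
            ddense[..., 0] = dimg * gz
        dtheta = dense_grad_to_lattice(ddense, mats)

        penalty = 0.0
        if config.smoothness_weight > 0:
            theta_mm = theta * spacing_arr
            bval, bgrad = _bending_energy(theta_mm)
            penalty = config.smoothness_weight * bval
            dtheta += config.smoothness_weight * bgrad * spacing_arr
        if mode2d:
            dtheta[..., 0] = 0.0
        return ncc + penalty, dtheta, wgrads

    theta = np.zeros(nc + (3,))
    velocity = np.zeros_like(theta)
    adam_m = np.zeros_like(theta)
    adam_v = np.zeros_like(theta)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    loss_trace: list[float] = []
    best_loss = np.inf
    best_theta = theta.copy()
    converged = False
    stall = 0

    for it in range(config.max_iters):
        loss, grad, wgrads = _loss_and_grad(theta)
        if not np.isfinite(loss):
            raise OptimizationDivergedError(it)
        loss_trace.append(loss)
        if loss < best_loss:  # strict: earliest state kept on ties
            best_loss = loss
            best_theta = theta.copy()
        if it > 0:
            prev = loss_trace[-2]
            # the criterion must hold for `patience` consecutive iterations,
            # otherwise a momentary stall of the optimizer would stop the run
            if abs(prev - loss) / max(abs(prev), 1e-12) < config.tolerance:
                stall += 1
                if stall >= config.patience:
                    converged = True
                    break
            else:
                stall = 0
        if float(np.max(np.abs(grad))) < 1e-9:
            # at a stationary point (e.g. moving == fixed); per-parameter
            # scaling would otherwise blow numerical noise up to full steps
            converged = True
            break
        if config.optimizer == "adam":
            adam_m = b1 * adam_m + (1 - b1) * grad
            adam_v = b2 * adam_v + (1 - b2) * grad**2
            mhat = adam_m / (1 - b1 ** (it + 1))
            vhat = adam_v / (1 - b2 ** (it + 1))
            theta = theta - config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        else:
            gmax = float(np.max(np.abs(grad)))
            if gmax > 0:
                velocity = config.momentum * velocity - config.learning_rate * grad / gmax
            else:
                velocity = config.momentum * velocity
            theta = theta + velocity
        if wgrads is not None:
            for lvl, wg in enumerate(wgrads):
                net.weights[lvl] = net.weights[lvl] - config.feature_learning_rate * wg

    if keep_w is not None:
        # nodes without data support: biharmonic infill from the surroundings
        node_idx = [
            np.clip(np.round(np.arange(nc[ax]) * cs_work[ax]).astype(int), 0, work_shape[ax] - 1)
            for ax in range(3)
        ]
        node_keep = keep_w[np.ix_(node_idx[0], node_idx[1], node_idx[2])]
        best_theta = _fill_excluded_lattice(best_theta, node_keep < 0.5, spacing_arr)

    # lift the working-resolution lattice to full resolution
    theta_full = best_theta.copy()
    theta_full[..., 1] *= f
    theta_full[..., 2] *= f
    field = DisplacementField(
        theta_full,
        (cs_work[0], cs_work[1] * f, cs_work[2] * f),
        moving.spacing,
    )
    dense_full = field.materialize(full_shape)
    grid = identity_grid(full_shape, mode="3d")
    if mode2d:
        warped_data = np.empty(full_shape)
        for k in range(full_shape[0]):
            warped_data[k] = sample_bilinear(
                moving.data[k],
                grid.points[k, ..., 0] + dense_full[k, ..., 2],
                grid.points[k, ..., 1] + dense_full[k, ..., 1],
            )
    else:
        warped_data = sample_trilinear(
            moving.data,
            grid.points[..., 0] + dense_full[..., 2],
            grid.points[..., 1] + dense_full[..., 1],
            grid.points[..., 2] + dense_full[..., 0],
        )
    warped = Volume(warped_data, fixed.spacing, fixed.origin)
    return RegistrationResult(
        field=field,
        warped=warped,
        loss_trace=loss_trace,
        iterations_run=len(loss_trace),
        converged=converged,
        best_loss=best_loss,
        initial_loss=loss_trace[0],
    )


# ---------------------------------------------------------------------------
# Landmark-based evaluation
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Corresponding anatomical landmarks in world-mm coordinates (z, y, x).

    ``fixed_mm`` are positions in the fixed (post-ablation) frame,
    ``moving_mm`` the corresponding positions in the moving frame.
    """

    moving_mm: np.ndarray
    fixed_mm: np.ndarray

    def __post_init__(self) -> None:
        self.moving_mm = np.atleast_2d(np.asarray(self.moving_mm, dtype=np.float64))
        self.fixed_mm = np.atleast_2d(np.asarray(self.fixed_mm, dtype=np.float64))
        if self.moving_mm.shape != self.fixed_mm.shape or self.moving_mm.shape[1] != 3:
            raise ValidationError("landmark arrays must both be (n, 3)")
        if self.moving_mm.shape[0] == 0:
            raise ValidationError("landmark set is empty")

    def __len__(self) -> int:
        return self.moving_mm.shape[0]


@dataclass
class LandmarkError:
    mean_mm: float
    sd_mm: float
    per_point_mm: np.ndarray


def landmark_error(
    field: DisplacementField,
    landmarks: LandmarkSet,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LandmarkError:
    """Mean/SD distance (mm) between mapped fixed-frame and moving-frame landmarks.

    Each fixed-frame landmark ``p`` is mapped to ``p + d(p) * spacing`` where
    ``d`` is the displacement interpolated at ``p``; the error is the
    Euclidean mm distance to the corresponding moving-frame landmark.
    """
    from scipy.ndimage import map_coordinates

    if len(landmarks) == 0:  # defensive; the dataclass already rejects this
        raise ValidationError("landmark set is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    if shape is None:
        if field.dense is None:
            raise GeometryError("need an image shape (or a materialized dense field)")
        shape = field.dense.shape[:3]
    dense = field.materialize(tuple(shape))
    vox = (landmarks.fixed_mm - origin) / spacing  # (n, 3) in (z, y, x) voxels
    disp = np.stack(
        [map_coordinates(dense[..., c], vox.T, order=1, mode="nearest") for c in range(3)],
        axis=1,
    )
    mapped = landmarks.fixed_mm + disp * spacing
    err = np.linalg.norm(mapped - landmarks.moving_mm, axis=1)
    return LandmarkError(float(err.mean()), float(err.std()), err)
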