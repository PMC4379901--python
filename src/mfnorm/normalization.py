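"""Second-stage functional normalization onto a fused functional template.

A subject's fused network image is registered to the group functional
template with a simplified SPM-style scheme: a 12-parameter affine
(translation, rotation, scale, shear) followed by a non-linear warp whose
per-axis displacement fields are expansions in a separable 3-D DCT-II basis.
Both stages minimize the sum of squared intensity differences (SSD) by
Gauss–Newton iteration with step halving, so the objective is non-increasing
over accepted iterations and the whole procedure is deterministic from the
identity initialization.  The non-linear stage adds a ridge penalty
``lam * ||c||^2`` on the basis coefficients (default lam = 0.01) and runs a
fixed number of sweeps (default 12).  The default basis is 7 x 8 x 7
functions per displacement direction, i.e. 392 parameters per direction.

The estimated warp (affine composed with the displacement field) is applied
to that subject's 4-D task data in a single resampling step, never as two
sequential interpolations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .template_fusion import FusedTemplate, build_template
from .volume_io import SeriesGrid, VolumeGrid

__all__ = [
    "DctWarp",
    "WarpConfig",
    "identity_affine_params",
    "affine_matrix",
    "dct_basis",
    "displacement_field",
    "estimate_affine",
    "estimate_warp",
    "apply_warp",
    "normalize_subject",
    "warp_to_json",
    "warp_from_json",
]


def identity_affine_params() -> np.ndarray:
    """[tx, ty, tz, rx, ry, rz, sx, sy, sz, hxy, hxz, hyz] at identity."""
    return np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)


def affine_matrix(params: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """4x4 voxel-space matrix for the 12 parameters, centred on the grid."""
    p = np.asarray(params, dtype=float)
    if p.shape != (12,):
        raise ValueError("affine parameters must have length 12")
    t, (rx, ry, rz), s, (hxy, hxz, hyz) = p[:3], p[3:6], p[6:9], p[9:12]
    cx, sx_ = np.cos(rx), np.sin(rx)
    cy, sy_ = np.cos(ry), np.sin(ry)
    cz, sz_ = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    rot_y = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    rot_z = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    shear = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    lin = rot_z @ rot_y @ rot_x @ shear @ np.diag(s)
    centre = (np.asarray(shape, dtype=float) - 1) / 2
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = t + centre - lin @ centre
    return mat


def dct_basis(n_points: int, n_funcs: int) -> np.ndarray:
    """Orthonormal DCT-II basis matrix of shape (n_points, n_funcs)."""
    i = np.arange(n_points)[:, None]
    m = np.arange(n_funcs)[None, :]
    basis = np.cos(np.pi * (2 * i + 1) * m / (2 * n_points))
    scale = np.where(m == 0, np.sqrt(1.0 / n_points), np.sqrt(2.0 / n_points))
    return basis * scale


@dataclass
class DctWarp:
    """Affine + separable-DCT displacement deformation on a fixed grid."""

    affine_params: np.ndarray
    basis_counts: tuple[int, int, int]
    coefficients: np.ndarray  # (3, prod(basis_counts)) voxel displacements
    grid_shape: tuple[int, int, int]
    lam: float = 0.01
    iterations: int = 12
    status: str = "ok"
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.affine_params = np.asarray(self.affine_params, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k = int(np.prod(self.basis_counts))
        if self.coefficients.shape != (3, k):
            raise ValueError(
                f"coefficients must be (3, {k}), got {self.coefficients.shape}"
            )
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class WarpConfig:
    """Settings for the non-linear estimation stage.

    ``penalty`` selects the regularizer weighted by ``lam``:

    * ``"membrane"`` (default) — squared first derivatives of the
      displacement field, diagonal in the DCT basis; smooth large
      displacements stay cheap, which is what makes multi-voxel warps
      recoverable;
    * ``"ridge"`` — plain squared coefficient norm.
    """

    basis_counts: tuple[int, int, int] = (7, 8, 7)
    lam: float = 0.01
    iterations: int = 12
    estimate_affine_first: bool = True
    affine_iterations: int = 12
    penalty: str = "membrane"

    def __post_init__(self) -> None:
        if self.penalty not in ("membrane", "ridge"):
            raise ValueError("penalty must be 'membrane' or 'ridge'")


def _penalty_weights(shape, basis_counts, penalty: str) -> np.ndarray:
    """Per-coefficient penalty weights, diagonal in the separable DCT basis.

    For the membrane (first-derivative) energy the weight of mode (m, n, o)
    is (pi*m/nx)^2 + (pi*n/ny)^2 + (pi*o/nz)^2, so the constant mode and
    other low frequencies are nearly free; the ridge uses unit weights.
    """
    if penalty == "ridge":
        return np.ones(int(np.prod(basis_counts)))
    freqs = [
        (np.pi * np.arange(basis_counts[a]) / shape[a]) ** 2 for a in range(3)
    ]
    w = (
        freqs[0][:, None, None]
        + freqs[1][None, :, None]
        + freqs[2][None, None, :]
    )
    return w.ravel()


def _basis_matrix(shape, basis_counts) -> np.ndarray:
    bx = dct_basis(shape[0], basis_counts[0])
    by = dct_basis(shape[1], basis_counts[1])
    bz = dct_basis(shape[2], basis_counts[2])
    full = np.einsum("im,jn,ko->ijkmno", bx, by, bz, optimize=True)
    return full.reshape(int(np.prod(shape)), int(np.prod(basis_counts)))


def _grid_coords(shape) -> np.ndarray:
    return np.indices(shape, dtype=float).reshape(3, -1)


def _sample(data: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    return map_coordinates(data, coords, order=order, mode="constant", cval=0.0)


def displacement_field(warp: DctWarp) -> np.ndarray:
    """Dense (3, nx, ny, nz) displacement field (voxels) of the DCT part."""
    basis = _basis_matrix(warp.grid_shape, warp.basis_counts)
    u = basis @ warp.coefficients.T  # (nvox, 3)
    return u.T.reshape((3,) + tuple(warp.grid_shape))


_FD_EPS = np.array([1e-2] * 3 + [1e-3] * 3 + [1e-3] * 3 + [1e-3] * 3)


def estimate_affine(
    source: VolumeGrid,
    target: VolumeGrid,
    iterations: int = 12,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """Estimate 12 affine parameters mapping target voxels into source.

    Gauss–Newton on the SSD between the affinely resampled source and the
    target, with a finite-difference Jacobian and step halving.  Returns the
    parameters and a status ("ok" or "max_iterations").
    """
    if source.data.shape != target.data.shape:
        raise ValueError("estimate_affine requires matching grids")
    for name, vol in (("source", source), ("target", target)):
        if vol.data.max() == vol.data.min():
            raise ValueError(f"{name} image is constant: no gradient to drive fit")
    shape = source.data.shape
    grid = _grid_coords(shape)
    grid_h = np.vstack([grid, np.ones(grid.shape[1])])
    tgt = target.data.ravel()

    def residual(p: np.ndarray) -> np.ndarray:
        coords = (affine_matrix(p, shape) @ grid_h)[:3]
        return _sample(source.data, coords) - tgt

    p = init.copy() if init is not None else identity_affine_params()
    r = residual(p)
    obj = float(r @ r)
    status = "max_iterations"
    for _ in range(iterations):
        jac = np.empty((r.size, 12))
        for k in range(12):
            dp = p.copy()
            dp[k] += _FD_EPS[k]
            jac[:, k] = (residual(dp) - r) / _FD_EPS[k]
        h = jac.T @ jac + 1e-9 * np.eye(12)
        g = jac.T @ r
        delta = np.linalg.solve(h, g)
        step, accepted = 1.0, False
        for _ in range(8):
            p_new = p - step * delta
            r_new = residual(p_new)
            obj_new = float(r_new @ r_new)
            if obj_new <= obj:
                p, r, obj, accepted = p_new, r_new, obj_new, True
                break
            step /= 2
        if not accepted:
            break
        if abs(delta).max() < 1e-6:
            status = "ok"
            break
    else:
        status = "max_iterations"
    if status != "ok" and abs(obj) < 1e-12:
        status = "ok"
    return p, status


def estimate_warp(
    source: VolumeGrid,
    target: VolumeGrid,
    config: WarpConfig | None = None,
) -> DctWarp:
    """Estimate affine + DCT displacement warp from source onto target.

    Minimizes ``SSD + lam * ||c||^2`` over the coefficient blocks by
    Gauss–Newton for ``config.iterations`` sweeps; the objective is
    non-increasing across accepted iterations.
    """
    config = config or WarpConfig()
    if source.data.shape != target.data.shape:
        raise ValueError("estimate_warp requires matching grids")
    shape = source.data.shape
    if config.estimate_affine_first:
        affine_params, _ = estimate_affine(
            source, target, iterations=config.affine_iterations
        )
    else:
        affine_params = identity_affine_params()

    basis = _basis_matrix(shape, config.basis_counts).astype(np.float32)
    k = basis.shape[1]
    grid = _grid_coords(shape)
    grid_h = np.vstack([grid, np.ones(grid.shape[1])])
    base = (affine_matrix(affine_params, shape) @ grid_h)[:3]
    # global intensity scaling to unit-RMS target, so lam weighs the data
    # term the same way regardless of the images' absolute scale
    rms = float(np.sqrt((target.data**2).mean()))
    scale = 1.0 / rms if rms > 0 else 1.0
    src = source.data * scale
    tgt = target.data.ravel() * scale
    grads = np.gradient(src)
    lam = config.lam
    pw = np.tile(_penalty_weights(shape, config.basis_counts, config.penalty), 3)

    coeff = np.zeros((3, k))

    def objective(c: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        coords = base + (basis @ c.T.astype(np.float32)).T
        r = _sample(src, coords) - tgt
        return float(r @ r + lam * (pw * c.ravel() ** 2).sum()), r, coords

    obj, resid, coords = objective(coeff)
    trace = [obj]
    status = "ok"
    for _ in range(config.iterations):
        gs = np.stack([_sample(g, coords) for g in grads]).astype(np.float32)
        jac = np.concatenate(
            [gs[d][:, None] * basis for d in range(3)], axis=1
        )  # (nvox, 3k) float32
        h = (jac.T @ jac).astype(float) + lam * np.diag(pw) + 1e-8 * np.eye(3 * k)
        g_vec = jac.T.astype(float) @ resid + lam * pw * coeff.ravel()
        delta = np.linalg.solve(h, g_vec).reshape(3, k)
        step, accepted = 1.0, False
        for _ in range(8):
            c_new = coeff - step * delta
            obj_new, r_new, coords_new = objective(c_new)
            if obj_new <= obj:
                coeff, obj, resid, coords = c_new, obj_new, r_new, coords_new
                accepted = True
                break
            step /= 2
        trace.append(obj)
        if not accepted:
            break

    return DctWarp(
        affine_params=affine_params,
        basis_counts=tuple(config.basis_counts),
        coefficients=coeff,
        grid_shape=tuple(shape),
        lam=lam,
        iterations=config.iterations,
        status=status,
        objective_trace=trace,
    )


def _warp_coords(warp: DctWarp) -> np.ndarray:
    shape = warp.grid_shape
    grid = _grid_coords(shape)
    grid_h = np.vstack([grid, np.ones(grid.shape[1])])
    base = (affine_matrix(warp.affine_params, shape) @ grid_h)[:3]
    basis = _basis_matrix(shape, warp.basis_counts)
    return base + (basis @ warp.coefficients.T).T


def apply_warp(
    warp: DctWarp,
    image: VolumeGrid | SeriesGrid,
    interpolation: str = "linear",
):
    """Resample an image (or every timepoint of a series) through the warp.

    Affine and displacement are composed into one coordinate map, so the
    data is interpolated exactly once.  Out-of-field voxels become 0.
    """
    orders = {"linear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = orders[interpolation]
    if tuple(image.data.shape[:3]) != tuple(warp.grid_shape):
        raise ValueError(
            f"image grid {image.data.shape[:3]} does not match warp grid "
            f"{warp.grid_shape}"
        )
    coords = _warp_coords(warp)
    shape = warp.grid_shape
    if isinstance(image, SeriesGrid):
        out = np.stack(
            [
                _sample(image.data[..., t], coords, order).reshape(shape)
                for t in range(image.n_timepoints)
            ],
            axis=-1,
        )
        return SeriesGrid(out, image.affine.copy(), t_r=image.t_r)
    out = _sample(image.data, coords, order).reshape(shape)
    return VolumeGrid(out, image.affine.copy())


def normalize_subject(
    subject_network_maps: list[VolumeGrid],
    template: FusedTemplate,
    task_series: SeriesGrid | None,
    config: WarpConfig | None = None,
    interpolation: str = "linear",
) -> tuple[DctWarp, SeriesGrid | None]:
    """Warp one subject onto the group functional template.

    The subject's network maps are fused with the *same* fusion settings as
    the group template, the warp is estimated fused-subject -> template, and
    applied to the subject's task series (if given).
    """
    tvol = template.volume
    for i, net in enumerate(subject_network_maps):
        if not tvol.same_grid(net):
            raise ValueError(f"subject network map {i} grid does not match template")
    if task_series is not None and not tvol.same_grid(task_series):
        raise ValueError("task series grid does not match template")
    fused_subject = build_template(
        subject_network_maps, params=template.entropy_params
    ).volume
    warp = estimate_warp(fused_subject, tvol, config)
    warped = apply_warp(warp, task_series, interpolation) if task_series else None
    return warp, warped


def warp_to_json(warp: DctWarp, path: str | Path) -> Path:
    payload = {
        "affine_params": warp.affine_params.tolist(),
        "basis_counts": list(warp.basis_counts),
        "coefficients": warp.coefficients.tolist(),
        "grid_shape": list(warp.grid_shape),
        "lam": warp.lam,
        "iterations": warp.iterations,
        "status": warp.status,
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def warp_from_json(path: str | Path) -> DctWarp:
    payload = json.loads(Path(path).read_text())
    return DctWarp(
        affine_params=np.asarray(payload["affine_params"]),
        basis_counts=tuple(payload["basis_counts"]),
        coefficients=np.asarray(payload["coefficients"]),
        grid_shape=tuple(payload["grid_shape"]),
        lam=payload["lam"],
        iterations=payload["iterations"],
        status=payload.get("status", "ok"),
    )
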