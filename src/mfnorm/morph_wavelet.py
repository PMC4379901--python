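"""Non-linear (morphological) level-1 wavelet analysis and synthesis.

The analysis operator splits a 2-D slice into disjoint 2x2 blocks.  For each
block the approximation coefficient is the block maximum M, and the three
detail coefficients are the (non-negative) gaps between M and the remaining
three members:

    approx      = max{X(r,c), X(r,c+1), X(r+1,c), X(r+1,c+1)}
    detail_v    = |M - X(r,c+1)|      (named "vertical" by convention)
    detail_h    = |M - X(r+1,c)|
    detail_d    = |M - X(r+1,c+1)|

Because the approximation is the block max, the sign branch of the detail
definition is unreachable and the details are always >= 0 on analysis output;
this is asserted rather than silently assumed.  Synthesis places M at all
four block positions and subtracts the detail gaps back:

    X'(r,c)     = M + min(detail_v, detail_h, detail_d, 0)
    X'(r,c+1)   = M + min(-detail_v, 0)
    X'(r+1,c)   = M + min(-detail_h, 0)
    X'(r+1,c+1) = M + min(-detail_d, 0)

Reconstruction is exact at every position except the block top-left when the
maximum lies elsewhere in the block, where the top-left value is replaced by
the block maximum.  The transform is gray-shift invariant: adding c to the
input adds c to the approximation and leaves all detail bands unchanged.

Only one decomposition level is supported (dual-resolution scheme); odd
dimensions are replicate-padded by one row/column and cropped on synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_io import VolumeGrid

__all__ = [
    "WaveletDecomposition",
    "VolumeDecomposition",
    "analyze",
    "synthesize",
    "analyze_volume",
    "synthesize_volume",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
BAND_NAMES = ("approx", "detail_v", "detail_h", "detail_d")


@dataclass
class WaveletDecomposition:
    """Level-1 morphological wavelet coefficients of one 2-D slice."""

    approx: np.ndarray
    detail_v: np.ndarray
    detail_h: np.ndarray
    detail_d: np.ndarray
    source_shape: tuple[int, int]
    pad_flags: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands()}
        if len(shapes) != 1:
            raise ValueError(f"band shapes differ: {shapes}")

    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.approx, self.detail_v, self.detail_h, self.detail_d)

    def band(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _pad_even(x: np.ndarray) -> tuple[np.ndarray, tuple[bool, bool]]:
    pad_r = x.shape[0] % 2 == 1
    pad_c = x.shape[1] % 2 == 1
    if pad_r or pad_c:
        x = np.pad(x, ((0, int(pad_r)), (0, int(pad_c))), mode="edge")
    return x, (pad_r, pad_c)


def analyze(slice_: np.ndarray, level: int = 1) -> WaveletDecomposition:
    """Decompose a 2-D slice into approximation and detail bands."""
    if level != 1:
        raise ValueError("only level-1 (dual-resolution) decomposition is supported")
    x = np.asarray(slice_, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("analyze expects a non-empty 2-D array")
    if not np.isfinite(x).all():
        raise ValueError("analyze: input contains non-finite values")
    source_shape = x.shape
    x, pad_flags = _pad_even(x)
    tl = x[0::2, 0::2]
    tr = x[0::2, 1::2]
    bl = x[1::2, 0::2]
    br = x[1::2, 1::2]
    m = np.maximum(np.maximum(tl, tr), np.maximum(bl, br))
    dec = WaveletDecomposition(
        approx=m,
        detail_v=np.abs(m - tr),
        detail_h=np.abs(m - bl),
        detail_d=np.abs(m - br),
        source_shape=source_shape,
        pad_flags=pad_flags,
    )
    # block max dominates every member, so the sign branch is unreachable
    assert (dec.detail_v >= 0).all() and (dec.detail_h >= 0).all()
    return dec


def synthesize(dec: WaveletDecomposition) -> np.ndarray:
    """Reconstruct a 2-D slice from a (possibly fused) decomposition."""
    m = np.asarray(dec.approx, dtype=float)
    yv = np.asarray(dec.detail_v, dtype=float)
    yh = np.asarray(dec.detail_h, dtype=float)
    yd = np.asarray(dec.detail_d, dtype=float)
    if not (m.shape == yv.shape == yh.shape == yd.shape):
        raise ValueError("band shapes differ")
    rows, cols = m.shape
    out = np.empty((2 * rows, 2 * cols), dtype=float)
    zero = np.zeros_like(m)
    out[0::2, 0::2] = m + np.minimum(np.minimum(yv, yh), np.minimum(yd, zero))
    out[0::2, 1::2] = m + np.minimum(-yv, zero)
    out[1::2, 0::2] = m + np.minimum(-yh, zero)
    out[1::2, 1::2] = m + np.minimum(-yd, zero)
    nr, nc = dec.source_shape
    return out[:nr, :nc]


@dataclass
class VolumeDecomposition:
    """Per-slice decompositions of a volume along one axis."""

    slices: list[WaveletDecomposition]
    slice_axis: str
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __len__(self) -> int:
        return len(self.slices)


def _slice_iter(data: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(data, axis, 0)


def analyze_volume(vol: VolumeGrid, slice_axis: str = "z") -> VolumeDecomposition:
    """Decompose a volume slice-wise along the given axis (default axial)."""
    if slice_axis not in _AXIS_INDEX:
        raise ValueError(f"slice_axis must be one of {sorted(_AXIS_INDEX)}")
    axis = _AXIS_INDEX[slice_axis]
    stack = _slice_iter(vol.data, axis)
    decs = [analyze(sl) for sl in stack]
    return VolumeDecomposition(
        slices=decs,
        slice_axis=slice_axis,
        grid_shape=vol.data.shape,
        affine=vol.affine.copy(),
    )


def synthesize_volume(vdec: VolumeDecomposition) -> VolumeGrid:
    """Invert analyze_volume, restoring the original grid shape and affine."""
    axis = _AXIS_INDEX[vdec.slice_axis]
    stack = np.stack([synthesize(d) for d in vdec.slices], axis=0)
    data = np.moveaxis(stack, 0, axis)
    if data.shape != vdec.grid_shape:
        raise ValueError(
            f"reconstructed shape {data.shape} != grid shape {vdec.grid_shape}"
        )
    return VolumeGrid(data, vdec.affine)
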