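"""Entropy-filtered maximum-selection fusion of intrinsic-network maps.

A functional template is built from several intrinsic-network (IN) spatial
maps that share one grid: each map is decomposed slice-wise with the
morphological wavelet, the four sub-bands are optionally replaced by local
Shannon-entropy maps that act as *selection priorities*, the maximum-selection
(MS) rule picks per coefficient the network with the largest priority
magnitude, and the fused bands are synthesized back to a volume.

The fused coefficient is the winner's original (signed, unfiltered) value, so
activation magnitudes survive fusion; a literal mode that outputs the
priority (entropy) values themselves is available via ``output="priority"``.
Voxels whose local entropy falls below ``epsilon_threshold`` have their
priority zeroed and can only win by the lowest-index tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .morph_wavelet import (
    BAND_NAMES,
    VolumeDecomposition,
    WaveletDecomposition,
    analyze_volume,
    synthesize_volume,
)
from .volume_io import VolumeGrid

__all__ = [
    "EntropyParams",
    "FusedTemplate",
    "local_entropy",
    "ms_fuse",
    "build_template",
]


@dataclass
class EntropyParams:
    """Local-entropy filter settings used as the fusion priority.

    neighborhood
        odd edge length of the square window (voxels), default 3.
    n_bins
        histogram bins; band values are quantized over the band's *global*
        range so entropies are comparable across positions.
    epsilon_threshold
        minimum local entropy (bits) for a coefficient to compete in fusion.
    enabled
        when False the raw band magnitude is the priority (pure MS).
    """

    neighborhood: int = 3
    n_bins: int = 256
    epsilon_threshold: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be odd and >= 3")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.epsilon_threshold < 0:
            raise ValueError("epsilon_threshold must be >= 0")


@dataclass
class FusedTemplate:
    """A fused multi-network functional template."""

    volume: VolumeGrid
    source_networks: list[str]
    entropy_params: EntropyParams
    fusion_scheme: str = "MS"
    provenance: VolumeGrid | None = None


def local_entropy(band: np.ndarray, params: EntropyParams | None = None) -> np.ndarray:
    """Replace each position by the Shannon entropy (bits) of its window.

    Values are quantized into ``n_bins`` over the band's global range;
    borders are replicate-padded.  A constant band yields all zeros.
    """
    params = params or EntropyParams()
    band = np.asarray(band, dtype=float)
    if band.ndim != 2:
        raise ValueError("local_entropy expects a 2-D band")
    if not np.isfinite(band).all():
        raise ValueError("local_entropy: non-finite values in band")
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.zeros_like(band)
    q = np.minimum(
        (params.n_bins * (band - lo) / (hi - lo)).astype(np.int64), params.n_bins - 1
    )
    r = params.neighborhood // 2
    padded = np.pad(q, r, mode="edge")
    win = sliding_window_view(padded, (params.neighborhood, params.neighborhood))
    win = win.reshape(band.shape + (-1,))
    k = win.shape[-1]
    # count, for each window member, how many members share its bin; then
    # H = -sum_b p_b log2 p_b = -mean_j log2(count_j / k)
    counts = (win[..., :, None] == win[..., None, :]).sum(axis=-1)
    return -np.log2(counts / k).mean(axis=-1)


def _priorities(
    decs: list[WaveletDecomposition],
    params: EntropyParams,
    filter_bands: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Stacked per-network priority magnitudes for each band."""
    out: dict[str, np.ndarray] = {}
    for name in BAND_NAMES:
        vals = np.stack([d.band(name) for d in decs])
        if params.enabled and name in filter_bands:
            pr = np.stack([local_entropy(v, params) for v in vals])
            if params.epsilon_threshold > 0:
                pr = np.where(pr >= params.epsilon_threshold, pr, 0.0)
        else:
            pr = np.abs(vals)
        out[name] = pr
    return out


def ms_fuse(
    decs: list[WaveletDecomposition],
    params: EntropyParams | None = None,
    filter_bands: tuple[str, ...] = BAND_NAMES,
    output: str = "original",
    return_winner: bool = False,
):
    """Maximum-selection fusion of decompositions of one slice.

    Per band and position the winner is the input whose priority (local
    entropy when filtering is enabled, raw magnitude otherwise) is largest;
    ties go to the lowest input index.  With ``output="original"`` the fused
    coefficient is the winner's signed band value; ``output="priority"``
    emits the winning priority value instead.
    """
    if not decs:
        raise ValueError("ms_fuse needs at least one decomposition")
    shapes = {d.approx.shape for d in decs}
    if len(shapes) != 1:
        raise ValueError(f"decompositions have mismatched band shapes: {shapes}")
    if output not in ("original", "priority"):
        raise ValueError("output must be 'original' or 'priority'")
    params = params or EntropyParams(enabled=False)
    prio = _priorities(decs, params, filter_bands)
    fused_bands: dict[str, np.ndarray] = {}
    winner_approx = None
    for name in BAND_NAMES:
        vals = np.stack([d.band(name) for d in decs])
        winner = np.argmax(prio[name], axis=0)  # first max -> lowest index
        src = vals if output == "original" else prio[name]
        fused_bands[name] = np.take_along_axis(src, winner[None], axis=0)[0]
        if name == "approx":
            winner_approx = winner
    fused = WaveletDecomposition(
        approx=fused_bands["approx"],
        detail_v=fused_bands["detail_v"],
        detail_h=fused_bands["detail_h"],
        detail_d=fused_bands["detail_d"],
        source_shape=decs[0].source_shape,
        pad_flags=decs[0].pad_flags,
    )
    if return_winner:
        return fused, winner_approx
    return fused


def build_template(
    networks: list[VolumeGrid],
    params: EntropyParams | None = None,
    slice_axis: str = "z",
    network_names: list[str] | None = None,
    filter_bands: tuple[str, ...] = BAND_NAMES,
    output: str = "original",
    with_provenance: bool = False,
) -> FusedTemplate:
    """Fuse several network maps on one grid into a functional template.

    Pipeline per slice: morphological wavelet analysis of every network,
    entropy filtering of sub-bands, MS fusion, synthesis.  Deterministic
    given inputs and parameters.
    """
    if not networks:
        raise ValueError("build_template needs at least one network map")
    ref = networks[0]
    for i, net in enumerate(networks[1:], start=1):
        if not ref.same_grid(net):
            raise ValueError(f"network {i} grid/affine does not match network 0")
    params = params or EntropyParams()
    names = network_names or [f"network_{i}" for i in range(len(networks))]

    vdecs = [analyze_volume(net, slice_axis) for net in networks]
    fused_slices: list[WaveletDecomposition] = []
    winner_slices: list[np.ndarray] = []
    for decs in zip(*(v.slices for v in vdecs)):
        fused, winner = ms_fuse(
            list(decs), params, filter_bands, output, return_winner=True
        )
        fused_slices.append(fused)
        winner_slices.append(winner)
    fused_vdec = VolumeDecomposition(
        slices=fused_slices,
        slice_axis=slice_axis,
        grid_shape=ref.data.shape,
        affine=ref.affine.copy(),
    )
    volume = synthesize_volume(fused_vdec)

    provenance = None
    if with_provenance:
        from .morph_wavelet import _AXIS_INDEX  # local import: private helper

        axis = _AXIS_INDEX[slice_axis]
        full = []
        for sl, dec in zip(winner_slices, fused_slices):
            up = np.repeat(np.repeat(sl, 2, axis=0), 2, axis=1)
            nr, nc = dec.source_shape
            full.append(up[:nr, :nc])
        prov = np.moveaxis(np.stack(full, axis=0), 0, axis)
        provenance = VolumeGrid(prov.astype(float), ref.affine.copy())

    return FusedTemplate(
        volume=volume,
        source_networks=names,
        entropy_params=params,
        provenance=provenance,
    )
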