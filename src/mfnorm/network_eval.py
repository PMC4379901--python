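"""Activation-map statistics: t-maps, FDR, region tables, correlations.

These are the map-level summaries used to judge a normalization scheme:
voxelwise one-sample t-maps over subjects, Benjamini–Hochberg FDR
thresholding, per-region peak/extent statistics with Euclidean peak shifts
between two schemes, subject-to-mean spatial correlation, and the
mean-volume "study specific" template baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import LabelVolume, VolumeGrid

__all__ = [
    "RegionStats",
    "one_sample_tmap",
    "fdr_threshold",
    "region_stats",
    "compare_regions",
    "spatial_correlation",
    "mean_template",
]


@dataclass
class RegionStats:
    """Suprathreshold summary of one labeled region of a t-map."""

    region_name: str
    peak_world: np.ndarray  # mm
    peak_t: float
    mean_t: float
    n_voxels: int


def one_sample_tmap(maps: list[VolumeGrid]) -> tuple[VolumeGrid, VolumeGrid]:
    """Voxelwise one-sample t-test (H0: mean 0) across subject maps.

    Returns (t-map, two-sided p-map); voxels with zero variance across
    subjects are masked as NaN in both.
    """
    if len(maps) < 2:
        raise ValueError("one_sample_tmap needs at least 2 maps")
    ref = maps[0]
    for i, m in enumerate(maps[1:], start=1):
        if not ref.same_grid(m):
            raise ValueError(f"map {i} grid does not match map 0")
    arr = np.stack([m.data for m in maps])
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = sd == 0
    t[bad] = np.nan
    p = np.full_like(t, np.nan)
    ok = ~bad
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return VolumeGrid(t, ref.affine.copy()), VolumeGrid(p, ref.affine.copy())


def fdr_threshold(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float | None]:
    """Benjamini–Hochberg step-up procedure.

    Returns (reject mask aligned with the input, critical p) where the
    critical p is the largest p(k) with p(k) <= k*q/m, or None when nothing
    is rejected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        return np.zeros(m, dtype=bool), None
    k_star = int(np.max(np.nonzero(ok)[0]))
    crit = float(ranked[k_star])
    reject = p <= crit
    return reject.reshape(np.asarray(p_values).shape), crit


def region_stats(
    t_map: VolumeGrid,
    p_map: VolumeGrid,
    labels: LabelVolume,
    q: float = 0.01,
) -> list[RegionStats]:
    """Per-region suprathreshold statistics at the BH-FDR corrected level.

    FDR is applied jointly over all finite in-atlas voxels.  Per region:
    count of suprathreshold voxels, mean t over them, and the world-mm peak
    of |t| (ties to the first voxel in scan order).  Regions left empty
    after thresholding are absent from the result.
    """
    if t_map.data.shape != labels.data.shape:
        raise ValueError("labels grid does not match t-map")
    finite = np.isfinite(t_map.data) & np.isfinite(p_map.data)
    in_atlas = labels.data > 0
    mask = finite & in_atlas
    reject = np.zeros(t_map.data.shape, dtype=bool)
    if mask.any():
        rej_flat, _ = fdr_threshold(p_map.data[mask], q)
        reject[mask] = rej_flat
    out: list[RegionStats] = []
    for lab in labels.labels:
        sel = (labels.data == lab) & reject
        if not sel.any():
            continue
        tvals = t_map.data[sel]
        idx = np.argwhere(sel)
        peak_local = int(np.argmax(np.abs(tvals)))
        ijk = idx[peak_local]
        out.append(
            RegionStats(
                region_name=labels.label_names[int(lab)],
                peak_world=np.asarray(t_map.voxel_to_world(ijk), dtype=float),
                peak_t=float(tvals[peak_local]),
                mean_t=float(tvals.mean()),
                n_voxels=int(sel.sum()),
            )
        )
    return out


def compare_regions(a: list[RegionStats], b: list[RegionStats]) -> pd.DataFrame:
    """Pair region tables from two schemes: % voxel gain and peak shift (mm).

    percent_gain is the gain of b over a in suprathreshold extent;
    euclid_shift_mm is the Euclidean distance between the two peaks.
    Only regions present in both tables are paired.
    """
    bmap = {r.region_name: r for r in b}
    rows = []
    for ra in a:
        rb = bmap.get(ra.region_name)
        if rb is None:
            continue
        rows.append(
            {
                "region": ra.region_name,
                "n_voxels_a": ra.n_voxels,
                "n_voxels_b": rb.n_voxels,
                "mean_t_a": ra.mean_t,
                "mean_t_b": rb.mean_t,
                "percent_gain": 100.0 * (rb.n_voxels - ra.n_voxels) / ra.n_voxels,
                "euclid_shift_mm": float(
                    np.linalg.norm(np.asarray(rb.peak_world) - np.asarray(ra.peak_world))
                ),
            }
        )
    return pd.DataFrame(rows)


def spatial_correlation(
    subject_map: VolumeGrid,
    reference_map: VolumeGrid,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation between two maps over an optional voxel mask."""
    if subject_map.data.shape != reference_map.data.shape:
        raise ValueError("maps are on different grids")
    if mask is None:
        mask = np.ones(subject_map.data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = subject_map.data[mask]
    y = reference_map.data[mask]
    return float(np.corrcoef(x, y)[0, 1])


def mean_template(volumes: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise mean across volumes (the study-specific template baseline)."""
    if not volumes:
        raise ValueError("mean_template needs at least one volume")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if not ref.same_grid(v):
            raise ValueError(f"volume {i} grid does not match volume 0")
    return VolumeGrid(
        np.mean([v.data for v in volumes], axis=0), ref.affine.copy()
    )
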