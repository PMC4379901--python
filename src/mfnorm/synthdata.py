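"""Synthetic cohorts with the structure the normalization method assumes.

The generator emulates what the pipeline consumes after group ICA:

* group-level intrinsic-network spatial maps as smooth localized Gaussian
  blobs on a small 3-D grid (default 32 x 32 x 16; a paper-scale preset of
  53 x 63 x 46 is available),
* per-subject network maps: the group map pushed through a smooth random
  displacement field expanded in a low-order DCT basis (so recovery tests
  can work in-span of the estimation basis) plus additive Gaussian noise,
* per-subject component timecourses drawn from a multivariate normal whose
  pairwise correlations depend on group membership, with an optional
  class-specific motif inserted into one component,
* an on-disk bundle (NIfTI maps, long-format TSV timecourses, subjects.tsv,
  truth.json) for end-to-end and CLI tests.

Everything is bit-reproducible from the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .normalization import DctWarp, dct_basis, identity_affine_params
from .volume_io import (
    LabelVolume,
    VolumeGrid,
    write_timecourses,
    write_volume,
)

__all__ = [
    "NetworkDef",
    "CohortSpec",
    "gen_network_maps",
    "gen_timecourses",
    "gen_cohort",
    "network_labels",
]

PAPER_GRID = (53, 63, 46)


@dataclass
class NetworkDef:
    """One intrinsic network: a set of Gaussian blobs (fractional centres)."""

    name: str
    centers: list[tuple[float, float, float]]
    widths: list[float]  # Gaussian sigma, voxels
    amplitudes: list[float]


def _default_networks() -> list[NetworkDef]:
    # four networks emulating the task-relevant set: bilateral temporal
    # blobs and left/right sensorimotor blobs, spatially disjoint
    return [
        NetworkDef(
            "superior_temporal",
            centers=[(0.22, 0.30, 0.40), (0.78, 0.30, 0.40)],
            widths=[2.5, 2.5],
            amplitudes=[1.0, 0.9],
        ),
        NetworkDef(
            "middle_temporal",
            centers=[(0.25, 0.62, 0.35), (0.75, 0.62, 0.35)],
            widths=[2.2, 2.2],
            amplitudes=[0.95, 0.95],
        ),
        NetworkDef(
            "sensorimotor_left",
            centers=[(0.32, 0.45, 0.72)],
            widths=[2.8],
            amplitudes=[1.0],
        ),
        NetworkDef(
            "sensorimotor_right",
            centers=[(0.68, 0.45, 0.72)],
            widths=[2.8],
            amplitudes=[1.0],
        ),
    ]


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults follow the modeled study: 28 healthy controls (HC) and 27
    patients (SP), 498 timepoints per timecourse, and one component pair
    (superior temporal - middle temporal) whose correlation differs between
    groups (0.55 vs 0.15) on top of a common 0.20 background.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    n_hc: int = 28
    n_sp: int = 27
    network_defs: list[NetworkDef] = field(default_factory=_default_networks)
    subject_jitter: float = 1.5  # peak displacement, voxels
    jitter_basis: tuple[int, int, int] = (3, 3, 3)
    noise_sd: float = 0.05
    T: int = 498
    base_correlation: float = 0.20
    group_correlation: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("superior_temporal", "middle_temporal"): (0.55, 0.15)
        }
    )
    motif: dict | None = None  # {"length", "amplitude", "group", "component"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_sp < 1 or self.T < 3:
            raise ValueError("counts and T must be positive (T >= 3)")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")
        for (rho_a, rho_b) in self.group_correlation.values():
            if not (-1 < rho_a < 1 and -1 < rho_b < 1):
                raise ValueError("correlations must lie in (-1, 1)")

    @property
    def component_names(self) -> list[str]:
        return [nd.name for nd in self.network_defs]

    @property
    def subject_ids(self) -> list[str]:
        return [f"hc{i:02d}" for i in range(self.n_hc)] + [
            f"sp{i:02d}" for i in range(self.n_sp)
        ]

    @property
    def groups(self) -> list[str]:
        return ["HC"] * self.n_hc + ["SP"] * self.n_sp


def _blob_volume(spec: CohortSpec, net: NetworkDef) -> np.ndarray:
    shape = np.asarray(spec.grid_shape, dtype=float)
    coords = np.indices(spec.grid_shape, dtype=float)
    vol = np.zeros(spec.grid_shape)
    for centre, width, amp in zip(net.centers, net.widths, net.amplitudes):
        c = np.asarray(centre, dtype=float) * (shape - 1)
        if np.any(c < 0) or np.any(c > shape - 1):
            raise ValueError(f"blob centre {centre} outside grid for {net.name}")
        d2 = sum((coords[a] - c[a]) ** 2 for a in range(3))
        vol += amp * np.exp(-d2 / (2 * width**2))
    return vol


def _random_warp(spec: CohortSpec, rng: np.random.Generator) -> DctWarp:
    """Smooth random displacement in the DCT basis, scaled to peak amplitude."""
    k = int(np.prod(spec.jitter_basis))
    coeff = rng.standard_normal((3, k))
    coeff[:, 0] = 0.0  # keep the constant mode out: no net translation
    warp = DctWarp(
        affine_params=identity_affine_params(),
        basis_counts=tuple(spec.jitter_basis),
        coefficients=coeff,
        grid_shape=tuple(spec.grid_shape),
    )
    if spec.subject_jitter > 0:
        from .normalization import displacement_field

        peak = np.abs(displacement_field(warp)).max()
        if peak > 0:
            warp.coefficients *= spec.subject_jitter / peak
    else:
        warp.coefficients[:] = 0.0
    return warp


def _push_through(vol: np.ndarray, warp: DctWarp) -> np.ndarray:
    from .normalization import displacement_field

    coords = np.indices(vol.shape, dtype=float).reshape(3, -1)
    u = displacement_field(warp).reshape(3, -1)
    out = map_coordinates(vol, coords + u, order=1, mode="constant", cval=0.0)
    return out.reshape(vol.shape)


def gen_network_maps(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Generate group maps, per-subject jittered maps, and ground truth.

    Returns a dict with keys ``group_maps`` (name -> VolumeGrid),
    ``subject_maps`` (subject id -> name -> VolumeGrid), ``true_warps``
    (subject id -> DctWarp) and ``labels`` (subject id -> group).
    """
    rng = rng or np.random.default_rng(spec.seed)
    affine = np.eye(4)
    group_maps = {
        nd.name: VolumeGrid(_blob_volume(spec, nd), affine.copy())
        for nd in spec.network_defs
    }
    subject_maps: dict[str, dict[str, VolumeGrid]] = {}
    true_warps: dict[str, DctWarp] = {}
    for sid in spec.subject_ids:
        warp = _random_warp(spec, rng)
        true_warps[sid] = warp
        maps = {}
        for name, gmap in group_maps.items():
            data = _push_through(gmap.data, warp)
            if spec.noise_sd > 0:
                data = data + rng.normal(0, spec.noise_sd, size=data.shape)
            maps[name] = VolumeGrid(data, affine.copy())
        subject_maps[sid] = maps
    return {
        "group_maps": group_maps,
        "subject_maps": subject_maps,
        "true_warps": true_warps,
        "labels": dict(zip(spec.subject_ids, spec.groups)),
    }


def _group_corr_matrix(spec: CohortSpec, group: str) -> np.ndarray:
    names = spec.component_names
    c = len(names)
    corr = np.full((c, c), spec.base_correlation)
    np.fill_diagonal(corr, 1.0)
    col = 0 if group == "HC" else 1
    for (a, b), rhos in spec.group_correlation.items():
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = rhos[col]
    eig = np.linalg.eigvalsh(corr)
    if eig.min() <= 0:
        bad = sorted(spec.group_correlation)
        raise ValueError(
            f"target correlation matrix for group {group} is not positive "
            f"definite (min eigenvalue {eig.min():.3g}); check pairs {bad}"
        )
    return corr


def gen_timecourses(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Per-subject (components x T) timecourses with group-dependent FNC.

    Rows are multivariate normal with the group's target pairwise
    correlations; the optional motif is a Hann-windowed bump added to one
    component of one class at a random offset per subject.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    chol = {g: np.linalg.cholesky(_group_corr_matrix(spec, g)) for g in ("HC", "SP")}
    names = spec.component_names
    out: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    motif_truth: dict[str, int] = {}
    for sid, group in zip(spec.subject_ids, spec.groups):
        z = rng.standard_normal((len(names), spec.T))
        tc = chol[group] @ z
        if spec.motif and group == spec.motif.get("group", "SP"):
            comp = names.index(spec.motif.get("component", names[0]))
            length = int(spec.motif["length"])
            amp = float(spec.motif["amplitude"])
            if amp != 0 and length >= 1:
                start = int(rng.integers(0, spec.T - length + 1))
                bump = amp * np.hanning(length + 2)[1:-1]
                tc[comp, start : start + length] += bump
                motif_truth[sid] = start
        out[sid] = tc
        labels[sid] = group
    return {"timecourses": out, "labels": labels, "motif_offsets": motif_truth}


def network_labels(spec: CohortSpec, threshold: float = 0.2) -> LabelVolume:
    """Integer label volume from the group networks' suprathreshold supports.

    Later networks overwrite earlier ones where supports touch (defaults are
    disjoint).  Useful as a stand-in parcellation for region statistics.
    """
    data = np.zeros(spec.grid_shape, dtype=int)
    names: dict[int, str] = {}
    for lab, nd in enumerate(spec.network_defs, start=1):
        blob = _blob_volume(spec, nd)
        data[blob > threshold * blob.max()] = lab
        names[lab] = nd.name
    return LabelVolume(data, np.eye(4), names)


def gen_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Write a full cohort bundle to disk; returns the path layout.

    Layout: ``group/<network>.nii.gz``, ``subjects/<sid>/<network>.nii.gz``,
    ``timecourses.tsv`` (long format), ``subjects.tsv``, ``truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = gen_network_maps(spec)
    tcs = gen_timecourses(spec)

    group_dir = out_dir / "group"
    group_dir.mkdir(exist_ok=True)
    for name, vol in maps["group_maps"].items():
        write_volume(vol, group_dir / f"{name}.nii.gz")
    subj_root = out_dir / "subjects"
    for sid, named in maps["subject_maps"].items():
        sdir = subj_root / sid
        sdir.mkdir(parents=True, exist_ok=True)
        for name, vol in named.items():
            write_volume(vol, sdir / f"{name}.nii.gz")

    write_timecourses(
        tcs["timecourses"], out_dir / "timecourses.tsv", spec.component_names
    )
    with open(out_dir / "subjects.tsv", "w") as fh:
        fh.write("subject_id\tgroup\n")
        for sid, group in zip(spec.subject_ids, spec.groups):
            fh.write(f"{sid}\t{group}\n")

    truth = {
        "seed": spec.seed,
        "grid_shape": list(spec.grid_shape),
        "component_names": spec.component_names,
        "group_correlation": {
            f"{a}|{b}": list(rhos)
            for (a, b), rhos in spec.group_correlation.items()
        },
        "base_correlation": spec.base_correlation,
        "subject_jitter": spec.subject_jitter,
        "noise_sd": spec.noise_sd,
        "motif_offsets": tcs["motif_offsets"],
        "true_warp_coefficients": {
            sid: w.coefficients.tolist() for sid, w in maps["true_warps"].items()
        },
        "jitter_basis": list(spec.jitter_basis),
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return {
        "root": out_dir,
        "group_dir": group_dir,
        "subjects_dir": subj_root,
        "timecourses": out_dir / "timecourses.tsv",
        "subjects_table": out_dir / "subjects.tsv",
        "truth": out_dir / "truth.json",
    }
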