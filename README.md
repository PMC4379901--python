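# mfnorm

Multi-network **functional template fusion and functional normalization**
for fMRI intrinsic networks.

Conventional fMRI spatial normalization aligns brains by structure, but
functional activation does not map one-to-one onto anatomy: the same
functional region can sit at different anatomical locations across
subjects. `mfnorm` addresses this by building a single *functional
template* from several intrinsic-network (IN) spatial maps — e.g. the
superior temporal, middle temporal, and sensorimotor networks identified by
group ICA of resting-state data — and adding a second, functional
normalization stage: each subject's fused network image is warped onto the
group functional template and the subject-specific warp `R_i` is applied to
that subject's task fMRI series. The package is aimed at researchers
studying multi-subject task fMRI (for example healthy-control vs patient
comparisons) who want to test whether functional registration sharpens
group activation maps, connectivity differences, and classification.

## Method at a glance

**Fusion.** Each network map is decomposed slice-wise with a level-1
*morphological wavelet*: per 2×2 block the approximation is the block
maximum `M = max{X(r,c), X(r,c+1), X(r+1,c), X(r+1,c+1)}` and the details
are the gaps `y_v = |M − X(r,c+1)|`, `y_h = |M − X(r+1,c)|`,
`y_d = |M − X(r+1,c+1)|`. The transform is gray-value-shift invariant, so
activation intensities survive the wavelet domain. Sub-bands are filtered
by local Shannon entropy `H = −Σ p log₂ p` over a 3×3 window (a fusion
priority that favours structured activation over flat background), fused by
maximum selection (per coefficient, the network with the largest priority
wins and contributes its original value), and synthesized back:
`X'(u,v) = X̂(u,v) + Ŷ(u,v)` with `X̂ = M` at all four block positions and
`Ŷ` restoring the detail gaps.

**Normalization.** The subject-to-template warp is a 12-parameter affine
plus per-axis displacement fields in a separable 3-D DCT basis (default
7×8×7 = 392 coefficients per direction), estimated by Gauss–Newton on
`SSD + λ·penalty` with λ = 0.01 over 12 iterations; affine and displacement
are composed and the task series resampled once.

**Evaluation.** One-sample t-maps with Benjamini–Hochberg FDR (q = 0.01),
per-region peak/extent tables with Euclidean peak shifts in mm, spatial
correlation to group means, per-subject FNC matrices with two-sample group
tests (Fisher z, BH-FDR at q = 0.05), and LDA / shapelet classification
under a repeated random-split protocol (14/14 train, 14/13 test, 100 runs).

See `docs/methods.md` for assumptions, parameter meanings, and numerical
choices.

## Worked example

No real cohort ships with the package; the synthetic generator creates one
with the structure the method assumes (jittered network blobs per subject,
group-dependent timecourse correlations). The `run-all` command runs the
whole pipeline — simulate → fuse → per-subject normalization → t-map /
region statistics → FNC group comparison — and prints a summary:

```bash
$ mfnorm run-all --out demo/ --seed 7 --n-hc 5 --n-sp 5 --t-len 120
{
 "seed": 7,
 "mean_correlation_before": 0.6233065455853823,
 "mean_correlation_after": 0.8061999935763435,
 "n_regions_suprathreshold": 4,
 "fnc_pairs_rejected": 1
}
```

Reading the numbers: before functional normalization the average spatial
correlation between a subject's fused network image and the group template
is 0.62; after warping each subject onto the template it rises to 0.81 —
the headline effect of the second normalization stage. All 4 simulated
networks contain FDR-significant voxels in the group t-map, and exactly one
FNC pair is flagged as differing between the groups — the superior-
temporal–middle-temporal pair, whose correlation the generator sets to 0.55
in controls vs 0.15 in patients.

The same stages are available individually (`mfnorm simulate`, `fuse`,
`normalize`, `tmap`, `regions`, `fnc`, `classify`) and as library calls:

```python
from mfnorm import build_template, normalize_subject, read_volume

nets = [read_volume(p) for p in ["sup_temporal.nii.gz", "mid_temporal.nii.gz",
                                 "sensorimotor.nii.gz"]]
template = build_template(nets)
warp, warped_series = normalize_subject(subject_nets, template, task_series)
```

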