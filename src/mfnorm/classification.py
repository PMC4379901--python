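"""Evaluation classifiers: Fisher LDA on FNC scores and shapelet search.

Both classifiers run under a repeated random-split protocol: per run a fresh
train/test split with fixed per-class counts (default 14/14 train, 14/13
test over 100 runs), fit on the training set, score on the test set.  Splits
are generated once per protocol seed, so competing methods can be compared
on identical splits.

The shapelet classifier performs an exhaustive search over subsequences of
the training series (stride 1, a configurable length range): the distance of
a series to a candidate is the minimum sliding-window Euclidean distance,
and the chosen (candidate, threshold) maximizes the information gain of the
induced binary split, with ties broken by larger split margin, then shorter
length, then earliest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LdaModel",
    "lda_fit",
    "lda_predict",
    "LdaClassifier",
    "Shapelet",
    "shapelet_fit",
    "shapelet_predict",
    "ShapeletClassifier",
    "SplitProtocol",
    "generate_splits",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# Linear discriminant analysis (binary Fisher LDA, pooled covariance)

@dataclass
class LdaModel:
    weights: np.ndarray
    threshold: float
    classes: np.ndarray  # [negative_class, positive_class]


def lda_fit(features: np.ndarray, labels, ridge: float | None = None) -> LdaModel:
    """Fisher linear discriminant with pooled covariance.

    ``ridge`` adds epsilon * I to the pooled covariance; without it a
    singular pooled covariance is an error rather than silently regularized.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (subjects x d)")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary LDA requires exactly 2 classes in training data")
    x0, x1 = x[y == classes[0]], x[y == classes[1]]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    n0, n1 = len(x0), len(x1)
    d = x.shape[1]
    s0 = np.cov(x0, rowvar=False).reshape(d, d) if n0 > 1 else np.zeros((d, d))
    s1 = np.cov(x1, rowvar=False).reshape(d, d) if n1 > 1 else np.zeros((d, d))
    pooled = ((n0 - 1) * s0 + (n1 - 1) * s1) / max(n0 + n1 - 2, 1)
    if ridge:
        pooled = pooled + ridge * np.eye(d)
    try:
        cond = np.linalg.cond(pooled)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "singular pooled covariance; pass ridge=<epsilon> to regularize"
        )
    w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2)
    return LdaModel(weights=w, threshold=threshold, classes=classes)


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    scores = x @ model.weights
    return np.where(scores > model.threshold, model.classes[1], model.classes[0])


class LdaClassifier:
    """fit/predict wrapper so LDA plugs into cross_validate."""

    def __init__(self, ridge: float | None = None):
        self.ridge = ridge
        self.model: LdaModel | None = None

    def fit(self, x, y) -> "LdaClassifier":
        self.model = lda_fit(x, y, ridge=self.ridge)
        return self

    def predict(self, x) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return lda_predict(self.model, x)


# ---------------------------------------------------------------------------
# Shapelet search

@dataclass
class Shapelet:
    """A subsequence with its best split threshold and information gain."""

    subsequence: np.ndarray
    split_threshold: float
    info_gain: float
    source_series_id: int
    start: int
    label_low: object  # class assigned when distance <= threshold
    label_high: object
    z_normalize: bool = False


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _znorm(windows: np.ndarray) -> np.ndarray:
    mu = windows.mean(axis=-1, keepdims=True)
    sd = windows.std(axis=-1, keepdims=True)
    return (windows - mu) / np.where(sd == 0, 1.0, sd)


def _min_sliding_dist(candidates: np.ndarray, series: np.ndarray, z: bool) -> np.ndarray:
    """Min Euclidean distance of each candidate (nc x L) to each series row."""
    length = candidates.shape[1]
    dists = np.empty((candidates.shape[0], series.shape[0]))
    c = _znorm(candidates) if z else candidates
    c2 = (c**2).sum(axis=1)
    for s_idx in range(series.shape[0]):
        w = sliding_window_view(series[s_idx], length)
        if z:
            w = _znorm(w)
        w2 = (w**2).sum(axis=1)
        sq = c2[:, None] + w2[None, :] - 2.0 * (c @ w.T)
        dists[:, s_idx] = np.sqrt(np.maximum(sq.min(axis=1), 0.0))
    return dists


def _best_split(dist_row: np.ndarray, labels: np.ndarray, classes) -> tuple:
    """Best (gain, margin, threshold) over split points of one candidate."""
    order = np.argsort(dist_row, kind="stable")
    d = dist_row[order]
    lab = labels[order]
    n = len(lab)
    is1 = (lab == classes[1]).astype(int)
    total1 = is1.sum()
    h_parent = _entropy(np.array([n - total1, total1]))
    cum1 = np.cumsum(is1)
    # degenerate fallback: no usable split point -> gain 0, all on the low side
    best = (0.0, 0.0, float(d[-1]))
    for j in range(n - 1):
        if d[j + 1] == d[j]:
            continue  # threshold cannot fall between equal distances
        n_le = j + 1
        le1 = cum1[j]
        h_le = _entropy(np.array([n_le - le1, le1]))
        n_gt = n - n_le
        gt1 = total1 - le1
        h_gt = _entropy(np.array([n_gt - gt1, gt1]))
        gain = h_parent - (n_le * h_le + n_gt * h_gt) / n
        margin = d[j + 1] - d[j]
        thr = (d[j] + d[j + 1]) / 2
        if (gain, margin) > (best[0], best[1]):
            best = (gain, margin, thr)
    return best


def shapelet_fit(
    series,
    labels,
    length_range: tuple[int, int] | None = None,
    z_normalize: bool = False,
) -> Shapelet:
    """Exhaustive shapelet search over the training series.

    ``length_range`` is inclusive; default 10–50% of the series length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a 2-D (n_series x T) array")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("shapelet_fit requires exactly 2 classes")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 series per class")
    t = x.shape[1]
    if length_range is None:
        length_range = (max(1, t // 10), max(1, t // 2))
    lmin, lmax = length_range
    if lmin < 1 or lmax < lmin or lmax > t:
        raise ValueError(f"invalid length range {length_range} for T={t}")

    best = None  # (gain, margin, -length, -(-idx)) ordering handled explicitly
    for length in range(lmin, lmax + 1):
        cands = []
        origins = []
        for s_idx in range(x.shape[0]):
            w = sliding_window_view(x[s_idx], length)
            cands.append(w)
            origins.extend((s_idx, start) for start in range(w.shape[0]))
        cands = np.concatenate(cands, axis=0)
        dists = _min_sliding_dist(cands, x, z_normalize)
        for c_idx in range(cands.shape[0]):
            gain, margin, thr = _best_split(dists[c_idx], y, classes)
            key = (gain, margin, -length)
            if best is None or key > best[0]:
                s_idx, start = origins[c_idx]
                low_mask = dists[c_idx] <= thr
                n1_low = (y[low_mask] == classes[1]).sum()
                n0_low = low_mask.sum() - n1_low
                label_low = classes[1] if n1_low > n0_low else classes[0]
                if n1_low == n0_low:
                    label_low = y[s_idx]  # tie: side of the source series
                label_high = classes[0] if label_low == classes[1] else classes[1]
                best = (
                    key,
                    Shapelet(
                        subsequence=cands[c_idx].copy(),
                        split_threshold=float(thr),
                        info_gain=float(gain),
                        source_series_id=int(s_idx),
                        start=int(start),
                        label_low=label_low,
                        label_high=label_high,
                        z_normalize=z_normalize,
                    ),
                )
    if best is None:
        raise ValueError("no valid split found (identical distances everywhere?)")
    return best[1]


def shapelet_predict(shapelet: Shapelet, series) -> np.ndarray:
    """Label series by which side of the threshold their min distance falls.

    A distance exactly at the threshold is assigned to the low (motif) side.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if x.shape[1] < len(shapelet.subsequence):
        raise ValueError("series shorter than the shapelet")
    dists = _min_sliding_dist(
        shapelet.subsequence[None, :], x, shapelet.z_normalize
    )[0]
    return np.where(
        dists <= shapelet.split_threshold, shapelet.label_low, shapelet.label_high
    )


class ShapeletClassifier:
    """fit/predict wrapper so the shapelet search plugs into cross_validate."""

    def __init__(
        self,
        length_range: tuple[int, int] | None = None,
        z_normalize: bool = False,
    ):
        self.length_range = length_range
        self.z_normalize = z_normalize
        self.shapelet: Shapelet | None = None

    def fit(self, x, y) -> "ShapeletClassifier":
        self.shapelet = shapelet_fit(x, y, self.length_range, self.z_normalize)
        return self

    def predict(self, x) -> np.ndarray:
        if self.shapelet is None:
            raise RuntimeError("classifier is not fitted")
        return shapelet_predict(self.shapelet, x)


# ---------------------------------------------------------------------------
# Repeated random-split protocol

@dataclass
class SplitProtocol:
    """Per-class train/test counts and run count for random-split CV."""

    n_train_a: int = 14
    n_train_b: int = 14
    n_test_a: int = 14
    n_test_b: int = 13
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train_a, self.n_train_b, self.n_test_a, self.n_test_b) < 1:
            raise ValueError("all split counts must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def generate_splits(labels, protocol: SplitProtocol) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/test index splits, reproducible from the protocol seed.

    The same split list can be reused across methods for paired comparison.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("protocol splits require exactly 2 classes")
    idx_a = np.flatnonzero(y == classes[0])
    idx_b = np.flatnonzero(y == classes[1])
    need_a = protocol.n_train_a + protocol.n_test_a
    need_b = protocol.n_train_b + protocol.n_test_b
    if len(idx_a) < need_a or len(idx_b) < need_b:
        raise ValueError(
            f"infeasible counts: need {need_a}/{need_b} per class, "
            f"have {len(idx_a)}/{len(idx_b)}"
        )
    rng = np.random.default_rng(protocol.seed)
    splits = []
    for _ in range(protocol.n_runs):
        pa = rng.permutation(idx_a)
        pb = rng.permutation(idx_b)
        train = np.concatenate([pa[: protocol.n_train_a], pb[: protocol.n_train_b]])
        test = np.concatenate(
            [
                pa[protocol.n_train_a : need_a],
                pb[protocol.n_train_b : need_b],
            ]
        )
        splits.append((train, test))
    return splits


def cross_validate(
    classifier,
    features: np.ndarray,
    labels,
    protocol: SplitProtocol,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Repeated random-split accuracy of a fit/predict classifier.

    Returns mean and sd of test accuracy plus the per-run scores; passing an
    explicit ``splits`` list lets several methods share identical splits.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if splits is None:
        splits = generate_splits(y, protocol)
    scores = []
    for train, test in splits:
        classifier.fit(x[train], y[train])
        pred = classifier.predict(x[test])
        scores.append(float(np.mean(pred == y[test])))
    scores = np.asarray(scores)
    return {
        "mean_accuracy": float(scores.mean()),
        "sd_accuracy": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        "scores": scores,
    }
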