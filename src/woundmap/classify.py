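"""Descriptor vectors, leave-one-out SVM classification and exact rank tests.

A whole time-lapse experiment is compressed to a short vector: the distance
axis of its velocity magnitude map is partitioned into equal intervals
(default 6) and the mean speed of each interval is taken over each healing
phase — 3 phases give a length-18 vector, 2 phases (for cohorts where full
closure is not always reached) a length-12 vector.  Norm-1 normalization
removes the overall motility scale, leaving only the spatio-temporal
pattern.  Small cohorts are classified with a linear SVM under leave-one-out
cross-validation, and group separation is scored with an exact two-sided
Wilcoxon rank-sum test (full permutation null).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from woundmap.strips import PhasePartition, VelocityMagnitudeMap

__all__ = [
    "DescriptorVector",
    "velocity_descriptor",
    "normalize",
    "loocv_svm",
    "ClassificationResult",
    "exact_ranksum",
    "pca2",
]


@dataclass
class DescriptorVector:
    """One experiment's descriptor: phase × distance-interval mean speeds,
    or a phase-2 texture histogram.

    Velocity descriptors are ordered phase-major: entries
    ``[p1·i0 … p1·i5, p2·i0 … p2·i5, (p3·i0 … p3·i5)]``.
    """

    experiment: str
    condition: str
    values: np.ndarray
    kind: str = "velocity"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("descriptor values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("descriptor contains non-finite values")


def velocity_descriptor(
    vmap: VelocityMagnitudeMap,
    phases: PhasePartition,
    n_intervals: int = 6,
    phases_used: int = 3,
    max_distance_um: float | None = None,
    experiment: str = "",
    condition: str = "",
) -> DescriptorVector:
    """Phase-partitioned mean-speed descriptor of a velocity magnitude map.

    The distance axis is split into ``n_intervals`` equal intervals over
    ``[0, max_distance_um]``; entry ``(phase, interval)`` is the mean of all
    defined map bins whose center falls in the interval, over the phase's
    frames.  3 phases × 6 intervals → length 18; 2 phases → length 12.
    A wholly-missing (interval × phase) cell is an error naming the cell.
    """
    if phases_used not in (2, 3):
        raise ValueError("phases_used must be 2 or 3")
    if max_distance_um is None:
        max_distance_um = vmap.n_bins * vmap.strip_width_um
    edges = np.linspace(0.0, max_distance_um, n_intervals + 1)
    centers = vmap.bin_centers_um()
    T = vmap.n_frames
    values = []
    for phase in range(1, phases_used + 1):
        window = phases.window(phase, T + 1)
        lo, hi = window.start, min(window.stop, T)
        if hi <= lo:
            raise ValueError(f"phase {phase} spans no frame pairs")
        block = vmap.M[lo:hi]
        for i in range(n_intervals):
            cols = (centers >= edges[i]) & (centers < edges[i + 1])
            cell = block[:, cols]
            if not np.isfinite(cell).any():
                raise ValueError(
                    f"no defined map bins for distance interval {i} "
                    f"({edges[i]:.0f}-{edges[i + 1]:.0f} µm) in phase {phase}"
                )
            values.append(float(np.nanmean(cell)))
    return DescriptorVector(experiment, condition, np.asarray(values))


def normalize(v: DescriptorVector | np.ndarray) -> DescriptorVector | np.ndarray:
    """Scale a descriptor to unit Euclidean norm (pattern, not magnitude)."""
    if isinstance(v, DescriptorVector):
        return replace(v, values=normalize(v.values), normalized=True)
    v = np.asarray(v, dtype=np.float64)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


@dataclass
class ClassificationResult:
    """Leave-one-out classification outcome for one cohort."""

    labels: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    accuracy: float
    group_sizes: dict
    ranksum_statistic: float
    ranksum_p: float


def loocv_svm(
    vectors: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence[str],
    C: float = 1.0,
    standardize: bool = True,
) -> ClassificationResult:
    """Leave-one-out linear-SVM classification of descriptor vectors.

    Each sample is predicted by a linear SVM (regularization ``C``) trained
    on all others; features are standardized on each training fold.  Returns
    per-fold predictions and decision scores, the aggregate accuracy, and an
    exact rank-sum test of the score separation between the two groups.
    Deterministic given the inputs.
    """
    X = np.asarray([np.asarray(v, dtype=np.float64) for v in vectors])
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("all descriptor vectors must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes for classification")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for leave-one-out")
    n = X.shape[0]
    preds = np.empty(n, dtype=y.dtype)
    scores = np.empty(n)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, ytr = X[train], y[train]
        if np.unique(ytr).size < classes.size:
            raise ValueError("a training fold lost a class entirely")
        Xte = X[i : i + 1]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, ytr)
        preds[i] = clf.predict(Xte)[0]
        scores[i] = clf.decision_function(Xte)[0] if classes.size == 2 else np.nan
    accuracy = float(np.mean(preds == y))
    if classes.size == 2 and np.isfinite(scores).all():
        a = scores[y == classes[0]]
        b = scores[y == classes[1]]
        w, p = exact_ranksum(a, b)
    else:
        w, p = float("nan"), float("nan")
    return ClassificationResult(
        labels=y,
        predictions=preds,
        scores=scores,
        accuracy=accuracy,
        group_sizes={str(c): int(k) for c, k in zip(classes, counts)},
        ranksum_statistic=w,
        ranksum_p=p,
    )


def exact_ranksum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test.

    The statistic is the sum of (average, tie-handled) pooled ranks of group
    A.  The null distribution is the full permutation null — every
    ``C(nA+nB, nA)`` assignment of the pooled ranks equiprobable — and the
    two-sided p doubles the smaller tail probability (capped at 1), which at
    complete separation of groups of 6 and 5 gives 2/462 ≈ 0.0043 and at 6
    and 6 gives 2/924 ≈ 0.0022.  Beyond ``exact_max_n`` pooled observations
    the normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if not np.isfinite(pooled).all():
        raise ValueError("scores contain non-finite values")
    ranks = stats.rankdata(pooled)
    n_a, n = a.size, pooled.size
    w = float(ranks[:n_a].sum())
    if n <= exact_max_n:
        eps = 1e-9
        count_le = 0
        count_ge = 0
        total = 0
        for comb in itertools.combinations(range(n), n_a):
            s = ranks[list(comb)].sum()
            total += 1
            if s <= w + eps:
                count_le += 1
            if s >= w - eps:
                count_ge += 1
        p = 2.0 * min(count_le, count_ge) / total
    else:
        mu = n_a * (n + 1) / 2.0
        n_b = b.size
        # tie-corrected variance of the rank sum
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return w, 1.0
        z = (w - mu) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


def pca2(vectors: Sequence[np.ndarray] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-component PCA of descriptor vectors.

    Returns ``(coords, explained_variance_ratio)`` with ``coords`` of shape
    (n, 2).  Sign convention: each principal axis is flipped so its
    largest-magnitude loading is positive, making the projection
    deterministic.  Requires at least 3 vectors and 2 distinct ones.
    """
    X = np.asarray([np.asarray(v, dtype=np.float64) for v in vectors])
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 equal-length vectors")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct vectors")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:2]
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    coords = Xc @ comps.T
    var = S**2
    ratio = var[:2] / var.sum() if var.sum() > 0 else np.zeros(2)
    return coords, ratio
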