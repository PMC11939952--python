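"""Specific-neural-coding statistics: similarity, clustering, correlation.

Three complementary analyses quantify whether a network's ISI coding is
*specific* to the stimulus kind:

* within-class similarity — mean pairwise cosine between the 3-feature
  coding vectors collected across the nine strengths of one stimulus
  (values near 1 mean the code is stable within a class);
* between-class disparity — K-means (K=3, Lloyd's algorithm with
  random-sample initialization) over all 27 coding samples, scored as the
  best-permutation agreement with the true stimulus labels, averaged over
  random restarts;
* plasticity relevance — Pearson correlation between the 100 ms-binned
  mean synaptic weight and mean ISI series of a run (n = 10 bins), with a
  Student-t significance test at df = n - 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import t as student_t

from .isi_coding import CodingSample

__all__ = [
    "SimilarityReport",
    "ClusterReport",
    "CorrelationReport",
    "cosine_similarity",
    "within_class_similarity",
    "kmeans_classify",
    "pearson_r",
    "t_test_r",
    "relevance_analysis",
]

#: cosine similarity above which two samples count as same-class
SIMILARITY_THRESHOLD = 0.8


@dataclass
class SimilarityReport:
    stimulus: str
    pairwise: np.ndarray  # cosines over all unordered strength pairs
    mean: float
    above_threshold: bool  # mean exceeds the 0.8 same-class threshold


@dataclass
class ClusterReport:
    features: tuple
    per_repeat: np.ndarray  # accuracy of each random restart
    mean: float


@dataclass
class CorrelationReport:
    stimulus: str
    strength: float
    r: float
    t: float
    n: int
    significance: str  # "0.01", "0.05" or "none"


def cosine_similarity(v1, v2) -> float:
    """cos(theta) = v1 . v2 / (|v1| |v2|); raises on a zero vector."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(v1 @ v2 / (n1 * n2))


def within_class_similarity(samples: list[CodingSample]) -> SimilarityReport:
    """Mean pairwise cosine over one stimulus's strength grid (36 pairs for 9)."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    vecs = [s.vector() for s in samples]
    cos = np.array(
        [cosine_similarity(a, b) for a, b in combinations(vecs, 2)]
    )
    labels = {s.label for s in samples}
    return SimilarityReport(
        stimulus=labels.pop() if len(labels) == 1 else "mixed",
        pairwise=cos,
        mean=float(cos.mean()),
        above_threshold=bool(cos.mean() > SIMILARITY_THRESHOLD),
    )


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    """Lloyd's K-means with random-sample initialization.

    Centers start as k distinct samples; assignment uses Euclidean distance;
    convergence when assignments stop changing.  An emptied cluster is
    re-seeded from a random sample.
    """
    centers = x[rng.choice(len(x), size=k, replace=False)].copy()
    assign = np.full(len(x), -1)
    for _ in range(max_iter):
        dists = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
        new_assign = dists.argmin(axis=1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for j in range(k):
            members = x[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                centers[j] = x[rng.integers(len(x))]
    return assign


def _best_permutation_accuracy(assign: np.ndarray, labels: np.ndarray) -> float:
    """Fraction correct under the best cluster-to-class label permutation."""
    classes = np.unique(labels)
    k = max(assign.max() + 1, len(classes))
    contingency = np.zeros((k, k))
    for c_idx, cls in enumerate(classes):
        for j in range(k):
            contingency[j, c_idx] = np.sum((assign == j) & (labels == cls))
    row, col = linear_sum_assignment(-contingency)
    return float(contingency[row, col].sum() / len(labels))


def kmeans_classify(
    samples: list[CodingSample],
    features: tuple = ("ev1", "ev2", "ev3"),
    k: int = 3,
    repeats: int = 100,
    seed: int | None = None,
) -> ClusterReport:
    """Cluster coding samples and score agreement with their stimulus labels.

    Features are used raw (no scaling).  Each of ``repeats`` restarts draws
    fresh random initial centers; the report carries the per-restart
    accuracies and their mean.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    x = np.array([s.vector(features) for s in samples])
    if x.ndim == 1:
        x = x[:, None]
    labels = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    acc = np.array(
        [
            _best_permutation_accuracy(_lloyd(x, k, rng), labels)
            for _ in range(repeats)
        ]
    )
    return ClusterReport(features=tuple(features), per_repeat=acc, mean=float(acc.mean()))


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a series")
    return float((dx * dy).sum() / (sx * sy))


def t_test_r(r: float, n: int) -> tuple[float, str]:
    """Significance of a correlation: t = r / sqrt((1 - r^2) / (n - 2)).

    Two-sided test against Student-t critical values with df = n - 2;
    returns (t, flag) with flag in {"0.01", "0.05", "none"}.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        t_stat = float(np.inf) * np.sign(r)
    else:
        t_stat = r / np.sqrt((1.0 - r * r) / (n - 2))
    df = n - 2
    if abs(t_stat) > student_t.ppf(1 - 0.01 / 2, df):
        sig = "0.01"
    elif abs(t_stat) > student_t.ppf(1 - 0.05 / 2, df):
        sig = "0.05"
    else:
        sig = "none"
    return float(t_stat), sig


def relevance_analysis(trace, stimulus: str = "", strength: float = float("nan")) -> CorrelationReport:
    """Correlate a run's binned MSW with its binned mean ISI.

    Uses the trace's recording bins (ten 100 ms bins for a 1000 ms run);
    raises if any bin lacks ISIs or if either series is constant.
    """
    x = np.asarray(trace.msw_series, dtype=float)
    y = np.asarray(trace.mean_isi_series, dtype=float)
    if np.isnan(y).any():
        raise ValueError(
            f"{int(np.isnan(y).sum())} recording bins contain no ISI; "
            "mean-ISI series incomplete"
        )
    r = pearson_r(x, y)
    t_stat, sig = t_test_r(r, len(x))
    return CorrelationReport(
        stimulus=stimulus,
        strength=strength,
        r=r,
        t=t_stat,
        n=len(x),
        significance=sig,
    )
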