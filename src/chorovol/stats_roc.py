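"""Diagnostic statistics for choroidal biomarkers: empirical ROC curves,
Mann-Whitney AUC, Youden operating points, binormal closed forms, and a
cohort simulator parameterized by published group summaries.

Clinical studies of these metrics publish only group-level summaries
(mean +- standard error, n eyes).  The binormal model is the minimal
completion of such summaries: each group is treated as Gaussian with
standard deviation ``SE * sqrt(n)``.  The closed-form AUC is then
``Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2))``, and the cohort simulator draws
finite samples of the published sizes to quantify the sampling spread of
the empirical AUC and of sensitivity/specificity at a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CohortSummary",
    "RocResult",
    "SimulationResult",
    "mann_whitney_auc",
    "roc_curve",
    "youden_cutoff",
    "binormal_auc",
    "binormal_operating_point",
    "simulate_cohorts",
    "REFERENCE_COHORTS",
]


@dataclass(frozen=True)
class CohortSummary:
    """Published group summary for one metric: mean +- SE over n eyes."""

    label: str
    metric: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n < 2:
            raise ValueError("need at least 2 eyes")

    @property
    def sd(self) -> float:
        """Implied group standard deviation, SE * sqrt(n)."""
        return self.se * np.sqrt(self.n)


#: Published cohort summaries for the central 6-mm ETDRS circle: vessel
#: volume (Vv) and choroidal volume (Vc) in mm^3 for healthy, CSC and
#: VKH/SO eyes.  These parameterize the binormal ROC analyses.
REFERENCE_COHORTS: Dict[Tuple[str, str], CohortSummary] = {
    (label, metric): CohortSummary(label, metric, mean, se, n)
    for label, metric, mean, se, n in [
        ("healthy", "vessel_volume", 3.17, 0.11, 77),
        ("healthy", "choroidal_volume", 6.47, 0.21, 77),
        ("csc", "vessel_volume", 4.68, 0.23, 34),
        ("csc", "choroidal_volume", 9.23, 0.40, 34),
        ("vkh", "vessel_volume", 3.83, 0.17, 33),
        ("vkh", "choroidal_volume", 8.04, 0.34, 33),
    ]
}


def _as_scores(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} score list must be non-empty")
    return arr


def _oriented(disease, healthy, direction: str):
    d = _as_scores(disease, "disease")
    h = _as_scores(healthy, "healthy")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' (disease scores high) or 'low'")
    if direction == "low":
        d, h = -d, -h
    return d, h


def mann_whitney_auc(disease, healthy, direction: str = "high") -> float:
    """Probability a random disease score ranks above a random healthy one.

    Computed from midranks (ties count 0.5), which equals the trapezoidal
    area under the empirical ROC curve.  ``direction='low'`` treats low
    scores as disease-like.
    """
    d, h = _oriented(disease, healthy, direction)
    pooled = np.concatenate([d, h])
    ranks = stats.rankdata(pooled)
    n1, n0 = d.size, h.size
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class RocResult:
    """An empirical ROC curve over candidate cutoffs.

    Cutoffs are midpoints between consecutive distinct pooled scores plus
    open ends below/above all scores; at cutoff c the rule calls "disease"
    iff (oriented) score > c, so ``sensitivity = P(disease > c)`` and
    ``specificity = P(healthy <= c)``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


def roc_curve(disease, healthy, direction: str = "high") -> RocResult:
    """Trace the empirical ROC curve; its trapezoidal AUC equals
    :func:`mann_whitney_auc` exactly."""
    d, h = _oriented(disease, healthy, direction)
    distinct = np.unique(np.concatenate([d, h]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    cuts = np.concatenate([[distinct[0] - span], mids, [distinct[-1] + span]])
    sens = (d[None, :] > cuts[:, None]).mean(axis=1)
    spec = (h[None, :] <= cuts[:, None]).mean(axis=1)
    fpr = 1.0 - spec
    # with ascending cutoffs both fpr and sens are nonincreasing, so the
    # reversed traversal walks the ROC monotonically (ties stay paired)
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    if direction == "low":
        cuts = -cuts[::-1]
        sens = sens[::-1]
        spec = spec[::-1]
    result = RocResult(cuts, sens, spec, auc, np.nan, direction)
    cutoff = youden_cutoff(result)
    return RocResult(cuts, sens, spec, auc, cutoff, direction)


def youden_cutoff(roc: RocResult) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties resolve to the lowest threshold.  With perfectly separated groups
    the maximizer is the midpoint of the separating gap (an interior
    candidate threshold).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


def binormal_auc(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """Closed-form AUC of two Gaussian score distributions:
    ``Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2))``."""
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(sd0, sd1)))


def binormal_operating_point(
    cutoff: float,
    diseased: CohortSummary,
    healthy: CohortSummary,
    direction: str = "high",
) -> Tuple[float, float]:
    """(sensitivity, specificity) in percent at a fixed cutoff under the
    binormal model (disease called when the score exceeds the cutoff for
    ``direction='high'``, falls below it for ``'low'``)."""
    sens = 1.0 - stats.norm.cdf(cutoff, loc=diseased.mean, scale=diseased.sd)
    spec = stats.norm.cdf(cutoff, loc=healthy.mean, scale=healthy.sd)
    if direction == "low":
        sens, spec = 1.0 - sens, 1.0 - spec
    return float(100.0 * sens), float(100.0 * spec)


@dataclass(frozen=True)
class SimulationResult:
    """Replicate distributions from the binormal cohort simulator."""

    auc: np.ndarray
    sensitivity: Optional[np.ndarray]
    specificity: Optional[np.ndarray]
    cutoff: Optional[float]

    @property
    def auc_mean(self) -> float:
        return float(self.auc.mean())

    @property
    def auc_se(self) -> float:
        return float(self.auc.std(ddof=1) / np.sqrt(self.auc.size))


def simulate_cohorts(
    diseased: CohortSummary,
    healthy: CohortSummary,
    n_reps: int = 10_000,
    seed: int = 0,
    cutoff: Optional[float] = None,
    direction: str = "high",
) -> SimulationResult:
    """Simulate replicate cohorts under the binormal model.

    Per replicate, ``diseased.n`` and ``healthy.n`` scores are drawn from
    the implied Gaussians and the empirical (midrank) AUC is computed; when
    ``cutoff`` is given, sensitivity and specificity at that fixed cutoff
    are recorded too.  Deterministic given ``seed``; the replicate-mean AUC
    converges to :func:`binormal_auc` of the same summaries.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    rng = np.random.default_rng(seed)
    n1, n0 = diseased.n, healthy.n
    d = rng.normal(diseased.mean, diseased.sd, size=(n_reps, n1))
    h = rng.normal(healthy.mean, healthy.sd, size=(n_reps, n0))
    sign = 1.0 if direction == "high" else -1.0
    pooled = np.concatenate([sign * d, sign * h], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    sens = spec = None
    if cutoff is not None:
        if direction == "high":
            sens = (d > cutoff).mean(axis=1)
            spec = (h <= cutoff).mean(axis=1)
        else:
            sens = (d < cutoff).mean(axis=1)
            spec = (h >= cutoff).mean(axis=1)
    return SimulationResult(auc, sens, spec, cutoff)
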