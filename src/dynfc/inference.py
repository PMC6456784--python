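"""Null-distribution construction and hypothesis testing for dFC.

For each region pair the null hypothesis is stationary connectivity
(``sigma^2 = 0`` up to estimation noise) against the one-sided alternative
``sigma^2 > 0``.  Surrogate copies of every subject supply null samples:
for surrogate index ``s`` the sample is the across-subject mean of the
windowed-metric variance, giving ``n_surrogates`` subject-averaged samples
per pair.  These can be tested per pair or pooled into a single aggregated
null (the default, which yields a highly resolved distribution:
250 surrogates x 78 pairs = 19,500 samples in the 13-region setting).

The critical value T* is the upper ``1 - alpha'`` empirical quantile
(nearest rank), with ``alpha' = alpha / m`` under Bonferroni correction
over the ``m = n(n-1)/2`` tested pairs.  A group-mean observed strength
strictly greater than T* rejects stationarity for that pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .metrics import MetricConfig, MetricId, pearson_corr
from .surrogates import SurrogateEnsemble
from .timeseries import Cohort
from .windows import DfcStrengthMatrix, WindowSpec, dfc_matrix

__all__ = [
    "NullDistribution",
    "TestConfig",
    "DfcTestResult",
    "DetectionProfile",
    "build_null",
    "critical_value",
    "test_dfc",
    "detection_profile",
    "test_retest",
]


@dataclass
class NullDistribution:
    """Surrogate sigma^2 samples per pair, optionally pooled across pairs."""

    metric: MetricId
    window: WindowSpec
    mode: str  # "per_pair" or "aggregated"
    pairs: list[tuple[int, int]]
    per_pair_samples: np.ndarray  # (n_pairs, n_surrogates)

    def __post_init__(self) -> None:
        self.per_pair_samples = np.asarray(self.per_pair_samples, dtype=float)
        if self.per_pair_samples.shape[0] != len(self.pairs):
            raise ValidationError("one sample row per pair required")
        if self.mode not in ("per_pair", "aggregated"):
            raise ValidationError("mode must be 'per_pair' or 'aggregated'")

    @property
    def n_surrogates(self) -> int:
        return self.per_pair_samples.shape[1]

    @property
    def pooled_samples(self) -> np.ndarray:
        """All pairs' samples concatenated (n_pairs * n_surrogates values)."""
        return self.per_pair_samples.ravel()


@dataclass
class TestConfig:
    """Significance level, multiplicity correction and null pooling mode."""

    alpha: float = 0.05
    correction: str = "bonferroni"  # or "none"
    null_mode: str = "aggregated"  # or "per_pair"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValidationError("correction must be 'bonferroni' or 'none'")
        if self.null_mode not in ("aggregated", "per_pair"):
            raise ValidationError("null_mode must be 'aggregated' or 'per_pair'")


@dataclass
class DfcTestResult:
    """Outcome of the sigma^2 > 0 test for every pair at one window."""

    metric: MetricId
    window: WindowSpec
    critical_value: float | np.ndarray
    reject: np.ndarray  # symmetric boolean matrix
    group_mean_strength: DfcStrengthMatrix


@dataclass
class DetectionProfile:
    """Minimum detecting window for one pair over a window grid.

    ``contiguous`` is True when the detected set is exactly the suffix
    ``{w : w >= min_window_seconds}`` of the grid; otherwise the pair is
    flagged (the dagger convention) and ``detected_windows`` lists the
    exact window lengths at which the null was rejected.
    """

    pair: tuple[int, int]
    min_window_seconds: float | None
    contiguous: bool
    detected_windows: list[float] = field(default_factory=list)


def _upper_triangle_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def build_null(
    cohort: Cohort,
    ensembles: list[SurrogateEnsemble],
    metric: MetricId | str,
    window: WindowSpec,
    config: MetricConfig | None = None,
    mode: str = "aggregated",
) -> NullDistribution:
    """Subject-averaged surrogate sigma^2 samples for every pair.

    ``ensembles[k]`` must hold the surrogates of ``cohort.subjects[k]``,
    all of equal size.  For surrogate index ``s`` and pair ``(i, j)`` the
    null sample is the mean over subjects of the dFC strength computed on
    each subject's s-th surrogate.
    """
    metric = MetricId(metric)
    if len(ensembles) != len(cohort):
        raise ValidationError("one ensemble per subject required")
    sizes = {len(e) for e in ensembles}
    if len(sizes) != 1:
        raise ValidationError(f"ensemble size mismatch: {sorted(sizes)}")
    n_surr = sizes.pop()
    n = cohort.n_regions
    pairs = _upper_triangle_pairs(n)
    iu = np.triu_indices(n, k=1)
    acc = np.zeros((len(pairs), n_surr))
    for ensemble in ensembles:
        for s, copy in enumerate(ensemble):
            mat = dfc_matrix(copy, metric, window, config)
            acc[:, s] += mat.values[iu]
    acc /= len(cohort)
    return NullDistribution(
        metric=metric, window=window, mode=mode, pairs=pairs,
        per_pair_samples=acc,
    )


def _nearest_rank_upper(samples: np.ndarray, alpha_adj: float) -> float:
    """Nearest-rank upper quantile at level ``1 - alpha_adj``."""
    ordered = np.sort(samples)
    m = ordered.size
    if alpha_adj * m < 1.0:
        warnings.warn(
            f"adjusted level {alpha_adj:.3g} below 1/{m} samples: "
            "critical value saturates at the maximum null sample",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(ordered[-1])
    k = math.ceil((1.0 - alpha_adj) * m)  # 1-based order statistic
    k = min(max(k, 1), m)
    return float(ordered[k - 1])


def critical_value(
    null: NullDistribution, config: TestConfig | None = None
) -> float | np.ndarray:
    """Critical value(s) T* from the null distribution.

    Aggregated mode pools all pairs' samples and returns one scalar;
    per-pair mode returns one T* per pair from its own samples.  The
    Bonferroni correction divides alpha by the number of tested pairs
    before taking the upper quantile.
    """
    config = config or TestConfig()
    m_pairs = len(null.pairs)
    alpha_adj = (
        config.alpha / m_pairs if config.correction == "bonferroni" else config.alpha
    )
    if config.null_mode == "aggregated":
        return _nearest_rank_upper(null.pooled_samples, alpha_adj)
    return np.array(
        [_nearest_rank_upper(row, alpha_adj) for row in null.per_pair_samples]
    )


def test_dfc(
    group_mean: DfcStrengthMatrix,
    null: NullDistribution,
    config: TestConfig | None = None,
) -> DfcTestResult:
    """Reject stationarity where the observed strength strictly exceeds T*.

    A value exactly equal to T* is NOT rejected.  The result matrix is
    symmetric with a False diagonal.
    """
    config = config or TestConfig()
    if group_mean.metric != null.metric:
        raise ValidationError(
            f"metric mismatch: {group_mean.metric} vs {null.metric}"
        )
    if group_mean.window != null.window:
        raise ValidationError("window mismatch between strengths and null")
    n = group_mean.values.shape[0]
    tstar = critical_value(null, config)
    reject = np.zeros((n, n), dtype=bool)
    if config.null_mode == "aggregated":
        for i, j in null.pairs:
            reject[i, j] = reject[j, i] = group_mean.values[i, j] > tstar
    else:
        for k, (i, j) in enumerate(null.pairs):
            reject[i, j] = reject[j, i] = group_mean.values[i, j] > tstar[k]
    return DfcTestResult(
        metric=null.metric,
        window=null.window,
        critical_value=tstar,
        reject=reject,
        group_mean_strength=group_mean,
    )


def detection_profile(
    results: list[DfcTestResult],
) -> dict[tuple[int, int], DetectionProfile]:
    """Per-pair minimum detecting window over a full grid of results.

    ``results`` must cover each grid window exactly once, all with the
    same metric.  A pair detected at every window at and above some length
    is contiguous; any other nonempty detected set gets the dagger flag
    with its explicit window list.  The output is independent of the
    ordering of ``results``.
    """
    if not results:
        raise ValidationError("need at least one test result")
    metrics = {r.metric for r in results}
    if len(metrics) != 1:
        raise ValidationError(f"mixed metrics in results: {metrics}")
    lengths = [r.window.length_seconds for r in results]
    if len(set(lengths)) != len(lengths):
        raise ValidationError("duplicate window lengths in results")
    order = np.argsort(lengths)
    grid = [lengths[k] for k in order]
    ordered = [results[k] for k in order]
    n = ordered[0].reject.shape[0]
    profiles: dict[tuple[int, int], DetectionProfile] = {}
    for i in range(n):
        for j in range(i + 1, n):
            detected = [
                grid[k] for k, r in enumerate(ordered) if r.reject[i, j]
            ]
            if not detected:
                profiles[(i, j)] = DetectionProfile(
                    pair=(i, j), min_window_seconds=None, contiguous=False,
                    detected_windows=[],
                )
                continue
            min_w = detected[0]
            suffix = [w for w in grid if w >= min_w]
            profiles[(i, j)] = DetectionProfile(
                pair=(i, j),
                min_window_seconds=min_w,
                contiguous=detected == suffix,
                detected_windows=detected,
            )
    return profiles


def test_retest(
    group_a: DfcStrengthMatrix, group_b: DfcStrengthMatrix
) -> float:
    """Pearson correlation of the two groups' pairwise strength vectors.

    Both matrices must share metric, window and region count; the
    correlation runs over the vectorized upper triangles.
    """
    if group_a.metric != group_b.metric:
        raise ValidationError("metric mismatch between groups")
    if group_a.window != group_b.window:
        raise ValidationError("window mismatch between groups")
    va, vb = group_a.upper_triangle(), group_b.upper_triangle()
    if va.size != vb.size:
        raise ValidationError("region-count mismatch between groups")
    try:
        return pearson_corr(va, vb)
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            f"constant strength vector: {exc}"
        ) from exc
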