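"""Sliding-window metric computation and the variance-based dFC statistic.

A rectangular window of fixed length slides over the time axis in steps of
one sample (1 TR by default); the chosen FC metric is evaluated on every
segment, and the variance of the resulting windowed series — the "dFC
strength" sigma^2 — is the test statistic for dynamic connectivity.

Window indexing is 0-based and half-open: window k covers columns
``[k, k + w)``, so a length-T series yields ``T - w + 1`` positions at
step 1.  The variance uses the sample convention (divisor ``count - 1``)
by default; the hypothesis test is invariant to this choice because data
and surrogates are treated identically.

Pearson, MI, VI and MTD have vectorized kernels (these dominate the cost
of surrogate null construction); the remaining metrics go through the
generic per-segment path.  A consistency test guarantees the kernels agree
with the per-segment definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    InsufficientWindowsError,
    ValidationError,
)
from .metrics import (
    MetricConfig,
    MetricId,
    metric_value,
    mtd_pair_series,
    sparse_precision,
)
from .timeseries import Cohort, RoiTimeSeriesSet

__all__ = [
    "WindowSpec",
    "WindowGrid",
    "WindowedMetricSeries",
    "DfcStrengthMatrix",
    "seconds_to_samples",
    "default_window_grid",
    "windowed_metric",
    "dfc_strength",
    "dfc_matrix",
    "cohort_mean_dfc",
    "strength_long_table",
]

#: Default window-length grid in seconds: 20 to 150 s in steps of 10 s.
DEFAULT_GRID_SECONDS: tuple[float, ...] = tuple(range(20, 151, 10))


def seconds_to_samples(length_seconds: float, tr_seconds: float) -> int:
    """Window length in samples: ``floor(length_seconds / tr_seconds)``."""
    if length_seconds <= 0 or tr_seconds <= 0:
        raise ValidationError("lengths must be positive")
    w = int(math.floor(length_seconds / tr_seconds))
    if w < 2:
        raise ValidationError(
            f"window of {length_seconds} s spans {w} sample(s) at "
            f"TR {tr_seconds} s; need at least 2"
        )
    return w


@dataclass(frozen=True)
class WindowSpec:
    """A rectangular sliding window.

    ``length_samples`` is derived from seconds via :func:`seconds_to_samples`
    when built through :meth:`from_seconds`.  ``shape`` is fixed to
    rectangular (typed for forward compatibility).
    """

    length_seconds: float
    length_samples: int
    step_samples: int = 1
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.length_samples < 2:
            raise ValidationError("length_samples must be >= 2")
        if self.step_samples < 1:
            raise ValidationError("step_samples must be >= 1")
        if self.shape != "rectangular":
            raise ValidationError("only rectangular windows are supported")

    @classmethod
    def from_seconds(
        cls, length_seconds: float, tr_seconds: float, step_samples: int = 1
    ) -> "WindowSpec":
        return cls(
            length_seconds=float(length_seconds),
            length_samples=seconds_to_samples(length_seconds, tr_seconds),
            step_samples=step_samples,
        )


@dataclass(frozen=True)
class WindowGrid:
    """An ordered grid of window specs with strictly increasing lengths."""

    specs: tuple[WindowSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValidationError("window grid must be nonempty")
        lengths = [s.length_seconds for s in self.specs]
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValidationError("grid lengths must be strictly increasing")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)


def default_window_grid(tr_seconds: float, step_samples: int = 1) -> WindowGrid:
    """The 20-150 s (step 10 s) grid converted to samples at the given TR."""
    return WindowGrid(
        tuple(
            WindowSpec.from_seconds(s, tr_seconds, step_samples)
            for s in DEFAULT_GRID_SECONDS
        )
    )


@dataclass
class WindowedMetricSeries:
    """One pair's windowed metric values (one value per window position)."""

    pair: tuple[int, int]
    metric: MetricId
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class DfcStrengthMatrix:
    """Symmetric matrix of sigma^2 values (diagonal not applicable: NaN)."""

    metric: MetricId
    window: WindowSpec
    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValidationError("strength matrix must be square")

    def upper_triangle(self) -> np.ndarray:
        """Vectorized upper triangle (the n(n-1)/2 distinct pair values)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Vectorized kernels
# ---------------------------------------------------------------------------

def _windowed_pearson_all(data: np.ndarray, w: int) -> np.ndarray:
    """Windowed Pearson correlation for all pairs: shape ``(n, n, L)``."""
    n, T = data.shape
    L = T - w + 1
    X = data - data.mean(axis=1, keepdims=True)  # global centering: stability
    zeros = np.zeros((n, 1))
    cs = np.cumsum(X, axis=1)
    cs = np.hstack([zeros, cs])
    S1 = cs[:, w:] - cs[:, :-w]  # windowed sums, (n, L)
    out = np.empty((n, n, L))
    # windowed sums of products for every unordered pair (incl. diagonal)
    prods = np.einsum("it,jt->ijt", X, X)
    csp = np.concatenate(
        [np.zeros((n, n, 1)), np.cumsum(prods, axis=2)], axis=2
    )
    S2 = csp[:, :, w:] - csp[:, :, :-w]  # (n, n, L)
    mean = S1 / w
    cov = S2 / w - mean[:, None, :] * mean[None, :, :]
    var = np.einsum("iil->il", cov).copy()
    bad = var <= 0
    if np.any(bad):
        i, k = np.argwhere(bad)[0]
        raise DegenerateInputError(
            f"region {i} is constant in window {k}: Pearson undefined"
        )
    denom = np.sqrt(var[:, None, :] * var[None, :, :])
    out = np.clip(cov / denom, -1.0, 1.0)
    return out


def _row_sum_clogc(ids: np.ndarray, log2_table: np.ndarray) -> np.ndarray:
    """Per-row ``sum c*log2(c)`` over run counts of an id matrix.

    ``ids`` has shape ``(R, w)``; each row is one window's cell indices.
    Rows are sorted, runs of equal ids are counted, and the entropy
    numerator ``sum c*log2(c)`` is accumulated per row.
    """
    R, w = ids.shape
    s = np.sort(ids, axis=1)
    flat = s.ravel()
    # singleton runs contribute 0 (1*log2(1)); only duplicates matter, and
    # they are sparse (w samples scattered over up to w^2 cells), so find
    # the duplicate positions first and reconstruct run lengths from them.
    eq = np.empty(flat.size - 1, dtype=bool)
    np.equal(flat[1:], flat[:-1], out=eq)
    eq[w - 1::w] = False  # never merge runs across row boundaries
    dup = np.flatnonzero(eq)
    if dup.size == 0:
        return np.zeros(R)
    brk = np.flatnonzero(np.diff(dup) > 1)
    run_start = np.concatenate([[0], brk + 1])
    run_end = np.concatenate([brk, [dup.size - 1]])
    counts = run_end - run_start + 2  # c-1 consecutive dup positions => c
    clogc = counts * log2_table[counts]
    rows = dup[run_start] // w
    return np.bincount(rows, weights=clogc, minlength=R)


def _windowed_bin_indices(
    data: np.ndarray, w: int, bins: int
) -> np.ndarray:
    """Per-region, per-window bin index of every sample: ``(n, L, w)`` ints.

    Equal-width bins over each window's [min, max]; the maximum falls in
    the last bin (rightmost closed), matching the histogram estimators.
    """
    n, T = data.shape
    view = np.lib.stride_tricks.sliding_window_view(data, w, axis=1)  # (n,L,w)
    lo = view.min(axis=2, keepdims=True)
    hi = view.max(axis=2, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0  # constant window: every sample in bin 0
    dtype = np.int16 if bins * bins < np.iinfo(np.int16).max else np.int32
    idx = np.floor((view - lo) / span * bins).astype(dtype)
    np.clip(idx, 0, bins - 1, out=idx)
    return idx


class _WindowedInfoKernel:
    """Shared state for fast windowed MI/VI over all pairs of a matrix.

    Bins per axis follow the segment bin rule (default: ``w`` bins for a
    length-``w`` window).  Marginal entropies are computed once per region
    and reused across pairs.
    """

    def __init__(self, data: np.ndarray, w: int, config: MetricConfig):
        self.data = np.asarray(data, dtype=float)
        self.w = w
        self.bins = config.n_bins(w)
        n, T = self.data.shape
        self.n = n
        self.L = T - w + 1
        self.log2_table = np.log2(np.arange(1, w + 1))
        self.log2_table = np.concatenate([[0.0], self.log2_table])
        self.idx = _windowed_bin_indices(self.data, w, self.bins)
        self.log2_w = math.log2(w)
        # marginal entropies per region per window, one batched pass
        sc = _row_sum_clogc(
            self.idx.reshape(n * self.L, w), self.log2_table
        ).reshape(n, self.L)
        self.h_marg = self.log2_w - sc / w

    def joint_entropy_pairs(
        self, pairs: list[tuple[int, int]]
    ) -> np.ndarray:
        """Joint entropies for several pairs in one batched pass: (P, L)."""
        P = len(pairs)
        ii = [p[0] for p in pairs]
        jj = [p[1] for p in pairs]
        joint = self.idx[ii] * np.asarray(self.bins, dtype=self.idx.dtype)
        joint += self.idx[jj]
        sc = _row_sum_clogc(
            joint.reshape(P * self.L, self.w), self.log2_table
        ).reshape(P, self.L)
        return self.log2_w - sc / self.w

    def mi_pairs(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        h_joint = self.joint_entropy_pairs(pairs)
        hi = self.h_marg[[p[0] for p in pairs]]
        hj = self.h_marg[[p[1] for p in pairs]]
        return np.maximum(hi + hj - h_joint, 0.0)

    def vi_pairs(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        h_joint = self.joint_entropy_pairs(pairs)
        hi = self.h_marg[[p[0] for p in pairs]]
        hj = self.h_marg[[p[1] for p in pairs]]
        return np.maximum(2.0 * h_joint - hi - hj, 0.0)

    def mi_series(self, i: int, j: int) -> np.ndarray:
        return self.mi_pairs([(i, j)])[0]

    def vi_series(self, i: int, j: int) -> np.ndarray:
        return self.vi_pairs([(i, j)])[0]


def _windowed_mtd_all(
    data: np.ndarray, window: WindowSpec, config: MetricConfig
) -> np.ndarray:
    """All-pairs MTD series with inner half-width from config or window."""
    from .metrics import mtd_series

    w_inner = config.mtd_inner_w
    if w_inner is None:
        w_inner = window.length_samples
    return mtd_series(data, config, w=w_inner)


_FAST_BIVARIATE = {
    MetricId.PEARSON,
    MetricId.MUTUAL_INFORMATION,
    MetricId.VARIATION_OF_INFORMATION,
    MetricId.MTD,
}


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _generic_windowed(
    data: np.ndarray,
    metric: MetricId,
    window: WindowSpec,
    pair: tuple[int, int],
    config: MetricConfig,
) -> np.ndarray:
    n, T = data.shape
    w, step = window.length_samples, window.step_samples
    values = []
    for k in range(0, T - w + 1, step):
        segment = data[:, k:k + w]
        try:
            values.append(metric_value(metric, segment, pair[0], pair[1], config))
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"window index {k}: {exc}"
            ) from exc
    return np.asarray(values)


def windowed_metric(
    ts: RoiTimeSeriesSet,
    metric: MetricId | str,
    window: WindowSpec,
    pair: tuple[int, int],
    config: MetricConfig | None = None,
) -> WindowedMetricSeries:
    """Windowed metric series for one pair of regions.

    Value k is computed on columns ``[k, k + w)``, advancing by
    ``step_samples``.  MTD uses its own centered formulation with inner
    half-width equal to the window length in samples (unless overridden
    via ``config.mtd_inner_w``) and yields its native valid range.
    """
    metric = MetricId(metric)
    config = config or MetricConfig()
    data = ts.data
    n, T = data.shape
    w = window.length_samples
    if w > T:
        raise ValidationError(f"window of {w} samples exceeds T={T}")
    i, j = pair
    if metric is MetricId.MTD:
        w_inner = config.mtd_inner_w or w
        values = mtd_pair_series(data[i], data[j], w_inner, config.mtd_ddof)
        values = values[:: window.step_samples]
    elif metric in _FAST_BIVARIATE and window.step_samples == 1:
        if metric is MetricId.PEARSON:
            values = _windowed_pearson_all(data[[i, j]], w)[0, 1]
        else:
            kernel = _WindowedInfoKernel(data[[i, j]], w, config)
            values = (
                kernel.mi_series(0, 1)
                if metric is MetricId.MUTUAL_INFORMATION
                else kernel.vi_series(0, 1)
            )
    else:
        values = _generic_windowed(data, metric, window, pair, config)
    return WindowedMetricSeries(pair=pair, metric=metric, values=values)


def dfc_strength(series: WindowedMetricSeries | np.ndarray) -> float:
    """Variance of the windowed metric series (the sigma^2 dFC statistic).

    Sample convention (divisor ``count - 1``).  Fewer than two window
    positions raise :class:`InsufficientWindowsError`.
    """
    values = series.values if isinstance(series, WindowedMetricSeries) else series
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientWindowsError(
            f"need >= 2 windowed values, got {values.size}"
        )
    return float(np.var(values, ddof=1))


def dfc_matrix(
    ts: RoiTimeSeriesSet,
    metric: MetricId | str,
    window: WindowSpec,
    config: MetricConfig | None = None,
) -> DfcStrengthMatrix:
    """dFC strength (sigma^2) for every unordered pair, symmetric fill.

    Diagonal entries are NaN (self-connectivity is not a tested quantity).
    """
    metric = MetricId(metric)
    config = config or MetricConfig()
    data = ts.data
    n, T = data.shape
    w = window.length_samples
    if w > T:
        raise ValidationError(f"window of {w} samples exceeds T={T}")
    values = np.full((n, n), np.nan)

    def _fill(i: int, j: int, series: np.ndarray) -> None:
        values[i, j] = values[j, i] = dfc_strength(series)

    step = window.step_samples
    if metric is MetricId.PEARSON and step == 1:
        all_r = _windowed_pearson_all(data, w)
        for i in range(n):
            for j in range(i + 1, n):
                _fill(i, j, all_r[i, j])
    elif metric in (
        MetricId.MUTUAL_INFORMATION, MetricId.VARIATION_OF_INFORMATION
    ) and step == 1:
        kernel = _WindowedInfoKernel(data, w, config)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        fn = (
            kernel.mi_pairs
            if metric is MetricId.MUTUAL_INFORMATION
            else kernel.vi_pairs
        )
        all_series = fn(pairs)
        for (i, j), series in zip(pairs, all_series):
            _fill(i, j, series)
    elif metric is MetricId.MTD:
        all_mtd = _windowed_mtd_all(data, window, config)[:, :, ::step]
        for i in range(n):
            for j in range(i + 1, n):
                _fill(i, j, all_mtd[i, j])
    elif metric is MetricId.ICOV:
        L = T - w + 1
        series = np.empty((n, n, (L + step - 1) // step))
        for out_k, k in enumerate(range(0, L, step)):
            try:
                series[:, :, out_k] = sparse_precision(data[:, k:k + w], config)
            except DegenerateInputError as exc:
                raise DegenerateInputError(f"window index {k}: {exc}") from exc
        for i in range(n):
            for j in range(i + 1, n):
                _fill(i, j, series[i, j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    series = _generic_windowed(data, metric, window, (i, j), config)
                except DegenerateInputError as exc:
                    raise DegenerateInputError(f"pair ({i}, {j}): {exc}") from exc
                _fill(i, j, series)
    return DfcStrengthMatrix(
        metric=metric, window=window, values=values,
        region_labels=list(ts.region_labels),
    )


def cohort_mean_dfc(
    cohort: Cohort,
    metric: MetricId | str,
    window: WindowSpec,
    config: MetricConfig | None = None,
) -> DfcStrengthMatrix:
    """Elementwise mean of per-subject dFC strength matrices."""
    metric = MetricId(metric)
    mats = [dfc_matrix(s, metric, window, config) for s in cohort]
    mean = np.mean([m.values for m in mats], axis=0)
    return DfcStrengthMatrix(
        metric=metric, window=window, values=mean,
        region_labels=cohort.region_labels,
    )


def strength_long_table(
    matrices: dict[str, DfcStrengthMatrix]
):
    """Long-format table of strength matrices keyed by subject id.

    Columns: subject, metric, window_s, region_i, region_j, value.
    """
    import pandas as pd

    rows = []
    for subject, mat in matrices.items():
        labels = mat.region_labels or [
            str(k) for k in range(mat.values.shape[0])
        ]
        n = mat.values.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "subject": subject,
                        "metric": mat.metric.value,
                        "window_s": mat.window.length_seconds,
                        "region_i": labels[i],
                        "region_j": labels[j],
                        "value": mat.values[i, j],
                    }
                )
    return pd.DataFrame(rows)
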