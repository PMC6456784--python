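"""The ten pairwise functional-connectivity metrics.

Linear: Pearson correlation, Pearson partial correlation, L1-penalized
inverse covariance (ICOV / precision).  Nonlinear: Spearman full and
partial correlation, Kendall correlation, mutual information (MI),
variation of information (VI), symmetrized Kullback-Leibler divergence of
the marginal PDFs, and multiplication of temporal derivatives (MTD).

Each metric is computable on an arbitrary data segment.  The information
measures use plug-in histogram estimators with the number of bins equal to
the number of samples in the segment (per axis), reported in bits.

Kendall here follows the literal rule set used in the sliding-window dFC
literature: pairs are concordant/discordant by strict sign agreement,
pairs tied in BOTH coordinates are excluded, and the statistic is
``2(NC - ND) / (N(N-1))``.  With ties in a single coordinate this differs
from the conventional tau-b normalization.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso, ledoit_wolf

from .errors import ConvergenceError, DegenerateInputError, ValidationError

__all__ = [
    "MetricId",
    "MetricConfig",
    "HistogramPdf",
    "pearson_corr",
    "rank_transform",
    "spearman_corr",
    "partial_residuals",
    "pearson_partial",
    "spearman_partial",
    "kendall_corr",
    "marginal_pdf",
    "entropy_bits",
    "mutual_information_bits",
    "variation_of_information_bits",
    "kl_symmetrized_bits",
    "mtd_pair_series",
    "mtd_series",
    "sparse_precision",
    "metric_value",
]


class MetricId(str, Enum):
    """Closed enumeration of the ten supported FC metrics."""

    PEARSON = "pearson"
    PEARSON_PARTIAL = "pearson_partial"
    ICOV = "icov"
    SPEARMAN = "spearman"
    SPEARMAN_PARTIAL = "spearman_partial"
    KENDALL = "kendall"
    MUTUAL_INFORMATION = "mutual_information"
    VARIATION_OF_INFORMATION = "variation_of_information"
    KL_SYMMETRIZED = "kl_symmetrized"
    MTD = "mtd"


#: Metrics that require the full row set of a segment, not just rows i, j.
FULL_ROW_METRICS = frozenset(
    {MetricId.PEARSON_PARTIAL, MetricId.SPEARMAN_PARTIAL, MetricId.ICOV}
)


@dataclass
class MetricConfig:
    """Tunable metric parameters.

    icov_lambda
        L1 penalty of the sparse precision estimate (default 0.1).
    icov_shrinkage
        If True, apply Ledoit-Wolf shrinkage to the sample covariance
        before the L1 solve (default off).
    kl_floor
        Replacement for zero histogram probabilities in the KL log-ratio;
        applied without renormalization so the divergence stays finite.
    mtd_inner_w
        Half-width ``w`` (samples) of MTD's centered averaging window;
        ``None`` means "use the sliding-window length in samples".
    bin_rule
        Histogram bin-count policy for MI/VI/KL: the string ``"n_points"``
        (bins per axis = samples in the segment) or a fixed positive int.
    mtd_ddof
        Delta degrees of freedom for the derivative standard deviation
        (0 = population convention, the default).
    variance_ddof
        Unused here; see :mod:`dynfc.windows`.
    """

    icov_lambda: float = 0.1
    icov_shrinkage: bool = False
    icov_tol: float = 1e-4
    icov_max_iter: int = 1000
    kl_floor: float = 1e-12
    mtd_inner_w: int | None = None
    bin_rule: int | str = "n_points"
    mtd_ddof: int = 0

    def __post_init__(self) -> None:
        if self.icov_lambda < 0:
            raise ValidationError("icov_lambda must be >= 0")
        if not (0.0 < self.kl_floor < 1.0):
            raise ValidationError("kl_floor must lie in (0, 1)")
        if self.mtd_inner_w is not None and self.mtd_inner_w < 1:
            raise ValidationError("mtd_inner_w must be >= 1")
        if isinstance(self.bin_rule, int) and self.bin_rule < 1:
            raise ValidationError("bin_rule int must be >= 1")

    def n_bins(self, n_points: int) -> int:
        return n_points if self.bin_rule == "n_points" else int(self.bin_rule)


@dataclass
class HistogramPdf:
    """A discrete PDF from an equal-width histogram (probabilities sum to 1)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValidationError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(self.probabilities < 0):
            raise ValidationError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Correlation-family metrics
# ---------------------------------------------------------------------------

def _as_1d(x: Sequence[float]) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError("expected a 1-D sequence")
    return a


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson linear correlation of two equal-length sequences."""
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size:
        raise ValidationError("sequences must have equal length")
    if xa.size < 2:
        raise ValidationError("need at least 2 samples")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = np.sqrt(dx @ dx)
    sy = np.sqrt(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("constant input: correlation undefined")
    r = float((dx @ dy) / (sx * sy))
    return min(1.0, max(-1.0, r))


def rank_transform(x: Sequence[float]) -> np.ndarray:
    """Ascending ranks 1..N; tied values get the average of covered ranks."""
    xa = _as_1d(x)
    if xa.size < 1:
        raise ValidationError("need at least 1 sample")
    return stats.rankdata(xa, method="average")


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of the rank vectors."""
    return pearson_corr(rank_transform(x), rank_transform(y))


def partial_residuals(
    X: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of rows i and j after regressing out all other rows.

    Each target row is projected (least squares, with intercept) onto the
    remaining ``n - 2`` rows; the returned residuals are orthogonal to
    every regressor and to the constant.
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if n < 3:
        raise ValidationError("partial metrics need at least 3 regions")
    if N <= n:
        raise ValidationError("need more samples than regions (N > n)")
    if i == j:
        raise ValidationError("i and j must differ")
    others = [k for k in range(n) if k not in (i, j)]
    Z = np.column_stack([np.ones(N)] + [X[k] for k in others])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise DegenerateInputError(
            f"conditioning rows {others} are rank-deficient "
            f"(rank {rank} < {Z.shape[1]} columns incl. intercept)"
        )
    coef, *_ = np.linalg.lstsq(Z, np.column_stack([X[i], X[j]]), rcond=None)
    resid = np.column_stack([X[i], X[j]]) - Z @ coef
    return resid[:, 0], resid[:, 1]


def pearson_partial(X: np.ndarray, i: int, j: int) -> float:
    """Pearson correlation of the partial (regressed-out) residuals."""
    ex, ey = partial_residuals(X, i, j)
    return pearson_corr(ex, ey)


def spearman_partial(X: np.ndarray, i: int, j: int) -> float:
    """Spearman correlation of the partial (regressed-out) residuals."""
    ex, ey = partial_residuals(X, i, j)
    return spearman_corr(ex, ey)


def kendall_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall correlation ``2(NC - ND) / (N(N-1))``.

    Strictly concordant / discordant pairs counted by sign agreement;
    pairs tied in either coordinate contribute zero, so doubly tied pairs
    are excluded automatically.  The denominator is the full pair count.
    """
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size:
        raise ValidationError("sequences must have equal length")
    N = xa.size
    if N < 2:
        raise ValidationError("need at least 2 samples")
    sx = np.sign(xa[:, None] - xa[None, :])
    sy = np.sign(ya[:, None] - ya[None, :])
    s = sx * sy  # +1 concordant, -1 discordant, 0 any tie
    nc_minus_nd = float(np.triu(s, k=1).sum())
    return 2.0 * nc_minus_nd / (N * (N - 1))


# ---------------------------------------------------------------------------
# Histogram / information-theoretic metrics
# ---------------------------------------------------------------------------

def marginal_pdf(x: Sequence[float], n_bins: int) -> HistogramPdf:
    """Equal-width histogram PDF over [min(x), max(x)], rightmost bin closed.

    A constant sequence yields a single unit-width bin with probability 1.
    """
    xa = _as_1d(x)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = float(xa.min()), float(xa.max())
    if lo == hi:
        return HistogramPdf(np.array([lo - 0.5, hi + 0.5]), np.array([1.0]))
    counts, edges = np.histogram(xa, bins=n_bins, range=(lo, hi))
    return HistogramPdf(edges, counts / xa.size)


def entropy_bits(p: HistogramPdf) -> float:
    """Shannon entropy of a histogram PDF in bits (0 log 0 := 0)."""
    probs = p.probabilities[p.probabilities > 0]
    return float(-(probs * np.log2(probs)).sum())


def _joint_counts(
    xa: np.ndarray, ya: np.ndarray, bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint and marginal histogram counts (bins per axis = ``bins``)."""
    # np.histogram2d degenerates when a coordinate is constant; widen range.
    def _range(a: np.ndarray) -> tuple[float, float]:
        lo, hi = float(a.min()), float(a.max())
        return (lo - 0.5, hi + 0.5) if lo == hi else (lo, hi)

    joint, _, _ = np.histogram2d(
        xa, ya, bins=bins, range=[_range(xa), _range(ya)]
    )
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def mutual_information_bits(
    x: Sequence[float], y: Sequence[float], config: MetricConfig | None = None
) -> float:
    """Plug-in mutual information (bits) over the joint histogram.

    Bins per axis follow ``config.bin_rule`` (default: the sample count).
    Cells with zero joint probability contribute zero.
    """
    config = config or MetricConfig()
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size or xa.size < 2:
        raise ValidationError("need equal-length sequences of >= 2 samples")
    N = xa.size
    bins = config.n_bins(N)
    joint, mx, my = _joint_counts(xa, ya, bins)
    nz = joint > 0
    pj = joint[nz] / N
    px = (mx / N)[np.nonzero(nz)[0]]
    py = (my / N)[np.nonzero(nz)[1]]
    mi = float((pj * np.log2(pj / (px * py))).sum())
    return max(0.0, mi)


def variation_of_information_bits(
    x: Sequence[float], y: Sequence[float], config: MetricConfig | None = None
) -> float:
    """Variation of information ``H(X) + H(Y) - 2 I(X,Y)`` in bits.

    All three terms come from the same joint-histogram configuration, so
    the result is nonnegative up to rounding (clamped at zero).
    """
    config = config or MetricConfig()
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size or xa.size < 2:
        raise ValidationError("need equal-length sequences of >= 2 samples")
    N = xa.size
    bins = config.n_bins(N)
    joint, mx, my = _joint_counts(xa, ya, bins)

    def _h(counts: np.ndarray) -> float:
        p = counts[counts > 0] / N
        return float(-(p * np.log2(p)).sum())

    vi = 2.0 * _h(joint.ravel()) - _h(mx) - _h(my)
    return max(0.0, vi)


def kl_symmetrized_bits(
    x: Sequence[float], y: Sequence[float], config: MetricConfig | None = None
) -> float:
    """Symmetrized KL divergence of the two marginal PDFs, in bits.

    Both marginals are estimated on a common set of equal-width bin edges
    spanning the union range; zero probabilities are replaced by
    ``config.kl_floor`` (no renormalization) so the log-ratio stays finite.
    Returns ``(KL(p||q) + KL(q||p)) / 2``.
    """
    config = config or MetricConfig()
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size or xa.size < 2:
        raise ValidationError("need equal-length sequences of >= 2 samples")
    N = xa.size
    bins = config.n_bins(N)
    lo = min(float(xa.min()), float(ya.min()))
    hi = max(float(xa.max()), float(ya.max()))
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(xa, bins=edges)[0] / N
    q = np.histogram(ya, bins=edges)[0] / N
    pf = np.where(p > 0, p, config.kl_floor)
    qf = np.where(q > 0, q, config.kl_floor)
    # directed sums run over bins where the numerator has mass
    kl_pq = float((p * np.log2(pf / qf)).sum())
    kl_qp = float((q * np.log2(qf / pf)).sum())
    return max(0.0, 0.5 * (kl_pq + kl_qp))


# ---------------------------------------------------------------------------
# Multiplication of temporal derivatives
# ---------------------------------------------------------------------------

def _mtd_normalized_derivatives(
    X: np.ndarray, ddof: int = 0
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    dt = np.diff(X, axis=1)
    sd = dt.std(axis=1, ddof=ddof)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise DegenerateInputError(
            f"region(s) {bad.tolist()} have zero derivative standard deviation"
        )
    return dt / sd[:, None]


def mtd_pair_series(
    x: Sequence[float],
    y: Sequence[float],
    w: int,
    ddof: int = 0,
) -> np.ndarray:
    """MTD coupling series for one pair with centered half-width ``w``.

    ``MTD(t) = (1/(2w+1)) * sum_{k=t-w}^{t+w} dt_x(k) dt_y(k) / (s_x s_y)``
    where ``dt`` is the first difference and ``s`` its standard deviation
    over the full series.  Only positions where the centered window fits
    are returned (no padding).
    """
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size:
        raise ValidationError("sequences must have equal length")
    if xa.size < 2 * w + 2:
        raise ValidationError(f"need at least {2 * w + 2} samples for w={w}")
    d = _mtd_normalized_derivatives(np.vstack([xa, ya]), ddof=ddof)
    prod = d[0] * d[1]
    kernel = np.ones(2 * w + 1) / (2 * w + 1)
    return np.convolve(prod, kernel, mode="valid")


def mtd_series(X: np.ndarray, config: MetricConfig | None = None,
               w: int | None = None) -> np.ndarray:
    """All-pairs MTD series: array of shape ``(n, n, L)``.

    ``w`` overrides ``config.mtd_inner_w``; one of the two must be set.
    """
    config = config or MetricConfig()
    if w is None:
        w = config.mtd_inner_w
    if w is None:
        raise ValidationError("MTD inner window w is not set")
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if N < 2 * w + 2:
        raise ValidationError(f"need at least {2 * w + 2} samples for w={w}")
    d = _mtd_normalized_derivatives(X, ddof=config.mtd_ddof)
    kernel = np.ones(2 * w + 1) / (2 * w + 1)
    L = d.shape[1] - 2 * w
    out = np.empty((n, n, L))
    for i in range(n):
        for j in range(i, n):
            series = np.convolve(d[i] * d[j], kernel, mode="valid")
            out[i, j] = out[j, i] = series
    return out


# ---------------------------------------------------------------------------
# Sparse inverse covariance
# ---------------------------------------------------------------------------

def sparse_precision(
    X_segment: np.ndarray, config: MetricConfig | None = None
) -> np.ndarray:
    """L1-penalized maximum-likelihood precision matrix of a segment.

    The sample covariance (population convention) of the rows is fed to a
    graphical-lasso solve at penalty ``config.icov_lambda``; at lambda = 0
    the direct matrix inverse is returned.  With ``config.icov_shrinkage``
    the covariance is first conditioned by Ledoit-Wolf shrinkage.
    The pairwise FC value is the (i, j) off-diagonal entry.
    """
    config = config or MetricConfig()
    X = np.asarray(X_segment, dtype=float)
    n, N = X.shape
    if n < 2:
        raise ValidationError("need at least 2 regions")
    if N < 3:
        raise ValidationError("need at least 3 samples")
    if config.icov_shrinkage:
        cov, _ = ledoit_wolf(X.T, assume_centered=False)
    else:
        cov = np.cov(X, ddof=0)
    if config.icov_lambda == 0.0:
        try:
            return np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular covariance: {exc}") from exc
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", category=UserWarning)
            _, precision = graphical_lasso(
                cov, alpha=config.icov_lambda,
                max_iter=config.icov_max_iter, tol=config.icov_tol,
            )
    except FloatingPointError as exc:
        raise ConvergenceError(
            f"graphical lasso failed at lambda={config.icov_lambda}: {exc}"
        ) from exc
    for warning in caught:
        msg = str(warning.message)
        if "did not converge" not in msg:
            continue
        gap_match = re.search(
            r"[Dd]ual(?:ity)? gap: (-?[\d.]+(?:[eE][+-]?\d+)?)", msg
        )
        gap = abs(float(gap_match.group(1))) if gap_match else np.inf
        # the solver's gap estimate can stall at a small (even negative)
        # value once the primal has stabilized; only a genuinely large
        # residual gap is a failure
        if gap > max(100.0 * config.icov_tol, 1e-2):
            raise ConvergenceError(
                f"graphical lasso did not converge at lambda="
                f"{config.icov_lambda} after {config.icov_max_iter} "
                f"iterations (duality gap {gap:.3g})"
            )
    return precision


# ---------------------------------------------------------------------------
# Uniform dispatch
# ---------------------------------------------------------------------------

def metric_value(
    metric: MetricId | str,
    X_segment: np.ndarray,
    i: int,
    j: int,
    config: MetricConfig | None = None,
) -> float:
    """Evaluate one metric for pair ``(i, j)`` on a data segment.

    Partial metrics and ICOV use the FULL row set of the segment; the
    bivariate metrics use rows ``i`` and ``j`` only.  MTD needs
    ``config.mtd_inner_w`` set and returns the mean of its coupling
    series over the segment (a single representative value; the
    sliding-window layer uses the native series instead).
    """
    metric = MetricId(metric)
    config = config or MetricConfig()
    X = np.asarray(X_segment, dtype=float)
    x, y = X[i], X[j]
    if metric is MetricId.PEARSON:
        return pearson_corr(x, y)
    if metric is MetricId.SPEARMAN:
        return spearman_corr(x, y)
    if metric is MetricId.KENDALL:
        return kendall_corr(x, y)
    if metric is MetricId.PEARSON_PARTIAL:
        return pearson_partial(X, i, j)
    if metric is MetricId.SPEARMAN_PARTIAL:
        return spearman_partial(X, i, j)
    if metric is MetricId.MUTUAL_INFORMATION:
        return mutual_information_bits(x, y, config)
    if metric is MetricId.VARIATION_OF_INFORMATION:
        return variation_of_information_bits(x, y, config)
    if metric is MetricId.KL_SYMMETRIZED:
        return kl_symmetrized_bits(x, y, config)
    if metric is MetricId.ICOV:
        return float(sparse_precision(X, config)[i, j])
    if metric is MetricId.MTD:
        if config.mtd_inner_w is None:
            raise ValidationError("MTD requires config.mtd_inner_w")
        return float(
            mtd_pair_series(x, y, config.mtd_inner_w, config.mtd_ddof).mean()
        )
    raise ValidationError(f"unknown metric {metric!r}")  # pragma: no cover
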