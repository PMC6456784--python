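"""Surrogate data generation under the stationary-connectivity null.

Two multivariate methods are provided:

* **MVPR** (multivariate phase randomization): every region's discrete
  Fourier transform is multiplied by the SAME uniformly random phase
  vector, with Hermitian symmetry imposed so the inverse transform is
  real.  The common phase cancels in every cross-spectrum, so each
  surrogate preserves all per-row amplitude spectra and all pairwise
  (circular) cross-covariances exactly — only phase relationships that
  would make connectivity time-varying are destroyed.

* **MVAR**: a stationary vector autoregressive model of order ``p``
  (chosen by minimizing the Schwarz Bayesian Criterion) is fitted by
  least squares; surrogates are built by seeding with ``p`` consecutive
  original columns and propagating the recursion with residual columns
  resampled uniformly with replacement.  Whole residual columns are drawn
  jointly so contemporaneous residual correlation is preserved.

A property report quantifies how well an ensemble preserves the original
autocovariance, stationary cross-correlation, power spectral density,
cross-power spectral density and amplitude distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeseries import RoiTimeSeriesSet

__all__ = [
    "MvarModel",
    "SurrogateSpec",
    "SurrogateEnsemble",
    "apply_common_phase",
    "mvpr_surrogate",
    "sbc_score",
    "fit_mvar",
    "mvar_surrogate",
    "generate_ensemble",
    "surrogate_property_report",
    "companion_spectral_radius",
]


@dataclass
class SurrogateSpec:
    """How to build a surrogate ensemble.

    method
        ``"MVPR"`` or ``"MVAR"``.
    n_surrogates
        Number of randomized copies per subject (default 250).
    seed
        Root seed; per-surrogate streams are derived by seed-sequence
        spawning so ensembles are order-independent.
    p_max
        Maximum VAR order scanned by the SBC minimization (MVAR only).
    """

    method: str = "MVPR"
    n_surrogates: int = 250
    seed: int = 0
    p_max: int = 20

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in ("MVPR", "MVAR"):
            raise ValidationError("method must be 'MVPR' or 'MVAR'")
        if self.n_surrogates < 1:
            raise ValidationError("n_surrogates must be >= 1")
        if self.p_max < 1:
            raise ValidationError("p_max must be >= 1")


@dataclass
class MvarModel:
    """A fitted order-p vector autoregressive model.

    ``coefficients`` is a list of ``p`` matrices ``A_1..A_p`` (each n x n);
    ``residuals`` holds the n x (T - p) one-step prediction errors and
    ``residual_covariance`` their (population) covariance.  ``sbc_by_order``
    maps every scanned order to its SBC score.
    """

    order_p: int
    coefficients: list[np.ndarray]
    residuals: np.ndarray
    residual_covariance: np.ndarray
    sbc_by_order: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order_p:
            raise ValidationError("need order_p coefficient matrices")
        eigvals = np.linalg.eigvalsh(self.residual_covariance)
        if eigvals.min() < -1e-8:
            raise ValidationError("residual covariance must be PSD")


@dataclass
class SurrogateEnsemble:
    """All surrogate copies generated from one subject."""

    source_subject: str
    method: str
    copies: list[RoiTimeSeriesSet]

    def __len__(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)


# ---------------------------------------------------------------------------
# MVPR
# ---------------------------------------------------------------------------

def apply_common_phase(data: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Multiply every row's rFFT by ``exp(i * phase)`` and invert.

    ``phase`` has one entry per nonnegative frequency (``T // 2 + 1``
    values); the DC entry — and the Nyquist entry for even T — must be 0
    so the inverse transform is real (Hermitian symmetry on the full
    spectrum).  The zero phase vector is the identity transform.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[1]
    n_freq = T // 2 + 1
    phase = np.asarray(phase, dtype=float)
    if phase.size != n_freq:
        raise ValidationError(f"need {n_freq} phases for T={T}")
    if phase[0] != 0.0:
        raise ValidationError("DC phase must be 0")
    if T % 2 == 0 and phase[-1] != 0.0:
        raise ValidationError("Nyquist phase must be 0 for even T")
    spectrum = np.fft.rfft(data, axis=1)
    spectrum *= np.exp(1j * phase)[None, :]
    return np.fft.irfft(spectrum, n=T, axis=1)


def _draw_common_phase(T: int, rng: np.random.Generator) -> np.ndarray:
    n_freq = T // 2 + 1
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_freq)
    phase[0] = 0.0
    if T % 2 == 0:
        phase[-1] = 0.0
    return phase


def mvpr_surrogate(
    ts: RoiTimeSeriesSet, rng: np.random.Generator
) -> RoiTimeSeriesSet:
    """One multivariate phase-randomized copy of a subject's matrix."""
    if ts.n_timepoints < 4:
        raise ValidationError("need T >= 4 for phase randomization")
    phase = _draw_common_phase(ts.n_timepoints, rng)
    return ts.with_data(apply_common_phase(ts.data, phase))


# ---------------------------------------------------------------------------
# MVAR
# ---------------------------------------------------------------------------

def _var_design(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged regressors: targets (T-p, n), design (T-p, n*p)."""
    n, T = X.shape
    Y = X[:, p:].T
    Z = np.hstack([X[:, p - lag:T - lag].T for lag in range(1, p + 1)])
    return Y, Z


def _fit_var_ls(X: np.ndarray, p: int) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Least-squares VAR(p) fit without intercept (data assumed zero-mean).

    Returns (coefficient matrices A_1..A_p, residuals n x (T-p),
    residual covariance with divisor T-p).
    """
    n, T = X.shape
    Y, Z = _var_design(X, p)
    gram = Z.T @ Z
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"near-singular VAR regressor Gram matrix (cond={cond:.3g})"
        )
    B = np.linalg.solve(gram, Z.T @ Y)  # (n*p, n)
    resid = (Y - Z @ B).T  # (n, T-p)
    coeffs = [B[lag * n:(lag + 1) * n, :].T for lag in range(p)]
    sigma = resid @ resid.T / resid.shape[1]
    return coeffs, resid, sigma


def sbc_score(X: np.ndarray, order: int) -> float:
    """Schwarz Bayesian Criterion of a least-squares VAR(order) fit.

    ``ln det(Sigma_p) + ln(T_eff) * p * n^2 / T_eff`` with
    ``T_eff = T - order``; lower is better.
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if T - order <= n * order + 1:
        raise ValidationError(
            f"insufficient samples for order {order}: T-p={T - order} "
            f"<= n*p+1={n * order + 1}"
        )
    _, _, sigma = _fit_var_ls(X, order)
    t_eff = T - order
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValidationError("residual covariance is singular")
    return float(logdet + np.log(t_eff) * order * n * n / t_eff)


def companion_spectral_radius(coefficients: list[np.ndarray]) -> float:
    """Spectral radius of the VAR companion matrix (< 1 means stable)."""
    p = len(coefficients)
    n = coefficients[0].shape[0]
    companion = np.zeros((n * p, n * p))
    companion[:n, :] = np.hstack(coefficients)
    if p > 1:
        companion[n:, :-n] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def fit_mvar(ts: RoiTimeSeriesSet, spec: SurrogateSpec | None = None) -> MvarModel:
    """Fit a VAR model with order chosen by SBC minimization over 1..p_max.

    The fitted values plus residuals reconstruct the input exactly for
    ``t > p``.  A warning is emitted if the fitted model is unstable
    (companion spectral radius >= 1), since surrogates would then not be
    covariance-stationary.
    """
    spec = spec or SurrogateSpec(method="MVAR")
    X = ts.data
    n, T = X.shape
    scores: dict[int, float] = {}
    for p in range(1, spec.p_max + 1):
        if T - p <= n * p + 1:
            break
        scores[p] = sbc_score(X, p)
    if not scores:
        raise ValidationError(
            f"series too short to fit any VAR order up to {spec.p_max}"
        )
    best = min(scores, key=scores.get)
    coeffs, resid, sigma = _fit_var_ls(X, best)
    radius = companion_spectral_radius(coeffs)
    if radius >= 1.0:
        warnings.warn(
            f"fitted VAR({best}) is unstable (spectral radius {radius:.3f}); "
            "surrogates may be non-stationary",
            RuntimeWarning,
            stacklevel=2,
        )
    return MvarModel(
        order_p=best,
        coefficients=coeffs,
        residuals=resid,
        residual_covariance=sigma,
        sbc_by_order=scores,
    )


def mvar_surrogate(
    model: MvarModel, ts: RoiTimeSeriesSet, rng: np.random.Generator
) -> RoiTimeSeriesSet:
    """One residual-resampled VAR surrogate of length T.

    The first ``p`` columns are a uniformly chosen contiguous block of the
    original; subsequent columns follow the fitted recursion driven by
    residual columns drawn uniformly with replacement.
    """
    X = ts.data
    n, T = X.shape
    p = model.order_p
    n_resid = model.residuals.shape[1]
    out = np.empty_like(X)
    t0 = int(rng.integers(0, T - p + 1))  # start of the length-p seed block
    out[:, :p] = X[:, t0:t0 + p]
    draws = rng.integers(0, n_resid, size=T - p)
    eps = model.residuals[:, draws]
    for t in range(p, T):
        acc = eps[:, t - p].copy()
        for lag, A in enumerate(model.coefficients, start=1):
            acc += A @ out[:, t - lag]
        out[:, t] = acc
    return ts.with_data(out)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def generate_ensemble(
    ts: RoiTimeSeriesSet, spec: SurrogateSpec
) -> SurrogateEnsemble:
    """Generate ``spec.n_surrogates`` copies; deterministic given the seed.

    Each surrogate gets its own spawned random stream, so the ensemble is
    identical regardless of generation order.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_surrogates)
    model = fit_mvar(ts, spec) if spec.method == "MVAR" else None
    copies = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        if spec.method == "MVPR":
            copies.append(mvpr_surrogate(ts, rng))
        else:
            copies.append(mvar_surrogate(model, ts, rng))
    return SurrogateEnsemble(
        source_subject=ts.subject_id, method=spec.method, copies=copies
    )


# ---------------------------------------------------------------------------
# Preserved-property report
# ---------------------------------------------------------------------------

def _circular_autocov(data: np.ndarray) -> np.ndarray:
    """Per-row circular autocovariance at all lags (rows centered)."""
    X = data - data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(X, axis=1)
    T = X.shape[1]
    return np.fft.irfft(spec * np.conj(spec), n=T, axis=1) / T


def _circular_crosscov(data: np.ndarray) -> np.ndarray:
    """Circular cross-covariance for all ordered pairs: (n, n, T)."""
    X = data - data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(X, axis=1)
    T = X.shape[1]
    cross = spec[:, None, :] * np.conj(spec[None, :, :])
    return np.fft.irfft(cross, n=T, axis=2) / T


def _psd(data: np.ndarray) -> np.ndarray:
    X = data - data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(X, axis=1)
    return (spec * np.conj(spec)).real / X.shape[1]


def _cross_psd_magnitude(data: np.ndarray) -> np.ndarray:
    X = data - data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(X, axis=1)
    return np.abs(spec[:, None, :] * np.conj(spec[None, :, :])) / X.shape[1]


def _amplitude_profile(data: np.ndarray) -> np.ndarray:
    """Per-row sorted values: the empirical quantile function."""
    return np.sort(data, axis=1)


_PROPERTIES = {
    "autocovariance": _circular_autocov,
    "cross_correlation": _circular_crosscov,
    "psd": _psd,
    "cross_psd_magnitude": _cross_psd_magnitude,
    "amplitude_distribution": _amplitude_profile,
}


def surrogate_property_report(
    ts: RoiTimeSeriesSet, ensemble: SurrogateEnsemble
) -> pd.DataFrame:
    """Discrepancy between original and ensemble-average signal properties.

    For each property the score is the mean absolute deviation between the
    original's property and the ensemble average of the copies' property;
    ``relative`` normalizes by the mean absolute value of the original
    property.  MVPR preserves autocovariance, PSD and cross-PSD magnitude
    exactly (relative discrepancy at numerical noise level).
    """
    if len(ensemble) == 0:
        raise ValidationError("ensemble is empty")
    rows = []
    for name, fn in _PROPERTIES.items():
        original = fn(ts.data)
        mean_copy = np.mean([fn(c.data) for c in ensemble], axis=0)
        mad = float(np.mean(np.abs(original - mean_copy)))
        scale = float(np.mean(np.abs(original)))
        rows.append(
            {
                "property": name,
                "discrepancy": mad,
                "relative": mad / scale if scale > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
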