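"""Data model and I/O for ROI time-series sets and cohorts.

The central container is :class:`RoiTimeSeriesSet`: one subject's
``n_regions x T`` matrix of region-averaged BOLD signals sampled every
``tr_seconds`` seconds.  Rows are regions, columns are time points — this
convention is used everywhere in the package.  A :class:`Cohort` is a list
of such sets sharing region labels, TR and length.

Also provided: an optional zero-phase Butterworth high-pass filter (slow
drift removal; default cutoff 0.0067 Hz, i.e. a 150 s cutoff period) and a
seeded random cohort split for test-retest experiments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ParseError, StructuralError, ValidationError

__all__ = [
    "RoiTimeSeriesSet",
    "Cohort",
    "PreprocessSpec",
    "read_roi_matrix",
    "write_roi_matrix",
    "highpass_filter",
    "split_cohort",
]

DEFAULT_HIGHPASS_HZ = 0.0067  # 1/150 s: removes slow scanner drifts


@dataclass
class RoiTimeSeriesSet:
    """One subject's region-by-time matrix with sampling metadata.

    Parameters
    ----------
    subject_id
        Free-text subject identifier.
    region_labels
        One unique label per region (row).
    tr_seconds
        Repetition time (sampling interval) in seconds; must be positive.
    data
        Real matrix of shape ``(n_regions, T)``; all values finite,
        ``n_regions >= 2`` and ``T >= 2``.
    """

    subject_id: str
    region_labels: list[str]
    tr_seconds: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D regions x time matrix")
        n, T = self.data.shape
        if n < 2:
            raise ValidationError(f"need at least 2 regions, got {n}")
        if T < 2:
            raise ValidationError(f"need at least 2 time points, got {T}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values (NaN/inf)")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        self.region_labels = [str(x) for x in self.region_labels]
        if len(self.region_labels) != n:
            raise ValidationError(
                f"{len(self.region_labels)} labels for {n} regions"
            )
        if len(set(self.region_labels)) != n:
            raise ValidationError("region_labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeriesSet":
        """Copy of this set with ``data`` replaced (shape may not change rows)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class Cohort:
    """A group of subjects sharing region labels, TR and series length."""

    subjects: list[RoiTimeSeriesSet]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("cohort must contain at least one subject")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.region_labels != ref.region_labels:
                raise ValidationError("all subjects must share region_labels")
            if s.tr_seconds != ref.tr_seconds:
                raise ValidationError("all subjects must share tr_seconds")
            if s.n_timepoints != ref.n_timepoints:
                raise ValidationError("all subjects must share T")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].region_labels

    @property
    def tr_seconds(self) -> float:
        return self.subjects[0].tr_seconds

    @property
    def n_regions(self) -> int:
        return self.subjects[0].n_regions

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].n_timepoints


@dataclass
class PreprocessSpec:
    """Optional temporal preprocessing: high-pass cutoff in Hz (None = skip)."""

    highpass_cutoff_hz: float | None = DEFAULT_HIGHPASS_HZ

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz is not None and self.highpass_cutoff_hz <= 0:
            raise ValidationError("highpass_cutoff_hz must be positive or None")


def _generated_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


def read_roi_matrix(
    path: str | Path,
    tr_seconds: float,
    delimiter: str = "\t",
    subject_id: str | None = None,
) -> RoiTimeSeriesSet:
    """Read a delimited region-by-time matrix into a :class:`RoiTimeSeriesSet`.

    One region per row, one time point per column.  If the first column of
    every row fails numeric parsing it is treated as a label column;
    otherwise labels ``R01..Rnn`` are generated.  Ragged rows raise
    :class:`StructuralError`; a non-numeric cell outside the label column
    raises :class:`ParseError` naming the offending row and column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    if not rows:
        raise StructuralError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise StructuralError(
            f"{path}: ragged rows (column counts {sorted(widths)})"
        )

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
        except ValueError:
            return False
        return True

    has_labels = all(not _is_number(r[0]) for r in rows)
    first_col = 1 if has_labels else 0
    labels = [r[0].strip() for r in rows] if has_labels else _generated_labels(len(rows))

    data = np.empty((len(rows), len(rows[0]) - first_col), dtype=float)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row[first_col:]):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {i + 1}, "
                    f"column {j + 1 + first_col}"
                ) from None
    return RoiTimeSeriesSet(
        subject_id=subject_id if subject_id is not None else path.stem,
        region_labels=labels,
        tr_seconds=tr_seconds,
        data=data,
    )


def write_roi_matrix(
    ts: RoiTimeSeriesSet,
    path: str | Path,
    delimiter: str = "\t",
    labels: bool = True,
) -> None:
    """Write the matrix in the same dialect; values at 17 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(ts.n_regions):
            cells = [f"{v:.17g}" for v in ts.data[i]]
            if labels:
                cells.insert(0, ts.region_labels[i])
            fh.write(delimiter.join(cells) + "\n")


def highpass_filter(
    ts: RoiTimeSeriesSet, spec: PreprocessSpec | None = None
) -> RoiTimeSeriesSet:
    """Zero-phase high-pass filter applied identically to every region row.

    A 2nd-order Butterworth high-pass is run forward and backward
    (``sosfiltfilt``), giving an effective 4th-order zero-phase response:
    the squared magnitude of the designed filter.  Returns a new set.
    """
    if spec is None:
        spec = PreprocessSpec()
    if spec.highpass_cutoff_hz is None:
        return ts.with_data(ts.data.copy())
    fs = 1.0 / ts.tr_seconds
    nyquist = fs / 2.0
    if spec.highpass_cutoff_hz >= nyquist:
        raise ValidationError(
            f"cutoff {spec.highpass_cutoff_hz} Hz >= Nyquist {nyquist} Hz"
        )
    sos = signal.butter(2, spec.highpass_cutoff_hz, btype="highpass", fs=fs,
                        output="sos")
    if ts.n_timepoints < 3 * 2:
        raise ValidationError("series too short for the high-pass filter")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return ts.with_data(filtered)


def split_cohort(
    cohort: Cohort,
    fractions: Sequence[float] = (0.5, 0.5),
    seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Random disjoint, exhaustive two-way split of a cohort.

    Deterministic for a fixed seed.  ``fractions`` must be two positive
    reals summing to 1; group sizes are ``round(f1 * n)`` and the rest.
    """
    if len(fractions) != 2 or any(f <= 0 for f in fractions):
        raise ValidationError("fractions must be two positive reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1 within 1e-9")
    n = len(cohort)
    if n < 2:
        raise ValidationError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    k = int(round(fractions[0] * n))
    k = min(max(k, 1), n - 1)  # both groups non-empty
    idx_a = sorted(order[:k].tolist())
    idx_b = sorted(order[k:].tolist())
    return (
        Cohort([cohort.subjects[i] for i in idx_a]),
        Cohort([cohort.subjects[i] for i in idx_b]),
    )
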