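"""Per-subject time-course conditioning.

Cleans region/component time courses before windowed connectivity is
computed: drop initial volumes, remove polynomial trends, regress out the
six rigid-body realignment parameters, despike, and low-pass filter.

All operations act column-wise (one column per region) and return a new
:class:`TimecourseMatrix`; inputs are never modified in place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class TimecourseMatrix:
    """One subject's region time courses.

    Parameters
    ----------
    values : ndarray, shape (n_timepoints, n_regions)
        Signal matrix, one column per region/component.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    subject_id : str
        Subject label.
    region_ids : tuple of str
        Ordered region labels, one per column.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = "subject"
    region_ids: tuple = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x regions)")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)
        if self.region_ids is None:
            object.__setattr__(
                self, "region_ids", tuple(f"r{i}" for i in range(v.shape[1]))
            )
        else:
            object.__setattr__(self, "region_ids", tuple(self.region_ids))
        if len(self.region_ids) != v.shape[1]:
            raise ValueError("region_ids length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MotionParameters:
    """Six rigid-body realignment parameters (SPM ``rp_*.txt`` layout:
    three translations in mm, three rotations in rad), one row per volume."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError("motion parameters must have shape (timepoints, 6)")
        if not np.all(np.isfinite(v)):
            raise ValueError("motion parameters contain non-finite entries")
        object.__setattr__(self, "values", v)


def _poly_basis(n: int, max_degree: int) -> np.ndarray:
    # time axis scaled to [-1, 1] for numerical conditioning
    t = np.linspace(-1.0, 1.0, n)
    return np.vander(t, max_degree + 1, increasing=True)


def drop_initial_volumes(tc: TimecourseMatrix, n_drop: int) -> TimecourseMatrix:
    """Remove the first ``n_drop`` timepoints (dummy/equilibration volumes)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= tc.n_timepoints:
        raise ValueError(
            f"n_drop={n_drop} leaves no data (have {tc.n_timepoints} timepoints)"
        )
    return replace(tc, values=tc.values[n_drop:])


def detrend_polynomial(tc: TimecourseMatrix, max_degree: int = 3) -> TimecourseMatrix:
    """Subtract the least-squares polynomial fit (intercept .. ``max_degree``)
    from every region. Residuals are orthogonal to the basis."""
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    n = tc.n_timepoints
    if n <= max_degree + 1:
        raise ValueError("not enough timepoints for the requested degree")
    X = _poly_basis(n, max_degree)
    beta, *_ = np.linalg.lstsq(X, tc.values, rcond=None)
    return replace(tc, values=tc.values - X @ beta)


def regress_nuisance(tc: TimecourseMatrix, motion: MotionParameters) -> TimecourseMatrix:
    """Regress the six realignment parameters (plus intercept) out of every
    region and keep the residuals. A rank-deficient design is handled by the
    pseudoinverse with a warning."""
    if motion.values.shape[0] != tc.n_timepoints:
        raise ValueError(
            "motion rows must equal timepoints "
            f"({motion.values.shape[0]} != {tc.n_timepoints})"
        )
    X = np.column_stack([np.ones(tc.n_timepoints), motion.values])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudoinverse")
    beta = np.linalg.pinv(X) @ tc.values
    return replace(tc, values=tc.values - X @ beta)


def despike(tc: TimecourseMatrix, c1: float = 2.5, c2: float = 4.0) -> TimecourseMatrix:
    """Soft-clip outliers region by region.

    A cubic baseline is fitted per region; the robust scale ``s`` of the
    residuals is the median absolute deviation scaled to the Gaussian
    (1.4826 x MAD). Residuals ``r`` with ``|r| > c1*s`` are compressed to::

        sign(r) * s * (c1 + (c2 - c1) * tanh((|r|/s - c1) / (c2 - c1)))

    so the output never exceeds ``c2*s`` above baseline; residuals at or
    below ``c1*s`` pass through unchanged (the compressor is continuous at
    the threshold). A region with zero MAD is returned unchanged.
    """
    if not (c2 > c1 > 0):
        raise ValueError("need c2 > c1 > 0")
    n = tc.n_timepoints
    X = _poly_basis(n, 3)
    beta, *_ = np.linalg.lstsq(X, tc.values, rcond=None)
    baseline = X @ beta
    r = tc.values - baseline
    out = tc.values.copy()
    for j in range(tc.n_regions):
        rj = r[:, j]
        s = 1.4826 * np.median(np.abs(rj - np.median(rj)))
        if s == 0.0:
            continue
        a = np.abs(rj) / s
        mask = a > c1
        if not mask.any():
            continue
        comp = np.sign(rj[mask]) * s * (
            c1 + (c2 - c1) * np.tanh((a[mask] - c1) / (c2 - c1))
        )
        out[mask, j] = baseline[mask, j] + comp
    return replace(tc, values=out)


def lowpass_filter(tc: TimecourseMatrix, cutoff_hz: float = 0.15) -> TimecourseMatrix:
    """Zero-phase low-pass filter (forward-backward 5th-order Butterworth).

    With TR = 2 s the Nyquist frequency is 0.25 Hz; the default 0.15 Hz
    cutoff keeps the slow BOLD-range fluctuations and removes
    high-frequency residual noise.
    """
    nyquist = 1.0 / (2.0 * tc.tr_seconds)
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    b, a = signal.butter(5, cutoff_hz / nyquist, btype="low")
    filtered = signal.filtfilt(b, a, tc.values, axis=0)
    return replace(tc, values=filtered)


def center_columns(tc: TimecourseMatrix) -> TimecourseMatrix:
    """Remove each region's mean (covariance downstream is mean-invariant)."""
    return replace(tc, values=tc.values - tc.values.mean(axis=0))


def condition(
    tc: TimecourseMatrix,
    motion: MotionParameters | None = None,
    n_drop: int = 10,
    max_degree: int = 3,
    despike_c1: float = 2.5,
    despike_c2: float = 4.0,
    cutoff_hz: float = 0.15,
) -> TimecourseMatrix:
    """Full conditioning chain in fixed order: drop volumes, detrend,
    nuisance regression, despike, low-pass filter, mean-center.

    ``motion`` may have as many rows as the raw input (its first ``n_drop``
    rows are dropped alongside) or as the post-drop data.
    """
    raw_n = tc.n_timepoints
    tc = drop_initial_volumes(tc, n_drop)
    tc = detrend_polynomial(tc, max_degree)
    if motion is not None:
        m = motion.values
        if m.shape[0] == raw_n:
            m = m[n_drop:]
        if m.shape[0] != tc.n_timepoints:
            raise ValueError("motion rows match neither raw nor dropped length")
        # detrend the regressors with the same basis so the sequential
        # residual is exactly orthogonal to the combined trend+motion design
        # (Frisch-Waugh-Lovell)
        X = _poly_basis(m.shape[0], max_degree)
        beta, *_ = np.linalg.lstsq(X, m, rcond=None)
        m_detrended = m - X @ beta
        if np.abs(m_detrended).max() > 0:
            tc = regress_nuisance(tc, MotionParameters(m_detrended))
    tc = despike(tc, despike_c1, despike_c2)
    tc = lowpass_filter(tc, cutoff_hz)
    return center_columns(tc)
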