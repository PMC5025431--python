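"""Tapered sliding-window connectivity and graphical-lasso regularization.

The window is a rectangle of ``width_tr`` TRs convolved with a Gaussian of
standard deviation ``gaussian_sigma_tr`` TRs, truncated back to the
rectangle's length and normalized to sum one. It slides in steps of one TR;
``n_timepoints`` conditioned timepoints yield ``n_timepoints - width_tr``
windows (170 timepoints, width 22 -> 148 windows). Each window produces a
weighted Pearson correlation matrix over all region pairs; the series can
then be regularized per subject with the graphical lasso, the L1 penalty
chosen by held-out log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.covariance import graphical_lasso

from .conditioning import TimecourseMatrix


@dataclass(frozen=True)
class TaperedWindow:
    """Normalized taper weights plus the parameters that built them."""

    weights: np.ndarray
    width_tr: int
    gaussian_sigma_tr: float
    step_tr: int = 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != self.width_tr:
            raise ValueError("weights must be a vector of length width_tr")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)


def make_taper(width_tr: int = 22, gaussian_sigma_tr: float = 3.0) -> TaperedWindow:
    """Build the tapered window: rectangle (*) Gaussian, truncated, normalized.

    The Gaussian kernel is discretized on integer offsets out to
    ``ceil(3 sigma)``; the full convolution is truncated to the central
    ``width_tr`` samples so the nominal window width is preserved, then
    normalized to sum one.
    """
    if width_tr < 2:
        raise ValueError("width_tr must be >= 2")
    if gaussian_sigma_tr <= 0:
        raise ValueError("gaussian_sigma_tr must be positive")
    rect = np.ones(width_tr)
    radius = int(math.ceil(3.0 * gaussian_sigma_tr))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / gaussian_sigma_tr) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(rect, kernel)  # length width_tr + 2*radius
    w = full[radius : radius + width_tr]  # central width_tr samples
    w /= w.sum()
    return TaperedWindow(weights=w, width_tr=width_tr, gaussian_sigma_tr=gaussian_sigma_tr)


def count_windows(n_timepoints: int, window: TaperedWindow) -> int:
    """Number of sliding windows: ``n_timepoints - width_tr`` (step 1).

    Window starts are offsets ``0 .. n_timepoints - width_tr - 1``; the
    final timepoint is unused. This is the convention under which 170
    timepoints and width 22 give exactly 148 windows.
    """
    if n_timepoints <= window.width_tr:
        raise ValueError(
            f"need more than width_tr={window.width_tr} timepoints, got {n_timepoints}"
        )
    return n_timepoints - window.width_tr


@dataclass(frozen=True)
class WindowedConnectivitySeries:
    """Ordered stack of symmetric connectivity matrices, one per window.

    ``kind`` is ``"correlation"`` for weighted Pearson matrices and
    ``"regularized_precision_derived"`` after graphical-lasso
    regularization. ``lambda_used`` records the selected L1 penalty (None
    before regularization).
    """

    matrices: np.ndarray  # (n_windows, n_regions, n_regions)
    kind: str
    window_starts: np.ndarray
    subject_id: str = "subject"
    lambda_used: float | None = None
    region_ids: tuple = field(default=None)

    def __post_init__(self):
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (n_windows, R, R)")
        if np.max(np.abs(m - m.transpose(0, 2, 1))) > 1e-8:
            raise ValueError("matrices must be symmetric")
        object.__setattr__(self, "matrices", m)
        object.__setattr__(self, "window_starts", np.asarray(self.window_starts, dtype=int))
        if self.window_starts.size != m.shape[0]:
            raise ValueError("window_starts must match number of matrices")
        if self.region_ids is None:
            object.__setattr__(
                self, "region_ids", tuple(f"r{i}" for i in range(m.shape[1]))
            )
        else:
            object.__setattr__(self, "region_ids", tuple(self.region_ids))

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


def windowed_correlation(
    tc: TimecourseMatrix, window: TaperedWindow
) -> WindowedConnectivitySeries:
    """Weighted Pearson correlation in every sliding window.

    Within a window at offset ``o`` the taper weights ``w`` define weighted
    mean, variance and covariance; the correlation is their normalized
    ratio. A region with zero weighted variance in a window gets zero
    correlations (with a warning); diagonals are one.
    """
    n_w = count_windows(tc.n_timepoints, window)
    w = window.weights
    width = window.width_tr
    R = tc.n_regions
    mats = np.empty((n_w, R, R))
    degenerate = 0
    for o in range(n_w):
        X = tc.values[o : o + width]
        mu = w @ X
        Xc = X - mu
        C = Xc.T @ (Xc * w[:, None])  # weighted covariance
        d = np.sqrt(np.diag(C))
        bad = d <= 0
        if bad.any():
            degenerate += 1
            d = np.where(bad, 1.0, d)
        corr = C / np.outer(d, d)
        if bad.any():
            corr[bad, :] = 0.0
            corr[:, bad] = 0.0
        np.fill_diagonal(corr, 1.0)
        corr = np.clip(corr, -1.0, 1.0)
        mats[o] = 0.5 * (corr + corr.T)
    if degenerate:
        warnings.warn(
            f"{degenerate} window(s) had a zero-variance region; "
            "correlations set to 0 there"
        )
    return WindowedConnectivitySeries(
        matrices=mats,
        kind="correlation",
        window_starts=np.arange(n_w),
        subject_id=tc.subject_id,
        region_ids=tc.region_ids,
    )


def _default_lambda_grid() -> np.ndarray:
    return 10.0 ** np.linspace(-3.0, 0.5, 8)


@dataclass(frozen=True)
class GraphicalLassoConfig:
    """L1-penalty grid and selection rule for the graphical lasso."""

    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    selection: str = "held_out_loglik"  # or "fixed"
    fixed_lambda: float = 0.1
    convergence_tol: float = 1e-4
    max_iter: int = 200
    max_holdout_windows: int = 20

    def __post_init__(self):
        g = np.asarray(self.lambda_grid, dtype=float)
        if g.size == 0 or (np.diff(g) <= 0).any() or (g < 0).any():
            raise ValueError("lambda_grid must be non-empty, positive, strictly increasing")
        object.__setattr__(self, "lambda_grid", g)
        if self.selection not in ("held_out_loglik", "fixed"):
            raise ValueError("selection must be 'held_out_loglik' or 'fixed'")


def _glasso_cov(S: np.ndarray, lam: float, tol: float, max_iter: int) -> np.ndarray:
    """Graphical-lasso covariance estimate at penalty ``lam``.

    At lam == 0 the penalized MLE given an empirical covariance is that
    covariance itself, so the input is returned unchanged.
    """
    if lam == 0.0:
        return S.copy()
    cov, _prec = graphical_lasso(S, alpha=lam, tol=tol, max_iter=max_iter)
    return cov


def _gauss_loglik(S_test: np.ndarray, cov_model: np.ndarray) -> float:
    """Gaussian log-likelihood (per sample, up to constants) of a test
    covariance under a model covariance: log det(P) - tr(S P)."""
    prec = np.linalg.inv(cov_model)
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return -np.inf
    return logdet - float(np.trace(S_test @ prec))


def select_lambda(
    series: WindowedConnectivitySeries, cfg: GraphicalLassoConfig
) -> tuple[float, dict]:
    """Select the L1 penalty by leave-one-window-out log-likelihood.

    Over a subsample of at most ``max_holdout_windows`` evenly spaced
    windows: for each held-out window, fit the graphical lasso to the mean
    of the remaining subsampled matrices and evaluate the held-out window's
    Gaussian log-likelihood; the penalty maximizing the mean held-out
    log-likelihood wins. Penalties where the solver fails are dropped with
    a warning.
    """
    n_w = series.n_windows
    n_hold = min(cfg.max_holdout_windows, n_w)
    idx = np.unique(np.linspace(0, n_w - 1, n_hold).astype(int))
    sub = series.matrices[idx]
    scores: dict[float, float] = {}
    for lam in cfg.lambda_grid:
        lls = []
        try:
            for i in range(len(idx)):
                S_train = np.delete(sub, i, axis=0).mean(axis=0) if len(idx) > 1 else sub[0]
                cov = _glasso_cov(S_train, float(lam), cfg.convergence_tol, cfg.max_iter)
                lls.append(_gauss_loglik(sub[i], cov))
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"graphical lasso failed at lambda={lam:g}: {exc}; dropped")
            continue
        scores[float(lam)] = float(np.mean(lls))
    if not scores:
        raise RuntimeError("graphical lasso failed at every lambda in the grid")
    best = max(scores, key=scores.get)
    return best, scores


def regularize_series(
    series: WindowedConnectivitySeries, cfg: GraphicalLassoConfig | None = None
) -> WindowedConnectivitySeries:
    """Replace every window's matrix by its graphical-lasso covariance
    estimate at a single per-subject penalty (selected by held-out
    log-likelihood unless ``cfg.selection == "fixed"``)."""
    if cfg is None:
        cfg = GraphicalLassoConfig()
    if cfg.selection == "fixed":
        lam = float(cfg.fixed_lambda)
    else:
        lam, _ = select_lambda(series, cfg)
    out = np.empty_like(series.matrices)
    for i in range(series.n_windows):
        out[i] = _glasso_cov(series.matrices[i], lam, cfg.convergence_tol, cfg.max_iter)
        out[i] = 0.5 * (out[i] + out[i].T)
    return replace(
        series, matrices=out, kind="regularized_precision_derived", lambda_used=lam
    )
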