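"""Sinusoidal and FIR GLMs for periodic BOLD responses.

Raw run timeseries are first expressed as %BOLD relative to the run mean.
Per voxel and run, an ordinary least-squares fit of a sine/cosine pair at
the stimulus frequency (plus constant baseline and linear drift nuisance
regressors, censoring the initial cycles) yields a complex *response
vector* ``z = sin_coef + 1j * cos_coef``: its modulus is half the
peak-to-peak response amplitude (%BOLD) and its angle the response phase.
Apparent delay is the fitted peak time minus cycle/4 (mid-ON), wrapped to
[0, cycle).

A model-free variant replaces the sine/cosine pair with 11 delta (FIR)
regressors covering cycle positions t0+1 .. t0+11; the signal at t0 is
absorbed by the baseline, so the reconstructed 12-point cycle waveform is
zero there by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .design import StudyDesign

__all__ = [
    "to_percent_bold",
    "fit_sincos",
    "fit_fir",
    "phase_to_delay",
    "delay_to_phase",
    "wrap_delay_difference",
    "circular_mean_vector",
    "normalize_hr_display",
    "SinCosGLM",
    "FIRGLM",
]


def to_percent_bold(raw: np.ndarray) -> np.ndarray:
    """Express a run timeseries as %BOLD relative to the run mean.

    ``out(v, t) = 100 * (raw(v, t) - mean_t) / mean_t`` per voxel; the
    output has zero temporal mean.  Voxels with non-positive run mean are
    returned as NaN columns (flagged, excluded downstream) with a warning.

    Parameters
    ----------
    raw : ndarray, shape (n_volumes, n_voxels) or (n_volumes,)
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    if squeeze:
        raw = raw[:, None]
    mean = raw.mean(axis=0)
    bad = mean <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxel(s) with non-positive run mean flagged as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(bad, 1.0, mean)
    out = 100.0 * (raw - mean) / safe
    out[:, bad] = np.nan
    return out[:, 0] if squeeze else out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = [names[i] for i in np.flatnonzero(norms == 0)]
        raise np.linalg.LinAlgError(f"design matrix has zero columns: {bad}")
    R = np.linalg.qr(X / norms, mode="r")
    small = np.abs(np.diag(R)) < 1e-10
    if small.any():
        bad = [names[i] for i in np.flatnonzero(small)]
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix; collinear columns: {bad}"
        )


class _RetainedOLS:
    """OLS on the retained (non-censored) rows of a fixed design matrix."""

    def __init__(self, design: StudyDesign, interest: np.ndarray, names: list[str]):
        keep = design.censor_mask()
        t = design.run_times()[keep]
        # drift uses the volume index centered on retained rows, removing
        # baseline/drift collinearity
        drift = t - t.mean()
        X = np.column_stack([interest[keep], np.ones(t.size), drift])
        names = names + ["baseline", "drift"]
        if keep.sum() < 2 * X.shape[1]:
            raise ValueError(
                "retained rows must be at least twice the number of model columns"
            )
        _check_rank(X, names)
        self.keep = keep
        self.X = X
        self.names = names
        self.pinv = np.linalg.pinv(X)
        self.n_interest = interest.shape[1]

    def coefficients(self, ts: np.ndarray) -> np.ndarray:
        """All OLS coefficients, shape (n_columns, n_voxels)."""
        ts = np.atleast_2d(np.asarray(ts, dtype=float))
        if ts.shape[0] != self.keep.size:
            raise ValueError(
                f"expected {self.keep.size} volumes, got {ts.shape[0]}"
            )
        return self.pinv @ ts[self.keep]


class SinCosGLM(TransformerMixin, BaseEstimator):
    """Per-run sinusoidal response-vector estimator (stateless transformer).

    ``transform`` maps %BOLD run timeseries to complex response vectors
    ``sin_coef + 1j * cos_coef``.

    Parameters
    ----------
    design : StudyDesign
    """

    def __init__(self, design: StudyDesign | None = None):
        self.design = design

    def _build(self) -> _RetainedOLS:
        design = self.design or StudyDesign()
        t = design.run_times()
        w = 2.0 * np.pi / design.cycle_seconds
        interest = np.column_stack([np.sin(w * t), np.cos(w * t)])
        return _RetainedOLS(design, interest, ["sin", "cos"])

    def fit(self, X=None, y=None) -> "SinCosGLM":
        self.ols_ = self._build()
        self.n_regressors_of_interest_ = 2
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Fit each run.

        Parameters
        ----------
        X : ndarray, (n_volumes, n_voxels) or (n_runs, n_volumes, n_voxels)
            %BOLD timeseries.

        Returns
        -------
        ndarray of complex, (n_voxels,) or (n_runs, n_voxels)
        """
        if not hasattr(self, "ols_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return np.stack([self.transform(run) for run in X])
        beta = self.ols_.coefficients(X)
        return beta[0] + 1j * beta[1]

    def nuisance(self, X: np.ndarray) -> np.ndarray:
        """Baseline and drift coefficients, shape (2, n_voxels)."""
        if not hasattr(self, "ols_"):
            self.fit()
        return self.ols_.coefficients(np.asarray(X, dtype=float))[2:]


class FIRGLM(TransformerMixin, BaseEstimator):
    """Model-free (FIR) hemodynamic-response estimator.

    Uses one delta regressor per cycle position t0+1 .. t0+(P-1) (11 for
    the default 12-volume cycle); the response at t0 is implicitly modeled
    by the baseline.  ``transform`` returns the reconstructed cycle
    waveform with a leading structural zero.
    """

    def __init__(self, design: StudyDesign | None = None):
        self.design = design

    def fit(self, X=None, y=None) -> "FIRGLM":
        design = self.design or StudyDesign()
        P = design.volumes_per_cycle
        pos = np.arange(design.n_volumes) % P
        interest = np.stack([(pos == k).astype(float) for k in range(1, P)], axis=1)
        self.ols_ = _RetainedOLS(
            design, interest, [f"fir_{k}" for k in range(1, P)]
        )
        self.n_regressors_of_interest_ = P - 1
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Reconstructed HR waveforms.

        Returns
        -------
        ndarray, (n_voxels, P) or (n_runs, n_voxels, P) with [..., 0] == 0.
        """
        if not hasattr(self, "ols_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return np.stack([self.transform(run) for run in X])
        beta = self.ols_.coefficients(X)
        amps = beta[: self.n_regressors_of_interest_].T  # (n_voxels, P-1)
        zero = np.zeros((amps.shape[0], 1))
        return np.concatenate([zero, amps], axis=1)


# ----------------------------------------------------------------------
# module-level wrappers

def fit_sincos(ts: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Complex response vector(s) from one %BOLD run (see :class:`SinCosGLM`)."""
    return SinCosGLM(design).fit().transform(ts)


def fit_fir(ts: np.ndarray, design: StudyDesign) -> np.ndarray:
    """FIR waveform(s) from one %BOLD run (see :class:`FIRGLM`)."""
    return FIRGLM(design).fit().transform(ts)


# ----------------------------------------------------------------------
# phase / delay conventions

def phase_to_delay(vectors: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Apparent delay (s) of response vectors, in [0, cycle).

    The fitted sinusoid ``a*sin(wt) + b*cos(wt)`` peaks at
    ``t_peak = (T/4 - angle(z) * T / 2pi) mod T`` with ``z = a + ib``;
    delay is ``(t_peak - T/4) mod T`` (peak time minus mid-ON).  Larger
    delay = later peak.

    Raises
    ------
    ValueError
        If any vector has zero amplitude (undefined delay).
    """
    z = np.asarray(vectors, dtype=complex)
    if np.any(np.abs(z) == 0):
        raise ValueError("delay is undefined for zero-amplitude response vectors")
    T = design.cycle_seconds
    d = np.mod(-np.angle(z) * T / (2.0 * np.pi), T)
    # values a rounding error short of T wrap to 0 (delay lives on a circle)
    d = np.where(T - d < T * 1e-12, 0.0, d)
    return d if np.ndim(vectors) else float(d)


def delay_to_phase(delay_seconds: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Inverse of :func:`phase_to_delay` (angle of the unit response vector)."""
    T = design.cycle_seconds
    return -2.0 * np.pi * np.asarray(delay_seconds, dtype=float) / T


def wrap_delay_difference(diff_seconds: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Wrap a delay difference to (-cycle/2, cycle/2]."""
    T = design.cycle_seconds
    return T / 2.0 - np.mod(T / 2.0 - np.asarray(diff_seconds, dtype=float), T)


def circular_mean_vector(vectors: np.ndarray, axis=None) -> np.ndarray:
    """Complex (vector) mean — the only permitted way to average responses
    across runs/voxels before taking amplitudes or delays."""
    return np.mean(np.asarray(vectors, dtype=complex), axis=axis)


# ----------------------------------------------------------------------
def normalize_hr_display(
    hr: np.ndarray,
    participant_vector: complex,
    group_vector: complex,
    design: StudyDesign,
) -> np.ndarray:
    """Remove a participant's amplitude and delay from an HR waveform
    (display only; never feeds statistics).

    The zero-centered waveform is rescaled by |group| / |participant| and
    its time axis circularly shifted by the participant-minus-group delay
    difference using periodic cubic interpolation, so participants'
    waveform shapes can be overlaid.

    Parameters
    ----------
    hr : ndarray, shape (P,) or (n, P)
        Cycle waveforms sampled at the P volume positions.
    """
    pz = complex(participant_vector)
    gz = complex(group_vector)
    if abs(pz) == 0:
        raise ValueError("participant vector amplitude must be > 0")
    if abs(gz) == 0:
        raise ValueError("group vector amplitude must be > 0")
    hr = np.asarray(hr, dtype=float)
    P = design.volumes_per_cycle
    if hr.shape[-1] != P:
        raise ValueError(f"expected waveforms of length {P}")
    scaled = hr * (abs(gz) / abs(pz))

    d_p = float(phase_to_delay(pz, design))
    d_g = float(phase_to_delay(gz, design))
    dt = float(wrap_delay_difference(d_p - d_g, design))

    t = np.arange(P) * design.tr_seconds
    t_periodic = np.append(t, design.cycle_seconds)

    def shift_one(w: np.ndarray) -> np.ndarray:
        spline = CubicSpline(t_periodic, np.append(w, w[0]), bc_type="periodic")
        return spline(np.mod(t + dt, design.cycle_seconds))

    if scaled.ndim == 1:
        return shift_one(scaled)
    return np.stack([shift_one(w) for w in scaled])
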