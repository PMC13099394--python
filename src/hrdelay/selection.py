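"""Four-stage voxel feature-selection cascade, computed per session.

A. *Stimulus representation*: voxel response polarity (positive when the
   phase lags within -pi/2 .. +pi/2 of the ROI-averaged response) mapped
   into visual-field space, density-uniformized along eccentricity,
   kernel-smoothed, and thresholded inside the stimulus annulus.
B. *Stimulus-driven voxels*: one-sample Hotelling T-squared test of the
   mean response vector against the origin (the "intercept" of a
   multivariate ANOVA on the 2D vector coordinates), alpha = 0.05,
   uncorrected.
C. *Non-vein voxels*: the vein-likeliness metric — SD of the detrended
   raw (not %BOLD) timeseries over its baseline — thresholded at the 80th
   percentile of voxels passing A and B; voxels strictly below pass.
D. *Most discriminant voxels*: Hotelling-Lawley condition statistic
   thresholded at its 20th percentile over voxels passing A-C; voxels
   strictly above pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .design import StudyDesign
from .glm import SinCosGLM, to_percent_bold

__all__ = [
    "classify_polarity",
    "refine_stimulus_representation",
    "hotelling_intercept",
    "condition_t2",
    "test_voxel_multivariate",
    "vein_metric",
    "percentile_cut",
    "apply_percentile_filters",
    "SessionVoxelSelector",
    "SelectionMask",
    "fit_session_selector",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# A. response polarity and the stimulus representation

def classify_polarity(vectors: np.ndarray, roi_mean: complex) -> np.ndarray:
    """Positive/negative BOLD polarity of per-voxel response vectors.

    A voxel is positive (posBOLD) when its phase lags within (-pi/2,
    +pi/2] of the ROI-averaged response (inclusive upper bound as the
    documented tie-break), negative (negBOLD) otherwise.  Zero-amplitude
    voxels are negative by convention (logged).

    Returns a boolean array, True = positive.
    """
    roi_mean = complex(roi_mean)
    if abs(roi_mean) == 0:
        raise ValueError("ROI-averaged vector must have amplitude > 0")
    z = np.atleast_1d(np.asarray(vectors, dtype=complex))
    zero = np.abs(z) == 0
    if zero.any():
        logger.info("%d zero-amplitude voxel(s) classified negBOLD by convention",
                    int(zero.sum()))
    dphase = np.angle(z * np.conj(roi_mean))
    positive = (dphase > -np.pi / 2) & (dphase <= np.pi / 2) & ~zero
    return positive


def refine_stimulus_representation(
    polarities: np.ndarray,
    meta: pd.DataFrame,
    annulus: tuple[float, float] = (0.75, 7.0),
    *,
    bandwidth: float = 0.5,
    field_max: float = 10.0,
) -> np.ndarray:
    """Stage-A mask: smoothed polarity map inside the stimulus annulus.

    Simplified spatial refinement: (1) eccentricity is warped by its
    empirical CDF over ROI voxels (uniformizing voxel density), rescaled
    to the field extent; (2) the 0/1 polarity indicator is smoothed over
    warped visual-field Cartesian coordinates with a Gaussian kernel;
    (3) a voxel passes when the smoothed polarity exceeds 0.5 and the
    voxel lies inside the annulus.  With fewer than 10 voxels inside the
    annulus the smoothing is unreliable and the mask falls back to
    annulus membership alone (with a warning).

    Parameters
    ----------
    polarities : boolean array, True = posBOLD
    meta : DataFrame with ``eccentricity`` (dva) and ``polar_angle`` (deg)
    annulus : (inner, outer) stimulus eccentricity limits, dva
    bandwidth : Gaussian kernel SD in warped-eccentricity units
    """
    pol = np.asarray(polarities, dtype=bool)
    ecc = meta["eccentricity"].to_numpy(dtype=float)
    ang = np.deg2rad(meta["polar_angle"].to_numpy(dtype=float))
    if ecc.size != pol.size:
        raise ValueError("every voxel needs visual-field coordinates")
    inner, outer = annulus
    in_annulus = (ecc >= inner) & (ecc <= outer)
    if in_annulus.sum() < 10:
        warnings.warn(
            "fewer than 10 voxels inside the stimulus annulus; "
            "falling back to annulus membership alone",
            RuntimeWarning,
            stacklevel=2,
        )
        return in_annulus

    # empirical-CDF warp of eccentricity (uniformizes density), back to dva scale
    order = stats.rankdata(ecc, method="average")
    warped = (order / ecc.size) * field_max
    x = warped * np.cos(ang)
    y = warped * np.sin(ang)
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    smoothed = (w @ pol.astype(float)) / w.sum(axis=1)
    return (smoothed > 0.5) & in_annulus


# ----------------------------------------------------------------------
# B / D. multivariate statistics on response-vector coordinates

def _coords(vectors: np.ndarray) -> np.ndarray:
    """(n_runs, n_voxels, 2) real coordinates from complex vectors."""
    z = np.asarray(vectors, dtype=complex)
    if z.ndim == 1:
        z = z[:, None]
    return np.stack([z.real, z.imag], axis=-1)


def _inv2(S: np.ndarray, rcond: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form inverse of stacked 2x2 matrices; flags singular ones."""
    a, b = S[..., 0, 0], S[..., 0, 1]
    c, d = S[..., 1, 0], S[..., 1, 1]
    det = a * d - b * c
    scale = np.maximum(np.abs(a) + np.abs(d), 1e-300)
    singular = np.abs(det) <= rcond * scale**2
    safe = np.where(singular, 1.0, det)
    inv = np.empty_like(S)
    inv[..., 0, 0] = d / safe
    inv[..., 0, 1] = -b / safe
    inv[..., 1, 0] = -c / safe
    inv[..., 1, 1] = a / safe
    return inv, singular


def hotelling_intercept(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample Hotelling T-squared of per-voxel mean response vectors.

    ``T2 = n * m' S^-1 m`` with S the sample covariance (ddof=1); the
    p-value comes from ``F = (n - p) / (p (n - 1)) * T2`` on (p, n - p)
    degrees of freedom, p = 2.  Singular covariance yields NaN (the voxel
    fails stage B, reason logged).

    Returns ``(t2, p)`` arrays of shape (n_voxels,).
    """
    X = _coords(vectors)
    n = X.shape[0]
    if n < 4:
        raise ValueError("at least 4 runs are required")
    m = X.mean(axis=0)
    c = X - m
    S = np.einsum("nvi,nvj->vij", c, c) / (n - 1)
    Sinv, singular = _inv2(S)
    t2 = n * np.einsum("vi,vij,vj->v", m, Sinv, m)
    t2 = np.where(singular, np.nan, t2)
    if singular.any():
        logger.info("%d voxel(s) excluded: singular response-vector covariance",
                    int(singular.sum()))
    p = 2
    F = (n - p) / (p * (n - 1)) * t2
    pval = stats.f.sf(F, p, n - p)
    return t2, pval


def condition_t2(vectors: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Condition-sensitivity statistic per voxel: Hotelling-Lawley trace of
    the one-way MANOVA across condition labels, scaled as a T-squared,
    ``(N - k) * trace(W^-1 B)``.

    Invariant to a common rotation of all of a voxel's response vectors.
    Singular within-group scatter yields NaN.
    """
    X = _coords(vectors)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("at least two condition labels are required")
    N = X.shape[0]
    k = groups.size
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], 2, 2))
    B = np.zeros_like(W)
    for g in groups:
        sel = labels == g
        Xg = X[sel]
        mg = Xg.mean(axis=0)
        cg = Xg - mg
        W += np.einsum("nvi,nvj->vij", cg, cg)
        dm = mg - grand
        B += sel.sum() * np.einsum("vi,vj->vij", dm, dm)
    Winv, singular = _inv2(W)
    hlt = np.einsum("vij,vji->v", Winv, B)
    return np.where(singular, np.nan, (N - k) * hlt)


def test_voxel_multivariate(
    vectors: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel multivariate ANOVA on response-vector 2D coordinates.

    Returns ``(intercept_t2, intercept_p, condition_t2)``; the intercept
    tests whether the mean vector differs from the zero-length null
    vector, the condition statistic ranks stimulus sensitivity.
    """
    t2, p = hotelling_intercept(vectors)
    return t2, p, condition_t2(vectors, labels)


# ----------------------------------------------------------------------
# C. vein likeliness

def vein_metric(raw_runs: np.ndarray) -> np.ndarray:
    """Vein-likeliness metric: SD of the detrended raw (absolute, not
    %BOLD) timeseries over its baseline, averaged across runs.

    Per run, an OLS baseline + linear-drift fit is removed from the raw
    series; the metric is ``sqrt(SS_resid / (n - 2)) / mean(raw)``.
    Voxels with non-positive baseline return NaN (warned).

    Parameters
    ----------
    raw_runs : ndarray, (n_runs, n_volumes, n_voxels) or (n_volumes, n_voxels)
    """
    raw = np.asarray(raw_runs, dtype=float)
    if raw.ndim == 2:
        raw = raw[None]
    n_runs, n_vol, _ = raw.shape
    t = np.arange(n_vol, dtype=float)
    X = np.column_stack([np.ones(n_vol), t - t.mean()])
    pinv = np.linalg.pinv(X)
    metrics = np.empty((n_runs, raw.shape[2]))
    for r in range(n_runs):
        Y = raw[r]
        resid = Y - X @ (pinv @ Y)
        sd = np.sqrt((resid**2).sum(axis=0) / (n_vol - 2))
        baseline = Y.mean(axis=0)
        bad = baseline <= 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} voxel(s) with non-positive baseline in "
                "vein metric set to NaN",
                RuntimeWarning,
                stacklevel=2,
            )
        metrics[r] = np.where(bad, np.nan, sd / np.where(bad, 1.0, baseline))
    return metrics.mean(axis=0)


# ----------------------------------------------------------------------
# C/D percentile filters

def percentile_cut(
    values: np.ndarray,
    candidates: np.ndarray,
    percentile: float,
    keep: str,
) -> tuple[np.ndarray, float]:
    """Strict percentile filter over a candidate pool.

    The threshold is the given percentile (linear interpolation between
    order statistics) of ``values`` over ``candidates``; voxels strictly
    below (``keep='below'``) or strictly above (``keep='above'``) pass.
    Ties at the threshold are excluded.  If the strict comparison empties
    the pool (e.g. all values equal), the filter falls back to the
    non-strict comparison with a warning.

    Returns ``(mask, threshold)``.
    """
    values = np.asarray(values, dtype=float)
    candidates = np.asarray(candidates, dtype=bool)
    pool = values[candidates]
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("empty candidate pool for percentile filter")
    thr = float(np.percentile(pool, percentile))
    with np.errstate(invalid="ignore"):
        passed = values < thr if keep == "below" else values > thr
    mask = candidates & passed & np.isfinite(values)
    if not mask.any():
        warnings.warn(
            "strict percentile comparison excluded every candidate; "
            "falling back to the non-strict comparison",
            RuntimeWarning,
            stacklevel=2,
        )
        with np.errstate(invalid="ignore"):
            passed = values <= thr if keep == "below" else values >= thr
        mask = candidates & passed & np.isfinite(values)
    return mask, thr


def apply_percentile_filters(
    vein: np.ndarray,
    cond_t2: np.ndarray,
    pass_ab: np.ndarray,
    *,
    vein_percentile: float = 80.0,
    t2_percentile: float = 20.0,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Stages C and D: the vein cut then the discriminability cut.

    C keeps voxels strictly below the ``vein_percentile`` of the vein
    metric over A-and-B passers; D keeps voxels strictly above the
    ``t2_percentile`` of the condition statistic over C passers.

    Returns ``(pass_c, vein_threshold, pass_d, t2_threshold)``.
    """
    pass_c, vein_thr = percentile_cut(vein, pass_ab, vein_percentile, "below")
    pass_d, t2_thr = percentile_cut(cond_t2, pass_c, t2_percentile, "above")
    return pass_c, vein_thr, pass_d, t2_thr


# ----------------------------------------------------------------------
@dataclass
class SelectionMask:
    """Boolean voxel masks with per-stage provenance for one session."""

    session_id: int
    pass_a: np.ndarray
    pass_b: np.ndarray
    pass_c: np.ndarray
    pass_d: np.ndarray
    vein_threshold: float
    t2_threshold: float


class SessionVoxelSelector(BaseEstimator):
    """Fit the four-stage selection cascade on one session.

    Parameters
    ----------
    design : StudyDesign
    annulus : (inner, outer) stimulus eccentricity limits, dva
    alpha : stage-B significance level (uncorrected, per the procedure)
    vein_percentile : stage-C cut (keep strictly below), percent
    t2_percentile : stage-D cut (keep strictly above), percent
    smoothing_bandwidth : stage-A Gaussian kernel SD, warped units
    field_max : visual-field extent used by the eccentricity warp, dva

    Attributes (after ``fit``)
    --------------------------
    run_vectors_ : (n_runs, n_voxels) complex per-run response vectors
    mean_vectors_, roi_mean_ : run-averaged vectors and their ROI mean
    polarity_, pass_a_, pass_b_, pass_c_, pass_d_ : stage masks
        (``pass_c_`` implies A and B; ``pass_d_`` implies ``pass_c_``)
    intercept_t2_, intercept_p_, condition_t2_, vein_metric_ : voxel stats
    vein_threshold_, t2_threshold_ : stored cut values
    support_ : final voxel mask (equal to ``pass_d_``)
    """

    def __init__(
        self,
        design: StudyDesign | None = None,
        annulus: tuple[float, float] = (0.75, 7.0),
        alpha: float = 0.05,
        vein_percentile: float = 80.0,
        t2_percentile: float = 20.0,
        smoothing_bandwidth: float = 0.5,
        field_max: float = 10.0,
    ):
        self.design = design
        self.annulus = annulus
        self.alpha = alpha
        self.vein_percentile = vein_percentile
        self.t2_percentile = t2_percentile
        self.smoothing_bandwidth = smoothing_bandwidth
        self.field_max = field_max

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        raw_runs: np.ndarray,
        meta: pd.DataFrame,
        session_id: int = 0,
    ) -> "SessionVoxelSelector":
        """Run the cascade.

        Parameters
        ----------
        X : complex ndarray (n_runs, n_voxels)
            Per-run response vectors of this session.
        y : array of condition labels per run.
        raw_runs : ndarray (n_runs, n_volumes, n_voxels)
            Raw-intensity timeseries (the vein metric is computed on
            absolute signal, not %BOLD).
        meta : voxel metadata with visual-field coordinates.
        """
        Z = np.asarray(X, dtype=complex)
        labels = np.asarray(y)
        self.session_id_ = session_id
        self.run_vectors_ = Z
        self.labels_ = labels
        self.mean_vectors_ = Z.mean(axis=0)
        self.roi_mean_ = complex(self.mean_vectors_.mean())

        self.polarity_ = classify_polarity(self.mean_vectors_, self.roi_mean_)
        self.pass_a_ = refine_stimulus_representation(
            self.polarity_,
            meta,
            self.annulus,
            bandwidth=self.smoothing_bandwidth,
            field_max=self.field_max,
        )
        t2, p, ct2 = test_voxel_multivariate(Z, labels)
        self.intercept_t2_, self.intercept_p_, self.condition_t2_ = t2, p, ct2
        with np.errstate(invalid="ignore"):
            self.pass_b_ = np.isfinite(p) & (p < self.alpha)
        self.vein_metric_ = vein_metric(raw_runs)
        pass_ab = self.pass_a_ & self.pass_b_
        self.pass_c_, self.vein_threshold_, self.pass_d_, self.t2_threshold_ = (
            apply_percentile_filters(
                self.vein_metric_,
                self.condition_t2_,
                pass_ab,
                vein_percentile=self.vein_percentile,
                t2_percentile=self.t2_percentile,
            )
        )
        self.support_ = self.pass_d_
        self.n_features_in_ = Z.shape[1]
        return self

    # convenience -------------------------------------------------------
    def transform(self, X: np.ndarray) -> np.ndarray:
        """Restrict a (n_runs, n_voxels) matrix to the selected voxels."""
        if not hasattr(self, "support_"):
            raise RuntimeError("selector is not fitted")
        return np.asarray(X)[..., self.support_]

    def mask(self) -> SelectionMask:
        return SelectionMask(
            session_id=self.session_id_,
            pass_a=self.pass_a_,
            pass_b=self.pass_b_,
            pass_c=self.pass_c_,
            pass_d=self.pass_d_,
            vein_threshold=self.vein_threshold_,
            t2_threshold=self.t2_threshold_,
        )

    def to_frame(self) -> pd.DataFrame:
        """Mask table: per-voxel stage booleans and statistics."""
        return pd.DataFrame(
            {
                "voxel_id": np.arange(self.n_features_in_),
                "polarity": np.where(self.polarity_, "pos", "neg"),
                "pass_A": self.pass_a_,
                "pass_B": self.pass_b_,
                "pass_C": self.pass_c_,
                "pass_D": self.pass_d_,
                "intercept_T2": self.intercept_t2_,
                "intercept_p": self.intercept_p_,
                "condition_T2": self.condition_t2_,
                "vein_metric": self.vein_metric_,
            }
        )


def fit_session_selector(
    dataset,
    design: StudyDesign | None = None,
    **selector_kwargs,
) -> SessionVoxelSelector:
    """Convenience: %BOLD conversion + per-run vector estimation + cascade
    for one :class:`~hrdelay.synth.VoxelDataset`."""
    design = design or dataset.design
    glm = SinCosGLM(design).fit()
    pb = np.stack([to_percent_bold(run) for run in dataset.runs])
    vectors = glm.transform(pb)
    sel = SessionVoxelSelector(design=design, **selector_kwargs)
    return sel.fit(
        vectors,
        np.asarray(dataset.conditions),
        raw_runs=dataset.runs,
        meta=dataset.meta,
        session_id=dataset.session_id,
    )
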