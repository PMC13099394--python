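"""Permutation nulls, bootstrap confidence intervals and group-level tests.

The decoding null distribution permutes condition labels *within each
3-run triplet* (the unit within which conditions were randomized), at an
early stage: since per-run response-vector estimation does not depend on
the labels, this is implemented by relabeling run-level vectors and
re-running every label-dependent stage (the stage-D discriminability cut
and SVM training/testing).  Significance requires the observed AUC to
exceed 95% of its permutation null (one-sided, uncorrected).

Confidence intervals come from bootstrap resampling with replacement
(runs within a participant, or participants for group statistics).
Bivariate intervals use a Gaussian-kernel density over resampled 2D
means: the density threshold is lowered until the enclosed contour
contains 95% of the resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decode import cross_session_decode
from .selection import SessionVoxelSelector, condition_t2, percentile_cut

__all__ = [
    "permute_labels",
    "permutation_test",
    "PermutationNull",
    "decode_with_labels",
    "permutation_null_auc",
    "BootstrapCI",
    "bootstrap_ci",
    "CredibleContour",
    "bivariate_credible_contour",
    "TestReport",
    "one_sample_t",
    "paired_t",
    "signed_rank",
    "rm_anova",
    "rm_anova_interaction",
    "correlation",
]


# ----------------------------------------------------------------------
# permutation machinery

def permute_labels(
    labels: Sequence, rng: int | np.random.Generator = 0
) -> np.ndarray:
    """Permute condition labels independently within each 3-run triplet.

    ``labels`` must partition into complete consecutive triplets.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels = np.asarray(labels)
    if labels.size % 3 != 0:
        raise ValueError("labels must partition into complete 3-run triplets")
    out = labels.copy()
    for start in range(0, labels.size, 3):
        out[start : start + 3] = labels[start + rng.permutation(3)]
    return out


def permutation_test(
    observed: float, null: np.ndarray
) -> tuple[float, bool]:
    """One-sided permutation p and the significance flag.

    ``p`` is the plain fraction of permuted values >= observed (no +1
    correction); the result is significant when the observed value
    exceeds the 95th percentile of its null.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty permutation null")
    p = float(np.mean(null >= observed))
    significant = bool(observed > np.percentile(null, 95))
    return p, significant


@dataclass
class PermutationNull:
    """Permutation-null summary for one decoding analysis."""

    observed: float
    null: np.ndarray = field(repr=False)
    p: float = 0.0
    significant: bool = False
    n_permutations: int = 0


def _stage_d_masks(
    selectors: Sequence[SessionVoxelSelector],
    labels_list: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Recompute the label-dependent stage-D mask of each session."""
    masks = []
    for sel, labels in zip(selectors, labels_list):
        ct2 = condition_t2(sel.run_vectors_, labels)
        mask, _ = percentile_cut(ct2, sel.pass_c_, sel.t2_percentile, "above")
        masks.append(mask)
    return masks


def _direction_auc(
    Ztr: np.ndarray,
    ytr: np.ndarray,
    Zte: np.ndarray,
    yte: np.ndarray,
    encoding: str,
    C: float,
) -> float:
    """One train->test direction, identical math to ComplexPatternSVC
    (normalize by train complex mean, encode, z-score with train stats,
    linear C-SVM) but without estimator scaffolding — used in the
    permutation hot loop.  Equivalence is asserted by a test."""
    from sklearn.svm import SVC

    from .decode import auc as _auc
    from .decode import encode_features

    divisor = Ztr.mean(axis=0)
    kept = np.abs(divisor) > 0
    Ftr = encode_features(Ztr[:, kept] / divisor[kept], encoding)
    Fte = encode_features(Zte[:, kept] / divisor[kept], encoding)
    scale = Ftr.std(axis=0)
    cm = scale > 0
    mean = Ftr[:, cm].mean(axis=0)
    Ftr = (Ftr[:, cm] - mean) / scale[cm]
    Fte = (Fte[:, cm] - mean) / scale[cm]
    pos_label = np.unique(ytr)[1]
    svc = SVC(kernel="linear", C=C).fit(Ftr, (ytr == pos_label).astype(int))
    scores = Fte @ svc.coef_.ravel() + svc.intercept_[0]
    return _auc(scores, yte, pos_label=pos_label)


def decode_with_labels(
    selectors: Sequence[SessionVoxelSelector],
    labels_list: Sequence[np.ndarray],
    pair: tuple[str, str],
    encoding: str,
    C: float = 1.0,
) -> float:
    """Session-mean cross-validated AUC under the given run labels.

    Stages A-C are label-independent and reused from the fitted
    selectors; stage D and the SVM are recomputed for the labels at
    hand, so the identity labeling reproduces the observed analysis
    exactly.
    """
    masks = _stage_d_masks(selectors, labels_list)
    results = cross_session_decode(
        [sel.run_vectors_ for sel in selectors],
        list(labels_list),
        masks,
        pair,
        encoding,
        C=C,
    )
    return float(np.mean([r.auc for r in results]))


def permutation_null_auc(
    selectors: Sequence[SessionVoxelSelector],
    labels_list: Sequence[np.ndarray],
    pair: tuple[str, str],
    encoding: str,
    n_permutations: int = 8192,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
) -> PermutationNull:
    """Observed AUC and its within-triplet label-permutation null.

    The null re-runs every label-dependent stage per permutation: the
    stage-D condition-T2 cut (on the cached stage A-C candidates) and
    the SVM train/test in both session directions.
    """
    import sklearn

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels_list = [np.asarray(l) for l in labels_list]
    # stage A-C candidates are label-independent: cache their global indices
    cand = [np.flatnonzero(sel.pass_c_) for sel in selectors]
    Zc = [sel.run_vectors_[:, idx] for sel, idx in zip(selectors, cand)]
    Zfull = [sel.run_vectors_ for sel in selectors]
    pcts = [sel.t2_percentile for sel in selectors]

    def session_mean_auc(labels: list[np.ndarray]) -> float:
        d_idx = []
        for Z, idx, labs, pct in zip(Zc, cand, labels, pcts):
            ct2 = condition_t2(Z, labs)
            mask, _ = percentile_cut(
                ct2, np.ones(ct2.size, dtype=bool), pct, "above"
            )
            d_idx.append(idx[mask])
        aucs = []
        for i in range(len(Zc)):
            for j in range(len(Zc)):
                if i == j:
                    continue
                tr = np.isin(labels[i], pair)
                te = np.isin(labels[j], pair)
                aucs.append(
                    _direction_auc(
                        Zfull[i][tr][:, d_idx[i]],
                        labels[i][tr],
                        Zfull[j][te][:, d_idx[i]],
                        labels[j][te],
                        encoding,
                        C,
                    )
                )
        return float(np.mean(aucs))

    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        observed = session_mean_auc(labels_list)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            permuted = [permute_labels(labels, rng) for labels in labels_list]
            null[b] = session_mean_auc(permuted)
    p, significant = permutation_test(observed, null)
    return PermutationNull(
        observed=observed,
        null=null,
        p=p,
        significant=significant,
        n_permutations=n_permutations,
    )


# ----------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapCI:
    """Bootstrap interval for one statistic."""

    point: np.ndarray
    low: np.ndarray
    high: np.ndarray
    coverage: float
    n_resamples: int
    resamples: np.ndarray = field(repr=False)

    @property
    def width(self) -> np.ndarray:
        return self.high - self.low


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float | np.ndarray],
    data: np.ndarray,
    n_resamples: int = 8192,
    coverage: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI, resampling units along the first axis.

    Each resample has the original size, drawn with replacement
    (runs for single-participant statistics, participants for group
    statistics).  The univariate interval is the central ``coverage``
    percentile range (use 0.90 for error-bar style intervals).
    Deterministic under a fixed seed.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < 2:
        raise ValueError("at least 2 resampling units are required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = np.asarray(statistic(data), dtype=float)
    resamples = np.empty((n_resamples,) + point.shape)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        resamples[b] = statistic(data[idx])
    tail = 100.0 * (1.0 - coverage) / 2.0
    low = np.percentile(resamples, tail, axis=0)
    high = np.percentile(resamples, 100.0 - tail, axis=0)
    return BootstrapCI(
        point=point,
        low=low,
        high=high,
        coverage=coverage,
        n_resamples=n_resamples,
        resamples=resamples,
    )


# ----------------------------------------------------------------------
# bivariate credible contour

@dataclass
class CredibleContour:
    """Density-level credible region of resampled 2D means."""

    level: float
    polygons: list[np.ndarray]
    enclosed_fraction: float
    coverage: float
    bandwidth: float | str


def bivariate_credible_contour(
    points: np.ndarray,
    coverage: float = 0.95,
    bandwidth: float | str | None = None,
    grid_size: int = 128,
) -> CredibleContour:
    """Highest-density contour enclosing ``coverage`` of resampled means.

    A Gaussian kernel density (Silverman's rule unless ``bandwidth`` is
    given) is evaluated at every resample; the density threshold is the
    largest level at which at least ``coverage`` of the resamples sit at
    or above it (the contour "grows around the true mean" as the level
    is lowered).  The polygon(s) are extracted from a grid evaluation at
    that level.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 100:
        raise ValueError("at least 100 resampled points are required")
    if np.allclose(pts, pts[0]):
        raise ValueError("all resampled points are identical; no contour exists")
    bw = "silverman" if bandwidth is None else bandwidth
    kde = stats.gaussian_kde(pts.T, bw_method=bw)
    dens = kde(pts.T)
    order = np.sort(dens)[::-1]
    m = int(np.ceil(coverage * pts.shape[0]))
    level = float(order[m - 1])
    enclosed = float(np.mean(dens >= level))

    # polygon extraction on a padded grid
    from skimage import measure

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    lo = lo - 0.25 * span
    hi = hi + 0.25 * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    Z = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_size, grid_size)
    polygons = []
    for contour in measure.find_contours(Z, level):
        poly = np.empty_like(contour)
        poly[:, 0] = np.interp(contour[:, 0], np.arange(grid_size), gx)
        poly[:, 1] = np.interp(contour[:, 1], np.arange(grid_size), gy)
        polygons.append(poly)
    return CredibleContour(
        level=level,
        polygons=polygons,
        enclosed_fraction=enclosed,
        coverage=coverage,
        bandwidth=bw,
    )


# ----------------------------------------------------------------------
# group-level tests

@dataclass
class TestReport:
    """Group-test summary (statistic, degrees of freedom, p-value)."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
        }


def one_sample_t(
    x: np.ndarray, popmean: float = 0.0, alternative: str = "two-sided"
) -> TestReport:
    """One-sample Student t (e.g. group AUC against chance 0.5)."""
    x = np.asarray(x, dtype=float)
    res = stats.ttest_1samp(x, popmean, alternative=alternative)
    return TestReport("one_sample_t", float(res.statistic), (x.size - 1,),
                      float(res.pvalue))


def paired_t(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> TestReport:
    """Paired Student t across participants."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must align")
    res = stats.ttest_rel(x, y, alternative=alternative)
    return TestReport("paired_t", float(res.statistic), (x.size - 1,),
                      float(res.pvalue))


def signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, alternative: str = "two-sided"
) -> TestReport:
    """Wilcoxon signed-rank test (paired when ``y`` is given)."""
    x = np.asarray(x, dtype=float)
    args = (x,) if y is None else (x, np.asarray(y, dtype=float))
    res = stats.wilcoxon(*args, alternative=alternative)
    return TestReport("signed_rank", float(res.statistic), (x.size,),
                      float(res.pvalue))


def rm_anova(values: np.ndarray) -> TestReport:
    """One-way repeated-measures ANOVA (conditions within participants).

    ``values`` has shape (n_participants, n_conditions).
    """
    from statsmodels.stats.anova import AnovaRM

    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 3:
        raise ValueError("at least 3 participants are required")
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": values.ravel(),
        }
    )
    table = AnovaRM(df, "value", "subject", within=["condition"]).fit().anova_table
    row = table.loc["condition"]
    return TestReport(
        "rm_anova",
        float(row["F Value"]),
        (float(row["Num DF"]), float(row["Den DF"])),
        float(row["Pr > F"]),
    )


def rm_anova_interaction(values: np.ndarray) -> TestReport:
    """2 x 2 repeated-measures interaction (both factors within).

    ``values`` has shape (n_participants, 2, 2); the report is the
    factor-1 x factor-2 interaction (e.g. information type x stimulus
    pair type in the decoding analysis).
    """
    from statsmodels.stats.anova import AnovaRM

    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if values.shape[1:] != (2, 2):
        raise ValueError("values must have shape (n_participants, 2, 2)")
    rows = []
    for s in range(n):
        for a in range(2):
            for b in range(2):
                rows.append((s, a, b, values[s, a, b]))
    df = pd.DataFrame(rows, columns=["subject", "f1", "f2", "value"])
    table = AnovaRM(df, "value", "subject", within=["f1", "f2"]).fit().anova_table
    row = table.loc["f1:f2"]
    return TestReport(
        "rm_anova_interaction",
        float(row["F Value"]),
        (float(row["Num DF"]), float(row["Den DF"])),
        float(row["Pr > F"]),
    )


def correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> TestReport:
    """Pearson or Spearman correlation across participants."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must align")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestReport(f"{method}_correlation", float(r), (x.size - 2,), float(p))
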