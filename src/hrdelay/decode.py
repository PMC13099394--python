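"""Linear SVM decoding of voxel patterns of response delay and amplitude.

Runs are samples, selected voxels are features.  The complex run-by-voxel
matrix of response vectors is first normalized voxel-by-voxel — divided
by the per-voxel complex mean over *training* runs, rotating/scaling each
voxel to mean angle 0 and length 1 (mainly to minimize phase wrap).
Features are then the angle (delay-only), the modulus (amplitude-only),
or the concatenated real and imaginary parts (both; real parts first),
z-scored per column with training statistics, and fed to a linear
C-SVM (libsvm backend, default C = 1).  Performance is the area under
the ROC curve of the decision values.  Cross-validation is strictly
between sessions: voxel selection, normalization and training use one
session; only the trained model crosses to the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

__all__ = [
    "normalize_vectors",
    "encode_features",
    "auc",
    "ComplexPatternSVC",
    "DecodeResult",
    "cross_session_decode",
]

logger = logging.getLogger(__name__)

ENCODINGS = ("delay", "amplitude", "both")


def normalize_vectors(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Rotate/scale response vectors voxel-by-voxel to train-mean 1 + 0i.

    The divisor is the complex mean over *training* runs per voxel; both
    train and test are divided by the train divisor (no leakage).  Voxels
    whose train mean has zero amplitude are dropped from both sets.

    Returns ``(train_norm, test_norm, kept)`` where ``kept`` is the
    boolean voxel mask of retained columns.
    """
    Ztr = np.asarray(train, dtype=complex)
    divisor = Ztr.mean(axis=0)
    kept = np.abs(divisor) > 0
    if not kept.all():
        logger.info("%d voxel(s) dropped: zero train-mean vector",
                    int((~kept).sum()))
    Ztr = Ztr[:, kept] / divisor[kept]
    Zte = None
    if test is not None:
        Zte = np.asarray(test, dtype=complex)[:, kept] / divisor[kept]
    return Ztr, Zte, kept


def encode_features(normalized: np.ndarray, encoding: str) -> np.ndarray:
    """Real-valued feature matrix from normalized complex vectors.

    ``delay`` -> angle in radians wrapped to (-pi, pi] (near zero after
    normalization); ``amplitude`` -> modulus; ``both`` -> the n x 2p
    matrix [all real parts | all imaginary parts].
    """
    Z = np.asarray(normalized, dtype=complex)
    if encoding == "delay":
        return np.angle(Z)
    if encoding == "amplitude":
        return np.abs(Z)
    if encoding == "both":
        return np.concatenate([Z.real, Z.imag], axis=1)
    raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def auc(decision_values: np.ndarray, labels: np.ndarray, pos_label=None) -> float:
    """Area under the ROC curve, Mann-Whitney form.

    The fraction of (positive, negative) pairs whose positive decision
    value exceeds the negative one, ties counted one half — equivalently
    computed from midranks.
    """
    s = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("AUC requires exactly two classes in the test set")
    if pos_label is None:
        pos_label = classes[1]
    pos = y == pos_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the test set")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class ComplexPatternSVC(ClassifierMixin, BaseEstimator):
    """Linear SVM over encoded complex response-vector patterns.

    Parameters
    ----------
    encoding : {'delay', 'amplitude', 'both'}
        Feature encoding of the normalized vectors.
    C : float
        Soft-margin constant (libsvm default equivalent, 1.0).

    Attributes
    ----------
    classes_ : the two class labels (positive class is ``classes_[1]``)
    divisor_ : per-voxel complex normalization divisor (train statistics)
    voxel_mask_ : voxels kept by normalization
    feature_mean_, feature_scale_ : per-column z-score statistics
    column_mask_ : encoded columns kept (nonzero train variance)
    svm_ : the fitted ``sklearn.svm.SVC(kernel='linear')``
    """

    def __init__(self, encoding: str = "both", C: float = 1.0):
        self.encoding = encoding
        self.C = C

    # ------------------------------------------------------------------
    def _encode_with_train_stats(self, Z: np.ndarray) -> np.ndarray:
        Zn = np.asarray(Z, dtype=complex)[:, self.voxel_mask_] / self.divisor_
        F = encode_features(Zn, self.encoding)[:, self.column_mask_]
        return (F - self.feature_mean_) / self.feature_scale_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ComplexPatternSVC":
        Z = np.asarray(X, dtype=complex)
        if Z.ndim != 2:
            raise ValueError("X must be a 2D complex (runs x voxels) matrix")
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        if counts.min() < 2:
            raise ValueError("at least 2 samples per class are required")
        self.classes_ = classes
        if self.encoding not in ENCODINGS:
            raise ValueError(
                f"unknown encoding {self.encoding!r}; expected one of {ENCODINGS}"
            )

        divisor = Z.mean(axis=0)
        self.voxel_mask_ = np.abs(divisor) > 0
        self.divisor_ = divisor[self.voxel_mask_]
        Zn = Z[:, self.voxel_mask_] / self.divisor_
        F = encode_features(Zn, self.encoding)
        scale = F.std(axis=0)
        self.column_mask_ = scale > 0
        if not self.column_mask_.any():
            raise ValueError("all encoded feature columns have zero variance")
        dropped = int((~self.column_mask_).sum())
        if dropped:
            logger.info("%d zero-variance feature column(s) dropped", dropped)
        F = F[:, self.column_mask_]
        self.feature_mean_ = F.mean(axis=0)
        self.feature_scale_ = scale[self.column_mask_]
        Fz = (F - self.feature_mean_) / self.feature_scale_
        self.svm_ = SVC(kernel="linear", C=self.C).fit(Fz, y)
        self.n_features_in_ = Z.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distances to the hyperplane (positive = ``classes_[1]``)."""
        return self.svm_.decision_function(self._encode_with_train_stats(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm_.predict(self._encode_with_train_stats(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """AUC of the decision values on (X, y)."""
        return auc(self.decision_function(X), y, pos_label=self.classes_[1])


@dataclass
class DecodeResult:
    """One train-session -> test-session decoding outcome."""

    condition_pair: tuple[str, str]
    encoding: str
    train_session: int
    test_session: int
    auc: float
    decision_values: np.ndarray = field(repr=False)
    n_train: int = 0
    n_test: int = 0
    permutation_p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def _pair_runs(vectors, labels, pair):
    labels = np.asarray(labels)
    sel = np.isin(labels, pair)
    if sel.sum() == 0 or np.unique(labels[sel]).size != 2:
        raise ValueError(f"both conditions of pair {pair} must be present")
    return np.asarray(vectors)[sel], labels[sel]


def cross_session_decode(
    session_vectors: list[np.ndarray],
    session_labels: list[np.ndarray],
    session_masks: list[np.ndarray],
    pair: tuple[str, str],
    encoding: str,
    C: float = 1.0,
) -> list[DecodeResult]:
    """Between-session cross-validated decoding of one condition pair.

    For each ordered session pair (train i, test j != i): restrict both
    sessions to the *train* session's voxel selection, normalize and
    z-score with train statistics, fit the linear SVM on the train runs
    of the two conditions and compute the AUC of its decision values on
    the test runs.  Returns one :class:`DecodeResult` per direction.
    """
    n_ses = len(session_vectors)
    if not (len(session_labels) == len(session_masks) == n_ses):
        raise ValueError("vectors, labels and masks must align per session")
    for v in session_vectors[1:]:
        if np.shape(v)[1] != np.shape(session_vectors[0])[1]:
            raise ValueError("voxel sets are not alignable across sessions")
    results = []
    for i in range(n_ses):
        for j in range(n_ses):
            if i == j:
                continue
            mask = np.asarray(session_masks[i], dtype=bool)
            Ztr, ytr = _pair_runs(session_vectors[i][:, mask], session_labels[i], pair)
            Zte, yte = _pair_runs(session_vectors[j][:, mask], session_labels[j], pair)
            clf = ComplexPatternSVC(encoding=encoding, C=C).fit(Ztr, ytr)
            scores = clf.decision_function(Zte)
            results.append(
                DecodeResult(
                    condition_pair=tuple(pair),
                    encoding=encoding,
                    train_session=i,
                    test_session=j,
                    auc=auc(scores, yte, pos_label=clf.classes_[1]),
                    decision_values=scores,
                    n_train=len(ytr),
                    n_test=len(yte),
                )
            )
    return results
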