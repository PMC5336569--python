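"""Multivariate chemometrics: PCA with target rotation, OPLS, OPLS-DA,
grouped cross-validated Q2, and Ward hierarchical clustering.

All estimators follow the scikit-learn protocol (``fit``, ``transform`` /
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) and accept plain arrays or the package's
:class:`~acclimet.containers.FeatureMatrix`.

OPLS splits the variation of the data matrix into one component predictive
of the response y and components orthogonal to it (the orthogonal-filtering
formulation: the predictive weight is the y-covariance direction, and each
orthogonal weight is the part of the current loading orthogonal to it).
OPLS-DA is the multi-response extension against a class-indicator matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix
from .errors import ValidationError
from .spectra_prep import ParetoScaler

__all__ = [
    "PCAModel", "fit_pca", "RotatedComponents", "rotate_to_target",
    "OPLS", "fit_opls", "grouped_q2", "OPLSDA", "fit_oplsda",
    "cross_val_accuracy", "Dendrogram", "hca_ward",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: the largest-magnitude element of each
    loading vector is made positive (scores flipped to match)."""
    for a in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[a])))
        if loadings[a, j] < 0:
            loadings[a] *= -1.0
            scores[:, a] *= -1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PCAModel(BaseEstimator):
    """Principal component analysis by SVD, with optional centering.

    The uncentered variant (``center=False``) decomposes the raw matrix, so
    score deviations from zero are meaningful -- used for the sex-difference
    analysis where the mean difference itself is the signal.

    Attributes
    ----------
    loadings_ : ndarray, shape (k, p)
        Orthonormal component loadings.
    scores_ : ndarray, shape (n, k)
    explained_variance_ratio_ : ndarray, shape (k,)
        Fraction of total (centered or raw) sum of squares per component.
    mean_ : ndarray or None
    """

    def __init__(self, n_components: int = 2, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y=None):
        X = _as_array(X)
        n, p = X.shape
        k = self.n_components
        max_rank = min(n - 1 if self.center else n, p)
        if k > max_rank:
            raise ValidationError(
                f"n_components={k} exceeds achievable rank {max_rank}")
        self.mean_ = X.mean(axis=0) if self.center else None
        Xc = X - self.mean_ if self.center else X
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float(np.sum(s ** 2))
        self.loadings_ = Vt[:k].copy()
        self.scores_ = (U[:, :k] * s[:k]).copy()
        self.singular_values_ = s[:k].copy()
        self.explained_variance_ratio_ = (s[:k] ** 2) / total if total > 0 \
            else np.zeros(k)
        _fix_signs(self.loadings_, self.scores_)
        return self

    def transform(self, X):
        X = _as_array(X)
        if self.mean_ is not None:
            X = X - self.mean_
        return X @ self.loadings_.T


def fit_pca(m, k: int, centered: bool = True) -> PCAModel:
    """Fit a k-component PCA of a feature matrix."""
    return PCAModel(n_components=k, center=centered).fit(m)


# ---------------------------------------------------------------------------
# target rotation
# ---------------------------------------------------------------------------

@dataclass
class RotatedComponents:
    """In-plane rotation of PCA components toward an external target.

    ``linear_*`` is the direction in the score plane most correlated with
    the target (for this study, developmental temperature); ``ushape_*`` is
    the remaining-variance direction orthogonal to it within the plane.
    """

    angle: float
    linear_scores: np.ndarray
    linear_loadings: np.ndarray
    ushape_scores: np.ndarray
    ushape_loadings: np.ndarray
    r_linear: float


def rotate_to_target(p: PCAModel, target, k_plane: int = 2) -> RotatedComponents:
    """Rotate the span of the first ``k_plane`` components so one axis is
    maximally Pearson-correlated with ``target``.

    The optimal direction is the solution of the 2x2 (k_plane x k_plane)
    generalized problem u ~ Cov(S)^-1 cov(S, target); the orthogonal
    complement direction maximizing the remaining score variance becomes the
    U-shape component.  Rotated loadings stay orthonormal.
    """
    t = np.asarray(target, dtype=float)
    if t.std() == 0:
        raise ValidationError("zero-variance rotation target")
    S = p.scores_[:, :k_plane]
    if S.shape[1] < k_plane:
        raise ValidationError("model has fewer components than k_plane")
    Sc = S - S.mean(axis=0)
    tc = t - t.mean()
    cov_st = Sc.T @ tc
    cov_ss = Sc.T @ Sc
    u = np.linalg.solve(cov_ss, cov_st)
    u /= np.linalg.norm(u)
    linear_scores = S @ u
    r_linear = float(stats.pearsonr(linear_scores, t)[0])
    if r_linear < 0:
        u, linear_scores, r_linear = -u, -linear_scores, -r_linear
    # orthogonal complement within the plane, remaining-variance direction
    basis = np.linalg.svd(np.eye(k_plane) - np.outer(u, u))[0][:, :k_plane - 1]
    M = basis.T @ (Sc.T @ Sc) @ basis
    v = basis @ np.linalg.eigh(M)[1][:, -1]
    ushape_scores = S @ v
    # orientation: positive U-shape scores mean higher values at the target's
    # extremes (correlate positively with the squared centered target)
    quad = (t - t.mean()) ** 2
    if quad.std() > 0 and float(np.corrcoef(ushape_scores, quad)[0, 1]) < 0:
        ushape_scores, v = -ushape_scores, -v
    L = p.loadings_[:k_plane]
    linear_loadings = u @ L
    ushape_loadings = v @ L
    angle = float(np.arctan2(u[1], u[0])) if k_plane == 2 else float("nan")
    return RotatedComponents(angle, linear_scores, linear_loadings,
                             ushape_scores, ushape_loadings, r_linear)


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

class OPLS(RegressorMixin, BaseEstimator):
    """Orthogonal projections to latent structures for a single response.

    Extracts ``n_orthogonal`` components of X-variation uncorrelated with y,
    deflates them, then fits one predictive component.  With
    ``n_orthogonal=0`` the predictive component coincides with
    single-component NIPALS PLS.  X and y are mean-centered internally;
    variable scaling (e.g. Pareto) is the caller's responsibility.

    Attributes (after fit)
    ----------------------
    weights_, loadings_, scores_, y_loading_ : predictive part
    orth_weights_, orth_loadings_, orth_scores_ : lists per orthogonal component
    R2Y_, R2X_ : explained fractions of y and of X
    q2_ : cross-validated predictability, set by :func:`grouped_q2` callers
    """

    def __init__(self, n_orthogonal: int = 0):
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = _as_array(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValidationError("X and y sizes differ")
        if y.std() == 0 or not np.all(np.isfinite(y)):
            raise ValidationError("y must be finite with positive variance")
        if self.n_orthogonal < 0:
            raise ValidationError("n_orthogonal must be >= 0")
        if self.n_orthogonal >= min(n - 1, p):
            raise ValidationError(
                f"n_orthogonal={self.n_orthogonal} >= rank bound {min(n - 1, p)}")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        ss_x = float(np.sum(Xc ** 2))
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("degenerate weight vector (X'y = 0)")
        w /= norm
        self.orth_weights_, self.orth_loadings_, self.orth_scores_ = [], [], []
        explained = 0.0
        for _ in range(self.n_orthogonal):
            t = Xc @ w
            p_load = Xc.T @ t / (t @ t)
            w_o = p_load - (w @ p_load) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                raise ValidationError("no orthogonal variation left to extract")
            w_o /= n_o
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            explained += float(t_o @ t_o) * float(p_o @ p_o)
            self.orth_weights_.append(w_o)
            self.orth_loadings_.append(p_o)
            self.orth_scores_.append(t_o)
        t = Xc @ w
        p_load = Xc.T @ t / (t @ t)
        q = float(yc @ t / (t @ t))
        self.weights_ = w
        self.scores_ = t
        self.loadings_ = p_load
        self.y_loading_ = q
        resid = yc - t * q
        self.R2Y_ = 1.0 - float(resid @ resid) / float(yc @ yc)
        explained += float(t @ t) * float(p_load @ p_load)
        self.R2X_ = explained / ss_x if ss_x > 0 else 0.0
        self.n_samples_ = n
        self.q2_ = None
        return self

    @property
    def A_(self) -> str:
        """Component count in the conventional '1+n_orth' notation."""
        return f"1+{len(self.orth_weights_)}"

    def _filter(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.x_mean_
        for w_o, p_o in zip(self.orth_weights_, self.orth_loadings_):
            t_o = Xc @ w_o
            Xc = Xc - np.outer(t_o, p_o)
        return Xc

    def predictive_scores(self, X) -> np.ndarray:
        """Predictive-component scores for (new) samples."""
        return self._filter(_as_array(X)) @ self.weights_

    def predict(self, X) -> np.ndarray:
        return self.predictive_scores(X) * self.y_loading_ + self.y_mean_


def fit_opls(X, y, n_orth: int = 0) -> OPLS:
    return OPLS(n_orthogonal=n_orth).fit(X, y)


def grouped_q2(X, y, groups, n_orth: int = 0, center_scale: bool = True) -> float:
    """Leave-one-group-out cross-validated Q2 of an OPLS model.

    Each group (here: a sex x temperature condition) is held out in turn;
    Pareto scaling and centering are re-estimated on the training fold to
    avoid leakage.  Q2 = 1 - PRESS / sum((y_held - mean(y_train))^2), with
    the total sum of squares pooled over folds against each fold's training
    mean.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise ValidationError("need >= 3 distinct groups")
    press = tss = 0.0
    for g in uniq:
        test = groups == g
        train = ~test
        if not train.any():
            raise ValidationError(f"group {g!r} contains all samples")
        Xtr, Xte = X[train], X[test]
        ytr, yte = y[train], y[test]
        if center_scale:
            scaler = ParetoScaler(center=True).fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        model = OPLS(n_orthogonal=n_orth).fit(Xtr, ytr)
        pred = model.predict(Xte)
        press += float(np.sum((yte - pred) ** 2))
        tss += float(np.sum((yte - ytr.mean()) ** 2))
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

class OPLSDA(BaseEstimator):
    """Multi-response OPLS against a class-indicator matrix.

    Orthogonal components (uncorrelated with every class indicator) are
    filtered out first, then ``n_predictive`` PLS2 (NIPALS) components are
    fitted on the filtered matrix.  Per-sample predictive scores live in
    ``scores_``; new samples are scored with :meth:`transform` and
    classified with :meth:`predict` (largest predicted indicator).
    """

    def __init__(self, n_predictive: int = 2, n_orthogonal: int = 0):
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal

    def fit(self, X, classes):
        X = _as_array(X)
        classes = np.asarray(classes)
        self.classes_, y_idx = np.unique(classes, return_inverse=True)
        counts = np.bincount(y_idx)
        if self.classes_.size < 2:
            raise ValidationError("need >= 2 classes")
        if counts.min() < 2:
            small = self.classes_[counts < 2].tolist()
            raise ValidationError(f"classes with < 2 samples: {small}")
        n, p = X.shape
        Y = np.zeros((n, self.classes_.size))
        Y[np.arange(n), y_idx] = 1.0
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        # basis of the y-predictive weight space
        U, s, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        r = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
        if r == 0:
            raise ValidationError("X carries no class-predictive variation")
        W_space = U[:, :r]
        self.orth_weights_, self.orth_loadings_ = [], []
        for _ in range(self.n_orthogonal):
            w = U[:, 0]
            t = Xc @ w
            p_load = Xc.T @ t / (t @ t)
            w_o = p_load - W_space @ (W_space.T @ p_load)
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                raise ValidationError("no orthogonal variation left to extract")
            w_o /= n_o
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            self.orth_weights_.append(w_o)
            self.orth_loadings_.append(p_o)
        # PLS2 NIPALS on the filtered matrix
        Xa, Ya = Xc.copy(), Yc.copy()
        Wm, Pm, Qm, Tm = [], [], [], []
        for _ in range(self.n_predictive):
            u = Ya[:, int(np.argmax(Ya.var(axis=0)))]
            t_old = None
            for _ in range(500):
                w = Xa.T @ u
                w /= np.linalg.norm(w)
                t = Xa @ w
                q = Ya.T @ t / (t @ t)
                u = Ya @ q / (q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) < 1e-12 * np.linalg.norm(t):
                    break
                t_old = t
            p_load = Xa.T @ t / (t @ t)
            Xa = Xa - np.outer(t, p_load)
            Ya = Ya - np.outer(t, q)
            Wm.append(w); Pm.append(p_load); Qm.append(q); Tm.append(t)
        self.weights_ = np.column_stack(Wm)
        self.loadings_ = np.column_stack(Pm)
        self.y_loadings_ = np.column_stack(Qm)
        self.scores_ = np.column_stack(Tm)
        # rotation mapping filtered X to scores: T = Xf W (P'W)^-1
        self.rotation_ = self.weights_ @ np.linalg.inv(
            self.loadings_.T @ self.weights_)
        return self

    def _filter(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.x_mean_
        for w_o, p_o in zip(self.orth_weights_, self.orth_loadings_):
            Xc = Xc - np.outer(Xc @ w_o, p_o)
        return Xc

    def transform(self, X) -> np.ndarray:
        """Predictive scores for (new) samples."""
        return self._filter(_as_array(X)) @ self.rotation_

    def predict(self, X):
        scores = self.transform(X)
        Yhat = scores @ self.y_loadings_.T + self.y_mean_
        return self.classes_[np.argmax(Yhat, axis=1)]

    def condition_mean_scores(self, labels) -> tuple[np.ndarray, np.ndarray]:
        """Mean predictive score vector per condition label."""
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        means = np.vstack([self.scores_[labels == u].mean(axis=0) for u in uniq])
        return uniq, means


def fit_oplsda(X, classes, n_pred: int = 2, n_orth: int = 0) -> OPLSDA:
    return OPLSDA(n_predictive=n_pred, n_orthogonal=n_orth).fit(X, classes)


def cross_val_accuracy(X, classes, n_pred: int = 2, n_orth: int = 0,
                       n_splits: int = 5, seed: int = 0) -> float:
    """Stratified K-fold class-prediction accuracy of an OPLS-DA model."""
    X = _as_array(X)
    classes = np.asarray(classes)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, classes):
        model = OPLSDA(n_predictive=n_pred, n_orthogonal=n_orth)
        model.fit(X[train], classes[train])
        correct += int(np.sum(model.predict(X[test]) == classes[test]))
    return correct / classes.size


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled points.

    ``merges`` is the SciPy linkage matrix (rows: left, right, height,
    count); heights are non-decreasing under Ward linkage.
    """

    merges: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        """Newick serialization; branch lengths are merge-height differences."""
        n = len(self.labels)

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.merges[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                name = str(self.labels[node]).replace(" ", "_")
                return f"{name}:{bl:.6g}"
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            h = height(node)
            return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

        root = n + self.merges.shape[0] - 1
        h = height(root)
        left, right = int(self.merges[-1, 0]), int(self.merges[-1, 1])
        return f"({render(left, h)},{render(right, h)});"


def hca_ward(points, labels) -> Dendrogram:
    """Ward-linkage hierarchical clustering of labelled score vectors
    (Euclidean geometry, Lance-Williams updates via SciPy)."""
    points = np.asarray(points, dtype=float)
    labels = [str(x) for x in labels]
    if len(labels) != points.shape[0]:
        raise ValidationError("labels must match points")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels")
    if points.shape[0] < 2:
        raise ValidationError("need >= 2 points")
    order = np.argsort(labels, kind="stable")  # lexicographic determinism
    Z = linkage(points[order], method="ward")
    return Dendrogram(merges=Z, labels=[labels[i] for i in order])
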