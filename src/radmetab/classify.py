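"""Class-separation analysis: PCA, PLS-DA with VIP scores, random forests, SOMs.

Estimators follow scikit-learn conventions (``fit``/``predict``, fitted
attributes with trailing underscores) so they compose with sklearn model
selection; the module-level ``fit_*`` functions are thin wrappers that accept
a log-scale :class:`~radmetab.io.AbundanceTable` plus dose-group labels and
return the fitted model together with importance rankings and confusion-style
reports.  Features are autoscaled (centered, unit variance) before any of the
projection methods, the usual convention for metabolomics class separation.

Percentages in reports are rounded half-up to integers, which is the rounding
that reproduces every printed cell of the reference confusion tables
(1/6 -> 17%, 2/7 -> 29%, 1/8 -> 13%, 3/8 -> 38%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.utils.validation import check_array, check_X_y

from .io import GROUPS, AbundanceTable, validate_metadata

logger = logging.getLogger(__name__)

MODE_RESUB = "resubstitution"
MODE_OOB = "out_of_bag"
MODE_LOO = "leave_one_out"


# --------------------------------------------------------------------------
# reporting


def _pct_half_up(num: int, den: int) -> int:
    """100 * num / den rounded half-up, computed exactly."""
    frac = Fraction(100 * num, den)
    return (2 * frac.numerator + frac.denominator) // (2 * frac.denominator)


@dataclass
class ClassifierReport:
    """Confusion matrix with per-class error rates and overall accuracy.

    ``per_class_error`` maps class -> integer percent (None for an empty
    actual class); ``accuracy`` is the integer percent of the trace over the
    total.
    """

    method: str
    mode: str
    matrix: pd.DataFrame
    per_class_error: dict[str, int | None] = field(default_factory=dict)
    accuracy: int | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["error_rate_pct"] = [
            self.per_class_error[c] if self.per_class_error[c] is not None else "n/a"
            for c in out.index
        ]
        return out


def confusion_report(
    matrix: np.ndarray | pd.DataFrame,
    class_order: list[str],
    method: str = "",
    mode: str = MODE_RESUB,
) -> ClassifierReport:
    """Build a report from a square actual x predicted count matrix."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {m.shape}")
    if m.shape[0] != len(class_order):
        raise ValueError("class_order length does not match matrix size")
    if (m < 0).any() or not np.issubdtype(m.dtype, np.number):
        raise ValueError("confusion matrix must hold nonnegative counts")
    m = m.astype(int)
    df = pd.DataFrame(m, index=list(class_order), columns=list(class_order))
    df.index.name = "actual"
    errors: dict[str, int | None] = {}
    for i, cls in enumerate(class_order):
        row_sum = int(m[i].sum())
        errors[cls] = None if row_sum == 0 else _pct_half_up(row_sum - int(m[i, i]), row_sum)
    total = int(m.sum())
    accuracy = None if total == 0 else _pct_half_up(int(np.trace(m)), total)
    return ClassifierReport(method=method, mode=mode, matrix=df,
                            per_class_error=errors, accuracy=accuracy)


def _class_order(labels: np.ndarray) -> list[str]:
    """Dose groups in canonical order; anything else appended sorted."""
    uniq = list(pd.unique(pd.Series(labels)))
    ordered = [g for g in GROUPS if g in uniq]
    ordered += sorted(set(uniq) - set(ordered))
    return ordered


# --------------------------------------------------------------------------
# scaling and PCA


def _autoscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    std = np.where(std == 0, 1.0, std)
    return mean, std


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scaled: pd.DataFrame


def fit_pca(log_table: AbundanceTable, n_components: int | None = None) -> PCAResult:
    """PCA of the autoscaled log table (quality-control view of the cohort)."""
    X = log_table.data.to_numpy()
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    mean, std = _autoscale_fit(X)
    Xs = (X - mean) / std
    rank = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_components is not None and n_components > rank:
        warnings.warn(
            f"requested {n_components} components exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    pca = PCA(n_components=n_components or rank, svd_solver="full")
    scores = pca.fit_transform(Xs)
    comp_ids = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=log_table.sample_ids, columns=comp_ids),
        loadings=pd.DataFrame(pca.components_.T, index=log_table.metabolite_ids, columns=comp_ids),
        explained_variance_ratio=pca.explained_variance_ratio_,
        scaled=pd.DataFrame(Xs, index=log_table.sample_ids, columns=log_table.metabolite_ids),
    )


# --------------------------------------------------------------------------
# PLS-DA


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis with VIP scores.

    A PLS regression (NIPALS) is fit on the one-hot class indicator matrix;
    a sample's predicted class is the argmax of its predicted indicators.
    ``vip_`` holds the variable-importance-in-projection score per feature:

        VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

    with SSY_a the Y sum of squares explained by component a; the mean of
    the squared VIPs over features is identically 1.

    Parameters
    ----------
    n_components : latent components (capped at min(n_samples - 1, n_features)).
    scale : autoscale features (center, unit variance) before the fit.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        self.classes_ = np.array(_class_order(np.asarray(y, dtype=object)))
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        counts = pd.Series(y).value_counts()
        if (counts < 2).any():
            raise ValueError(f"every class needs >= 2 samples, got {counts.to_dict()}")
        Y = np.zeros((X.shape[0], len(self.classes_)))
        for i, label in enumerate(y):
            Y[i, class_index[label]] = 1.0
        if self.scale:
            self.x_mean_, self.x_std_ = _autoscale_fit(X)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_std_ = np.ones(X.shape[1])
        Xs = (X - self.x_mean_) / self.x_std_
        a = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self.pls_ = PLSRegression(n_components=a, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # y residual underflow chatter
            self.pls_.fit(Xs, Y)
        self.n_components_ = a
        self.vip_ = self._compute_vip()
        self.n_features_in_ = X.shape[1]
        return self

    def _compute_vip(self) -> np.ndarray:
        W = self.pls_.x_weights_  # (p, a), unit-norm columns
        T = self.pls_.x_scores_  # (n, a)
        Q = self.pls_.y_loadings_  # (k, a)
        ssy = np.einsum("na,na->a", T, T) * np.einsum("ka,ka->a", Q, Q)
        p = W.shape[0]
        wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), np.finfo(float).tiny)
        return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_std_
        return self.pls_.predict(Xs)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def _loo_confusion(model, X: np.ndarray, y: np.ndarray, classes: list[str]) -> np.ndarray:
    """Leave-one-out confusion matrix; folds whose training set would lose a
    class entirely are skipped with a warning."""
    preds, actual = [], []
    y = np.asarray(y, dtype=object)
    counts = pd.Series(y).value_counts()
    skipped = 0
    for i in range(X.shape[0]):
        if counts[y[i]] <= 1:
            skipped += 1
            continue
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        fold = clone(model).fit(X[mask], y[mask])
        preds.append(fold.predict(X[i : i + 1])[0])
        actual.append(y[i])
    if skipped:
        warnings.warn(f"leave-one-out skipped {skipped} singleton-class fold(s)", stacklevel=2)
    return _sk_confusion(actual, preds, labels=classes)


def _importance_frame(metabolites: list[str], scores: np.ndarray, vip_flag: bool) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    out = pd.DataFrame({"metabolite": metabolites, "score": scores, "rank": ranks})
    if vip_flag:
        out["vip_gt_1"] = scores > 1.0
    return out.sort_values("rank").reset_index(drop=True)


def fit_plsda(
    log_table: AbundanceTable,
    labels: np.ndarray | pd.Series,
    n_components: int = 2,
) -> tuple[PLSDAClassifier, pd.DataFrame, dict[str, ClassifierReport]]:
    """Fit PLS-DA on a log table; returns (model, VIP ranking, reports).

    Reports are produced in both resubstitution and leave-one-out modes —
    resubstitution flatters the fit, leave-one-out estimates generalization.
    """
    X = log_table.data.to_numpy()
    y = np.asarray(labels, dtype=object)
    model = PLSDAClassifier(n_components=n_components).fit(X, y)
    classes = list(model.classes_)
    ranking = _importance_frame(log_table.metabolite_ids, model.vip_, vip_flag=True)
    resub = _sk_confusion(y, model.predict(X), labels=classes)
    loo = _loo_confusion(model, X, y, classes)
    reports = {
        MODE_RESUB: confusion_report(resub, classes, method="PLS-DA", mode=MODE_RESUB),
        MODE_LOO: confusion_report(loo, classes, method="PLS-DA", mode=MODE_LOO),
    }
    return model, ranking, reports


# --------------------------------------------------------------------------
# random forest


def fit_random_forest(
    log_table: AbundanceTable,
    labels: np.ndarray | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[RandomForestClassifier, pd.DataFrame, ClassifierReport]:
    """Bagged randomized trees with out-of-bag confusion reporting.

    Importance is the mean impurity decrease.  OOB evaluation is the
    canonical, nearly unbiased error estimate for bagged ensembles.
    """
    y = np.asarray(labels, dtype=object)
    if len(pd.unique(pd.Series(y))) < 2:
        raise ValueError("random forest needs at least 2 classes")
    if n_trees < 10:
        warnings.warn(f"n_trees={n_trees} gives an unstable OOB estimate", stacklevel=2)
    X = log_table.data.to_numpy()
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, bootstrap=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns if some samples never OOB
        model.fit(X, y)
    classes = _class_order(y)
    sk_order = list(model.classes_)
    oob = model.oob_decision_function_
    pred = np.empty(len(y), dtype=object)
    never_oob = np.isnan(oob).any(axis=1) | (oob.sum(axis=1) == 0)
    pred[~never_oob] = [sk_order[k] for k in np.argmax(oob[~never_oob], axis=1)]
    if never_oob.any():  # vanishingly rare at default tree counts
        pred[never_oob] = model.predict(X[never_oob])
    matrix = _sk_confusion(y, pred, labels=classes)
    report = confusion_report(matrix, classes, method="RandomForest", mode=MODE_OOB)
    ranking = _importance_frame(log_table.metabolite_ids, model.feature_importances_, vip_flag=False)
    return model, ranking, report


# --------------------------------------------------------------------------
# self-organizing map


class SelfOrganizingMap(BaseEstimator):
    """Batch-trained rectangular SOM with a Gaussian neighborhood.

    The codebook is initialized from a seed-controlled Gaussian around the
    data centroid and refined by batch updates while the neighborhood
    radius decays linearly from half the larger grid dimension to
    ``final_radius``.  ``quantization_errors_[0]`` is the error of the
    initial codebook; training must not end worse than it started.

    Attributes after ``fit``: ``codebook_`` (n_nodes, n_features),
    ``grid_coords_`` (n_nodes, 2), ``bmus_`` (per training sample),
    ``quantization_errors_`` (initial + per epoch).
    """

    def __init__(
        self,
        grid_shape: tuple[int, int] = (10, 10),
        n_epochs: int = 100,
        initial_radius: float | None = None,
        final_radius: float = 0.1,
        random_state: int | None = None,
    ):
        self.grid_shape = grid_shape
        self.n_epochs = n_epochs
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.random_state = random_state

    def _init_codebook(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # uninformed Gaussian init around the data centroid, one per-feature
        # std wide: keeps the initial quantization error an honest baseline
        # that training then improves on (a "smart" init such as sampling the
        # data or spanning the PCA plane can start below the trained error)
        n_nodes = self.grid_shape[0] * self.grid_shape[1]
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        return X.mean(axis=0) + rng.normal(size=(n_nodes, X.shape[1])) * std

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        gx, gy = self.grid_shape
        if gx < 1 or gy < 1:
            raise ValueError(f"invalid grid shape {self.grid_shape}")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        rng = np.random.default_rng(self.random_state)
        coords = np.array([(i, j) for i in range(gx) for j in range(gy)], dtype=float)
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        codebook = self._init_codebook(X, rng)
        r0 = self.initial_radius if self.initial_radius is not None else max(gx, gy) / 2.0
        r0 = max(r0, self.final_radius)
        errors = [self._quantization_error(X, codebook)]
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            radius = r0 + (self.final_radius - r0) * frac
            d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
            bmu = np.argmin(d2, axis=1)
            h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))  # (n_samples, n_nodes)
            weight = h.sum(axis=0)
            updated = (h.T @ X) / np.where(weight == 0, 1.0, weight)[:, None]
            codebook = np.where((weight > 0)[:, None], updated, codebook)
            errors.append(self._quantization_error(X, codebook))
        self.codebook_ = codebook
        self.grid_coords_ = coords
        self.quantization_errors_ = np.array(errors)
        self.bmus_ = self.predict(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _quantization_error(X: np.ndarray, codebook: np.ndarray) -> float:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())

    def predict(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        d2 = ((X[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def component_plane(self, feature_index: int) -> np.ndarray:
        """The codebook slice of one feature, as a (gx, gy) matrix."""
        gx, gy = self.grid_shape
        return self.codebook_[:, feature_index].reshape(gx, gy)

    def hit_counts(self, labels: np.ndarray | pd.Series) -> pd.DataFrame:
        """Per-node class hit counts for the training samples."""
        labels = np.asarray(labels, dtype=object)
        classes = _class_order(labels)
        counts = pd.DataFrame(0, index=range(self.codebook_.shape[0]), columns=classes)
        for node, lab in zip(self.bmus_, labels):
            counts.at[node, lab] += 1
        counts.index.name = "node"
        return counts


@dataclass
class SOMGrid:
    """Fitted SOM bundle: the estimator plus per-metabolite component planes
    and per-node class hit counts."""

    model: SelfOrganizingMap
    metabolite_ids: list[str]
    hit_counts: pd.DataFrame | None

    @property
    def codebook(self) -> np.ndarray:
        return self.model.codebook_

    @property
    def quantization_errors(self) -> np.ndarray:
        return self.model.quantization_errors_

    def component_plane(self, metabolite: str) -> np.ndarray:
        return self.model.component_plane(self.metabolite_ids.index(metabolite))


def fit_som(
    log_table: AbundanceTable,
    grid_shape: tuple[int, int] = (10, 10),
    n_epochs: int = 100,
    seed: int = 0,
    labels: np.ndarray | pd.Series | None = None,
) -> SOMGrid:
    """Train a SOM on the autoscaled log table."""
    X = log_table.data.to_numpy()
    mean, std = _autoscale_fit(X)
    model = SelfOrganizingMap(
        grid_shape=grid_shape, n_epochs=n_epochs, random_state=seed
    ).fit((X - mean) / std)
    hits = model.hit_counts(labels) if labels is not None else None
    return SOMGrid(model=model, metabolite_ids=log_table.metabolite_ids, hit_counts=hits)
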