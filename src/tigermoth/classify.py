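"""Genotype classification from colour/pattern features.

Linear discriminant analysis of the three genotype groups (WW, Wy, yy)
as a 3-group problem, leave-one-out evaluation, and a shadow-feature
(random-forest) importance screen that compares each real feature
against permuted copies of all features.

The discriminant is the classic Fisher/Gaussian LDA: features are
standardised, a pooled within-class covariance is estimated (ridge
regularised if singular), discriminant axes solve the generalised
eigenproblem of between- versus within-class scatter, and class
assignment maximises the Gaussian discriminant score under uniform
class priors (configurable — with group sizes as unbalanced as
37/88/42, empirical priors would bias assignment toward the
heterozygote).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "DiscriminantModel",
    "ConfusionReport",
    "ImportanceReport",
    "fit_discriminant",
    "evaluate",
    "project",
    "shadow_feature_selection",
    "GenotypeDiscriminant",
    "DiscriminantResults",
]


@dataclass
class DiscriminantModel:
    """Fitted linear discriminant: class means, pooled covariance, axes."""

    classes: tuple
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    class_means: np.ndarray        # (k, d) in standardised space
    pooled_cov: np.ndarray         # (d, d)
    axes: np.ndarray               # (d, n_axes), Sw-orthonormal
    eigenvalues: np.ndarray
    priors: np.ndarray
    ridged: bool = False

    def _standardise(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature schema mismatch; missing columns {missing}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature schema mismatch")
        return (X - self.center) / self.scale

    def decision_scores(self, X) -> np.ndarray:
        """Gaussian LDA discriminant score per class (higher = more likely)."""
        Z = self._standardise(X)
        icov = linalg.pinvh(self.pooled_cov)
        W = icov @ self.class_means.T                       # (d, k)
        const = -0.5 * np.sum(self.class_means @ icov * self.class_means, axis=1)
        return Z @ W + const + np.log(self.priors)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


def fit_discriminant(features: pd.DataFrame, labels, priors=None,
                     ridge: float = 1e-6) -> DiscriminantModel:
    """Fit the 3-group (or k-group) linear discriminant.

    Features are standardised internally; zero-variance columns get unit
    scale and are neutralised by the covariance ridge.  If the pooled
    within-class covariance is singular it is regularised by
    ``ridge * trace/d`` on the diagonal (recorded on the model).  Axes
    are the generalised eigenvectors of between- vs within-class
    scatter, Sw-orthonormal, at most ``n_classes - 1`` of them.
    """
    X = features.select_dtypes(include=[np.number]) if isinstance(features, pd.DataFrame) \
        else pd.DataFrame(np.asarray(features, dtype=float))
    names = tuple(str(c) for c in X.columns)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(labels)
    if Xv.shape[0] != len(y):
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 members: {small}")
    n, d = Xv.shape
    if n <= 2:
        raise ValueError("need more than two rows")
    center = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (Xv - center) / scale
    k = len(classes)
    means = np.vstack([Z[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((d, d))
    for i, c in enumerate(classes):
        R = Z[y == c] - means[i]
        Sw += R.T @ R
    Sw /= max(n - k, 1)
    ridged = False
    eigmin = linalg.eigvalsh(Sw)[0]
    if eigmin < 1e-10 * max(np.trace(Sw) / d, 1e-30):
        Sw = Sw + ridge * (np.trace(Sw) / d + 1e-30) * np.eye(d)
        ridged = True
    mbar = means.mean(axis=0)  # uniform weighting across classes
    Mb = means - mbar
    Sb = (Mb.T @ Mb) / max(k - 1, 1)
    evals, evecs = linalg.eigh(Sb, Sw)   # ascending; Sw-orthonormal vectors
    order = np.argsort(evals)[::-1][: min(k - 1, d)]
    axes = evecs[:, order]
    eigenvalues = evals[order]
    if priors is None:
        pri = np.full(k, 1.0 / k)
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (k,) or np.any(pri <= 0):
            raise ValueError("priors must be positive, one per class")
        pri = pri / pri.sum()
    return DiscriminantModel(tuple(classes), names, center, scale, means,
                             Sw, axes, eigenvalues, pri, ridged)


@dataclass
class ConfusionReport:
    """Confusion matrix (true rows x predicted columns) with accuracies."""

    matrix: pd.DataFrame
    overall_accuracy: float
    per_class_accuracy: dict

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ConfusionReport(overall={self.overall_accuracy:.4f})"


def _confusion(y_true, y_pred, classes) -> ConfusionReport:
    classes = list(classes)
    mat = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    total = mat.to_numpy().sum()
    diag = np.trace(mat.to_numpy())
    per_class = {}
    for c in classes:
        row = mat.loc[c].sum()
        per_class[c] = float(mat.loc[c, c] / row) if row else float("nan")
    return ConfusionReport(mat, float(diag / total), per_class)


def evaluate(model: DiscriminantModel, features: pd.DataFrame, labels,
             scheme: str = "loo") -> ConfusionReport:
    """Evaluate a discriminant configuration by leave-one-out refitting.

    Each fold refits the model without one row and predicts it; the
    report aggregates all folds.  ``scheme='resubstitution'`` skips the
    refits and scores the training data directly.
    """
    y = np.asarray(labels)
    unseen = set(y) - set(model.classes)
    if unseen:
        raise ValueError(f"labels unseen at training time: {sorted(unseen)}")
    X = features[list(model.feature_names)] if isinstance(features, pd.DataFrame) else features
    if scheme == "resubstitution":
        return _confusion(y, model.predict(X), model.classes)
    if scheme != "loo":
        raise ValueError(f"unknown scheme {scheme!r}")
    Xdf = pd.DataFrame(X, columns=list(model.feature_names)).reset_index(drop=True)
    preds = []
    for i in range(len(Xdf)):
        keep = np.ones(len(Xdf), dtype=bool)
        keep[i] = False
        sub = fit_discriminant(Xdf[keep], y[keep], priors=None)
        preds.append(sub.predict(Xdf.iloc[[i]])[0])
    return _confusion(y, np.asarray(preds), model.classes)


def project(model: DiscriminantModel, features) -> np.ndarray:
    """Discriminant scores (<= 2 axes for 3 groups) for plotting/tabulating.

    Scores are the standardised features projected on the Sw-orthonormal
    axes; the training mean projects to the origin.
    """
    Z = model._standardise(features)
    return Z @ model.axes


@dataclass
class ImportanceReport:
    """Shadow-feature screen outcome per feature."""

    table: pd.DataFrame                    # feature, hits, n_iter, p_value, status
    importance_history: np.ndarray = field(repr=False)   # (n_iter, d)
    shadow_max_history: np.ndarray = field(repr=False)   # (n_iter,)

    def status(self, feature: str) -> str:
        return self.table.set_index("feature").loc[feature, "status"]

    @property
    def confirmed(self) -> list[str]:
        return self.table[self.table["status"] == "confirmed"]["feature"].tolist()


def shadow_feature_selection(features: pd.DataFrame, labels, n_iter: int = 100,
                             seed: int = 0, n_trees: int = 500,
                             alpha: float = 0.01) -> ImportanceReport:
    """Shadow-feature importance screen (random-forest, Boruta-style logic).

    Each iteration appends an independently permuted copy of every
    feature (the shadows), fits a seeded random forest and records for
    each real feature whether its impurity importance exceeds the
    maximum shadow importance.  Features whose win count is
    significantly above chance (two-sided binomial test vs 0.5 at level
    ``alpha``) are ``confirmed``, significantly below are ``rejected``,
    the rest ``tentative``.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = features.select_dtypes(include=[np.number]) if isinstance(features, pd.DataFrame) \
        else pd.DataFrame(np.asarray(features, dtype=float))
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if n_iter < 20:
        raise ValueError("n_iter must be at least 20 for the binomial decision")
    if np.all(Xv.std(axis=0) == 0):
        raise ValueError("degenerate feature set: all features constant")
    rng = np.random.default_rng(seed)
    n, d = Xv.shape
    hits = np.zeros(d, dtype=int)
    imp_hist = np.empty((n_iter, d))
    shadow_hist = np.empty(n_iter)
    for it in range(n_iter):
        shadows = np.column_stack([rng.permutation(Xv[:, j]) for j in range(d)])
        Xa = np.hstack([Xv, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        rf.fit(Xa, y)
        imp = rf.feature_importances_
        real, shadow = imp[:d], imp[d:]
        smax = shadow.max()
        hits += real > smax
        imp_hist[it] = real
        shadow_hist[it] = smax
    rows = []
    for j, name in enumerate(names):
        p = stats.binomtest(int(hits[j]), n_iter, 0.5).pvalue
        if p < alpha and hits[j] > n_iter / 2:
            status = "confirmed"
        elif p < alpha and hits[j] < n_iter / 2:
            status = "rejected"
        else:
            status = "tentative"
        rows.append(dict(feature=name, hits=int(hits[j]), n_iter=n_iter,
                         p_value=float(p), status=status))
    return ImportanceReport(pd.DataFrame(rows), imp_hist, shadow_hist)


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class GenotypeDiscriminant:
    """3-group genotype discriminant over a feature table.

    ``GenotypeDiscriminant.from_dataframe(df, label_col="genotype")``
    takes a feature table (e.g. from
    :func:`tigermoth.features.build_feature_table`), keeps its numeric
    columns, and :meth:`fit` returns a :class:`DiscriminantResults`
    with the fitted model, leave-one-out confusion report and
    discriminant scores.
    """

    def __init__(self, features: pd.DataFrame, labels, priors=None):
        self.features = features.select_dtypes(include=[np.number])
        self.labels = np.asarray(labels)
        self.priors = priors

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "genotype",
                       drop: tuple[str, ...] = ("seed_index",), **kw) -> "GenotypeDiscriminant":
        feats = df.drop(columns=[label_col, *[c for c in drop if c in df.columns]],
                        errors="ignore")
        if "failed" in df.columns:
            ok = ~df["failed"].astype(bool)
            feats = feats[ok]
            labels = df.loc[ok, label_col]
            feats = feats.drop(columns=["failed"], errors="ignore")
        else:
            labels = df[label_col]
        return cls(feats, labels, **kw)

    def fit(self, evaluate_loo: bool = True) -> "DiscriminantResults":
        model = fit_discriminant(self.features, self.labels, priors=self.priors)
        confusion = evaluate(model, self.features, self.labels,
                             scheme="loo" if evaluate_loo else "resubstitution")
        scores = project(model, self.features)
        return DiscriminantResults(self, model, confusion, scores)


@dataclass
class DiscriminantResults:
    """Fitted discriminant + leave-one-out evaluation + projections."""

    spec: GenotypeDiscriminant
    model: DiscriminantModel
    confusion: ConfusionReport
    scores: np.ndarray

    def summary(self) -> str:
        m = self.model
        lines = [
            "Linear discriminant analysis of genotype groups",
            "=" * 48,
            f"classes: {', '.join(map(str, m.classes))}   features: {len(m.feature_names)}"
            f"   axes: {m.axes.shape[1]}" + ("   (ridged covariance)" if m.ridged else ""),
            f"leave-one-out accuracy: {100 * self.confusion.overall_accuracy:.2f}%",
            "per-class accuracy:",
        ]
        for c, a in self.confusion.per_class_accuracy.items():
            lines.append(f"  {c}: {100 * a:.2f}%")
        lines.append("confusion matrix (true x predicted):")
        lines.append(self.confusion.matrix.to_string())
        return "\n".join(lines)
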