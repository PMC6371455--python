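"""Ridge prediction of splicing rates and feature-relevance analyses.

Single-cell and pseudo-bulk PSI are modelled with linear ridge regression on
the genomic and/or methylation feature blocks.  Performance is the Pearson
r^2 between out-of-sample predictions and observed splicing rates, under
tenfold cross-validation repeated four times with different splits.  Folds
are stratified by exon: all (exon, cell) rows of one exon share a fold, so
no exon contributes to both training and validation.  The ridge penalty is
chosen on the training folds via an inner grid (efficient leave-one-out
ridge CV); features are standardized on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, RidgeCV
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

DEFAULT_ALPHAS = np.logspace(-2, 4, 13)


@dataclass
class ModelSpec:
    """Configuration of one cross-validated ridge model."""

    feature_set: str = "genomic"
    target: str = "single_cell_psi"
    alphas: Sequence[float] = field(default_factory=lambda: DEFAULT_ALPHAS)
    folds: int = 10
    repeats: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CvResult:
    """Out-of-sample performance of a cross-validated model."""

    r2_per_repeat: np.ndarray
    predictions: pd.DataFrame  # rows aligned with input; one column per repeat
    spec: ModelSpec

    @property
    def r2_mean(self) -> float:
        return float(self.r2_per_repeat.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.r2_per_repeat.std(ddof=1)) if len(self.r2_per_repeat) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeat": np.arange(len(self.r2_per_repeat)),
            "r2": self.r2_per_repeat,
        }).assign(feature_set=self.spec.feature_set, target=self.spec.target)


def pearson_r2(y_true, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if np.std(y_true) == 0:
        raise ValueError("constant target: r^2 undefined")
    if np.std(y_pred) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


def _row_groups(index: pd.Index) -> np.ndarray:
    """Fold-stratification groups: the exon of each row, else the row itself."""
    if isinstance(index, pd.MultiIndex) and "exon_id" in index.names:
        return index.get_level_values("exon_id").to_numpy()
    return index.to_numpy()


def grouped_folds(groups: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold id per row; all rows of one group land in the same fold."""
    uniq = pd.unique(groups)
    perm = rng.permutation(len(uniq))
    fold_of_group = {g: perm[i] % n_folds for i, g in enumerate(uniq)}
    return np.array([fold_of_group[g] for g in groups])


def _make_ridge(alphas):
    return make_pipeline(StandardScaler(), RidgeCV(alphas=alphas))


def cross_validated_ridge(
    features: pd.DataFrame,
    targets: pd.Series,
    spec: Optional[ModelSpec] = None,
) -> CvResult:
    """Exon-stratified repeated tenfold CV of a ridge model.

    Rows of ``features`` and ``targets`` must be aligned; missing feature
    values are not allowed.  Returns per-repeat Pearson r^2 between the
    pooled out-of-fold predictions and the observed targets.
    """
    spec = spec or ModelSpec()
    X = features.to_numpy(float)
    y = targets.to_numpy(float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are not aligned")
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    if np.std(y) == 0:
        raise ValueError("constant target: r^2 undefined")
    groups = _row_groups(features.index)
    rng = np.random.default_rng(spec.seed)

    r2s = np.empty(spec.repeats)
    preds = pd.DataFrame(index=features.index)
    for rep in range(spec.repeats):
        fold_ids = grouped_folds(groups, spec.folds, rng)
        y_hat = np.empty_like(y)
        for fold in range(spec.folds):
            test = fold_ids == fold
            if not test.any():
                continue
            model = _make_ridge(spec.alphas)
            model.fit(X[~test], y[~test])
            y_hat[test] = model.predict(X[test])
        r2s[rep] = pearson_r2(y, y_hat)
        preds[f"repeat_{rep}"] = y_hat
    return CvResult(r2_per_repeat=r2s, predictions=preds, spec=spec)


# ---------------------------------------------------------------------------
# Per-feature relevance

def per_feature_relevance(
    features: pd.DataFrame,
    targets: pd.Series,
    task: str = "linear",
) -> pd.DataFrame:
    """Single-feature relevance scores for one target vector.

    ``linear``: signed Pearson r and r^2 per feature.  ``logistic``: the
    absolute logistic-ridge weight times the feature's SD, plus the
    single-feature AUC.  Zero-variance features score 0.
    """
    X = features.to_numpy(float)
    y = np.asarray(targets, float)
    sx = X.std(axis=0)
    if task == "linear":
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sy = y.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
        r = np.where((sx > 0) & (sy > 0), r, 0.0)
        return pd.DataFrame({"r": r, "r2": r ** 2}, index=features.columns)
    if task == "logistic":
        scaler = StandardScaler()
        Xs = scaler.fit_transform(X)
        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(Xs, y.astype(int))
        # weights are on standardized features; multiply back by raw SD ratio
        w = np.abs(clf.coef_[0]) / np.where(sx > 0, sx, 1.0)
        relevance = np.where(sx > 0, w * sx, 0.0)
        aucs = np.array([
            roc_auc_score(y, X[:, j]) if sx[j] > 0 else 0.5
            for j in range(X.shape[1])
        ])
        aucs = np.maximum(aucs, 1.0 - aucs)
        return pd.DataFrame({"weight_sd": relevance, "auc": aucs},
                            index=features.columns)
    raise ValueError(f"unknown task {task!r}")


def cell_relevance_matrix(features: pd.DataFrame, psi) -> pd.DataFrame:
    """Cells x features matrix of per-cell feature-PSI correlations.

    For each cell, every (exon-level) feature is correlated with that cell's
    PSI across the exons quantified in the cell.
    """
    psi_df = psi.psi if hasattr(psi, "psi") else psi
    common = features.index.intersection(psi_df.index)
    X = features.loc[common].to_numpy(float)
    rows = {}
    for cell in psi_df.columns:
        y = psi_df.loc[common, cell].to_numpy(float)
        mask = ~np.isnan(y)
        if mask.sum() < 3:
            continue
        xm, ym = X[mask], y[mask]
        sx, sy = xm.std(axis=0), ym.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((xm - xm.mean(axis=0)) * (ym - ym.mean())[:, None]).mean(axis=0) / (sx * sy)
        rows[cell] = np.where((sx > 0) & (sy > 0), r, 0.0)
    return pd.DataFrame(rows, index=features.columns).T.rename_axis("cell_id")


@dataclass
class RelevancePcaResult:
    scores: pd.DataFrame      # cells x components
    loadings: pd.DataFrame    # features x components
    explained_variance_ratio: np.ndarray
    top_positive: pd.Series   # five largest positive PC1 loadings
    top_negative: pd.Series   # five most negative PC1 loadings
    separation_auc: Optional[float] = None


def feature_relevance_pca(
    relevance: pd.DataFrame,
    state_labels: Optional[pd.Series] = None,
    n_components: int = 2,
) -> RelevancePcaResult:
    """Centered PCA of the cells x features relevance matrix.

    With binary state labels, also reports how well PC1 separates the two
    states (AUC of the PC1 score as a classifier).
    """
    if relevance.shape[0] < 2 or relevance.shape[1] < 2:
        raise ValueError("relevance PCA needs >= 2 cells and >= 2 features")
    n_components = min(n_components, *relevance.shape)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(relevance.to_numpy(float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(pca.components_.T, index=relevance.columns,
                            columns=comp_names)
    pc1 = loadings["PC1"].sort_values()
    auc = None
    if state_labels is not None:
        labels = state_labels.loc[relevance.index]
        y = (labels == labels.unique()[0]).astype(int)
        auc = roc_auc_score(y, scores[:, 0])
        auc = float(max(auc, 1.0 - auc))
    return RelevancePcaResult(
        scores=pd.DataFrame(scores, index=relevance.index, columns=comp_names),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        top_positive=pc1.tail(5)[::-1],
        top_negative=pc1.head(5),
        separation_auc=auc,
    )


def cross_state_transfer(
    features_a: pd.DataFrame,
    targets_a: pd.Series,
    features_b: pd.DataFrame,
    targets_b: pd.Series,
    alphas=DEFAULT_ALPHAS,
) -> float:
    """Train on all of state A, evaluate Pearson r^2 on state B unrefitted."""
    if list(features_a.columns) != list(features_b.columns):
        raise ValueError("feature manifests differ between states")
    model = _make_ridge(alphas)
    model.fit(features_a.to_numpy(float), np.asarray(targets_a, float))
    pred = model.predict(features_b.to_numpy(float))
    return pearson_r2(np.asarray(targets_b, float), pred)
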