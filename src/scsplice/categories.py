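"""Five-way splicing categories, their prediction, and cross-state switches.

Exons with mean PSI < 0.2 are *excluded* and > 0.8 *included*; within the
intermediate band, the deviation of each exon's observed SD from a scaled
binomial expectation (SD ~ c * sqrt(p(1-p)), c fitted to all exons by least
squares) is compared against Tukey fences of the deviation distribution:
above Q3 + 1.5*IQR -> *overdispersed*, below Q1 - 1.5*IQR -> *underdispersed*,
otherwise *multimodal*.  Categories are predicted with multinomial logistic
ridge (one-vs-rest AUC per category, macro-averaged), and category switching
between two states is tabulated and predicted per source category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .types import CATEGORIES

INTERMEDIATE_BAND = (0.2, 0.8)


@dataclass
class DispersionFit:
    """Scaled-binomial expected-dispersion fit and its Tukey fences."""

    scale: float            # c in SD ~ c * sqrt(p(1-p))
    upper_threshold: float  # Q3 + 1.5 IQR of intermediate-band deviations
    lower_threshold: float  # Q1 - 1.5 IQR
    n_exons: int
    n_intermediate: int

    def expected_sd(self, mean_psi):
        p = np.asarray(mean_psi, float)
        return self.scale * np.sqrt(p * (1.0 - p))


def fit_expected_dispersion(
    mean_psi,
    observed_sd,
    band=INTERMEDIATE_BAND,
    min_intermediate: int = 10,
) -> DispersionFit:
    """Least-squares fit of SD ~ c * sqrt(p(1-p)) over all exons.

    The Tukey fences are computed from the deviation (observed - expected)
    of intermediate-band exons, with linear-interpolation quartiles.
    """
    p = np.asarray(mean_psi, float)
    sd = np.asarray(observed_sd, float)
    ok = ~np.isnan(p) & ~np.isnan(sd)
    p, sd = p[ok], sd[ok]
    x = np.sqrt(p * (1.0 - p))
    denom = float(np.sum(x * x))
    c = float(np.sum(sd * x) / denom) if denom > 0 else 0.0
    if np.all(sd == 0):
        c = 0.0
    dev = sd - c * x
    inter = (p > band[0]) & (p < band[1])
    if inter.sum() < min_intermediate:
        raise ValueError(
            f"need >= {min_intermediate} intermediate-band exons, got {int(inter.sum())}"
        )
    q1, q3 = np.quantile(dev[inter], [0.25, 0.75])
    iqr = q3 - q1
    return DispersionFit(
        scale=c,
        upper_threshold=float(q3 + 1.5 * iqr),
        lower_threshold=float(q1 - 1.5 * iqr),
        n_exons=int(ok.sum()),
        n_intermediate=int(inter.sum()),
    )


def assign_categories(
    summary: pd.DataFrame,
    fit: DispersionFit,
    band=INTERMEDIATE_BAND,
) -> pd.DataFrame:
    """Assign each exon its splicing category.

    ``summary`` carries per-exon ``bpsi`` and ``psi_sd`` (see
    :func:`scsplice.psi.exon_summary`).  Exons without an SD (fewer than two
    quantified cells) are labelled ``unassigned``.
    """
    p = summary["bpsi"].to_numpy(float)
    sd = summary["psi_sd"].to_numpy(float)
    expected = fit.expected_sd(p)
    deviation = sd - expected
    cats = np.full(len(summary), "unassigned", dtype=object)
    has_sd = ~np.isnan(sd)
    cats[(p < band[0]) & ~np.isnan(p)] = "excluded"
    cats[(p > band[1]) & ~np.isnan(p)] = "included"
    inter = (p >= band[0]) & (p <= band[1]) & has_sd
    cats[inter & (deviation > fit.upper_threshold)] = "overdispersed"
    cats[inter & (deviation < fit.lower_threshold)] = "underdispersed"
    cats[inter & (deviation >= fit.lower_threshold)
         & (deviation <= fit.upper_threshold)] = "multimodal"
    return pd.DataFrame({
        "category": cats,
        "mean_psi": p,
        "observed_sd": sd,
        "expected_sd": expected,
        "deviation": deviation,
    }, index=summary.index)


@dataclass
class CategoryAucResult:
    per_category: pd.DataFrame   # category x (auc_mean, auc_sd, n, unstable)
    macro_auc_per_repeat: np.ndarray

    @property
    def macro_auc(self) -> float:
        return float(self.macro_auc_per_repeat.mean())

    @property
    def macro_auc_sd(self) -> float:
        return (float(self.macro_auc_per_repeat.std(ddof=1))
                if len(self.macro_auc_per_repeat) > 1 else 0.0)


def train_category_classifier(
    features: pd.DataFrame,
    categories: pd.Series,
    folds: int = 10,
    repeats: int = 4,
    seed: int = 0,
    C: float = 1.0,
) -> CategoryAucResult:
    """Multinomial logistic ridge with out-of-fold one-vs-rest AUCs.

    The macro-average AUC is the unweighted mean of per-category AUCs over
    the categories present.  A category with fewer members than folds is
    flagged unstable.
    """
    y = categories.loc[features.index]
    present = [c for c in CATEGORIES if (y == c).any()] or sorted(y.unique())
    if y.nunique() < 2:
        raise ValueError("need >= 2 categories to train a classifier")
    X = features.to_numpy(float)
    y_arr = y.to_numpy()

    auc_mat = np.full((repeats, len(present)), np.nan)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=min(folds, y.value_counts().min(), len(y)),
                              shuffle=True, random_state=seed * 1000 + rep)
        proba = np.zeros((len(y_arr), len(present)))
        for train, test in skf.split(X, y_arr):
            clf = make_pipeline(
                StandardScaler(),
                LogisticRegression(C=C, max_iter=2000),
            )
            clf.fit(X[train], y_arr[train])
            classes = list(clf.classes_)
            p = clf.predict_proba(X[test])
            for j, cat in enumerate(present):
                if cat in classes:
                    proba[test, j] = p[:, classes.index(cat)]
        for j, cat in enumerate(present):
            binary = (y_arr == cat).astype(int)
            if binary.sum() in (0, len(binary)):
                continue
            auc_mat[rep, j] = roc_auc_score(binary, proba[:, j])

    counts = y.value_counts()
    per_cat = pd.DataFrame({
        "auc_mean": np.nanmean(auc_mat, axis=0),
        "auc_sd": np.nanstd(auc_mat, axis=0, ddof=1) if repeats > 1 else 0.0,
        "n": [int(counts.get(c, 0)) for c in present],
    }, index=pd.Index(present, name="category"))
    per_cat["unstable"] = per_cat["n"] < folds
    macro = np.nanmean(auc_mat, axis=1)
    return CategoryAucResult(per_category=per_cat, macro_auc_per_repeat=macro)


def category_switch_table(
    assignments_a: pd.DataFrame,
    assignments_b: pd.DataFrame,
) -> dict:
    """5x5 switch counts between states over jointly categorized exons."""
    a = assignments_a.loc[assignments_a["category"] != "unassigned", "category"]
    b = assignments_b.loc[assignments_b["category"] != "unassigned", "category"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return {"table": None, "retained_fraction": float("nan"), "n_shared": 0}
    table = pd.crosstab(a.loc[shared], b.loc[shared],
                        rownames=["state_a"], colnames=["state_b"])
    table = table.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    retained = float(np.trace(table.to_numpy()) / len(shared))
    return {"table": table, "retained_fraction": retained, "n_shared": len(shared)}


def predict_category_switching(
    features_a: pd.DataFrame,
    assignments_a: pd.DataFrame,
    assignments_b: pd.DataFrame,
    folds: int = 10,
    repeats: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-source-category logistic ridge AUC for switched-vs-retained.

    For each category at state A, exons categorized in both states are
    labelled by whether their category changed at state B; a logistic ridge
    is cross-validated within that category.  Categories without both label
    classes are flagged with NaN AUC.
    """
    a = assignments_a.loc[assignments_a["category"] != "unassigned", "category"]
    b = assignments_b.loc[assignments_b["category"] != "unassigned", "category"]
    shared = a.index.intersection(b.index).intersection(features_a.index)
    rows = []
    for cat in CATEGORIES:
        members = shared[a.loc[shared] == cat]
        if len(members) == 0:
            continue
        switched = (b.loc[members] != cat).astype(int)
        if switched.nunique() < 2:
            rows.append((cat, len(members), int(switched.sum()), np.nan, np.nan))
            continue
        X = features_a.loc[members].to_numpy(float)
        y = switched.to_numpy()
        n_splits = int(min(folds, np.bincount(y).min()))
        aucs = []
        if n_splits >= 2:
            for rep in range(repeats):
                skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                      random_state=seed * 1000 + rep)
                score = np.zeros(len(y))
                for train, test in skf.split(X, y):
                    clf = make_pipeline(
                        StandardScaler(),
                        LogisticRegression(C=1.0, max_iter=2000),
                    )
                    clf.fit(X[train], y[train])
                    score[test] = clf.predict_proba(X[test])[:, 1]
                aucs.append(roc_auc_score(y, score))
        auc_mean = float(np.mean(aucs)) if aucs else np.nan
        auc_sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else np.nan
        rows.append((cat, len(members), int(switched.sum()), auc_mean, auc_sd))
    return pd.DataFrame(
        rows, columns=["category", "n", "n_switched", "auc_mean", "auc_sd"]
    ).set_index("category")


def methylation_category_contrast(
    context_meth_by_exon: pd.DataFrame,
    assignments: pd.DataFrame,
    min_group: int = 5,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Rank-test contrast of context methylation per category vs the rest.

    ``context_meth_by_exon`` is an exon x context matrix of methylation
    levels (e.g. the per-exon mean of per-cell context rates).  For every
    (category, context), a two-sample Wilcoxon (Mann-Whitney) test compares
    the category's exons against all other categorized exons; effects are
    differences of group medians; q-values are BH-adjusted over the whole
    family of tests.  Groups below ``min_group`` are skipped.
    """
    cats = assignments.loc[assignments["category"] != "unassigned", "category"]
    shared = cats.index.intersection(context_meth_by_exon.index)
    cats = cats.loc[shared]
    rows = []
    for cat in CATEGORIES:
        in_cat = cats.index[cats == cat]
        out_cat = cats.index[cats != cat]
        for ctx in context_meth_by_exon.columns:
            x = context_meth_by_exon.loc[in_cat, ctx].dropna()
            y = context_meth_by_exon.loc[out_cat, ctx].dropna()
            if len(x) < min_group or len(y) < min_group:
                continue
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append((cat, ctx, float(np.median(x) - np.median(y)),
                         float(p), len(x), len(y)))
    table = pd.DataFrame(
        rows, columns=["category", "context", "effect", "p", "n_in", "n_out"]
    )
    if len(table):
        table["q"] = multipletests(table["p"], method=fdr_method)[1]
    else:
        table["q"] = np.empty(0)
    return table
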