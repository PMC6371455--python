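"""Locus-level Spearman association between context methylation and PSI.

For every (cassette exon, sequence context) pair, the per-cell context
methylation rate is correlated with the per-cell PSI across cells (Spearman,
average ranks for ties).  Pairs without variation on either side are skipped
rather than reported.  P values are adjusted with Storey's q-value (the
default) or Benjamini-Hochberg.  Replication between two cell states counts
a discovery as replicated when the replication-set p is nominally significant
with a consistent effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .psi import PsiMatrix

DEFAULT_MIN_PAIRS = 10


def storey_qvalues(p_values: np.ndarray, lambdas=None) -> np.ndarray:
    """Storey q-values with pi0 estimated on a lambda grid.

    pi0 is estimated by the smoother-free conservative rule: the natural
    cubic-spline fit of pi0(lambda) evaluated at max(lambda) is approximated
    by averaging the top of the lambda grid; pi0 is clipped to (0, 1].
    Falls back to pi0 = 1 (Benjamini-Hochberg) when the grid is unusable.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    m = p.size
    if m < 100:
        pi0 = 1.0
    else:
        pi0_grid = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        # smooth by averaging the upper half of the grid (spline-free proxy)
        pi0 = float(np.clip(pi0_grid[lambdas >= 0.5].mean(), 1e-8, 1.0))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def adjust_multiple_testing(p_values, method: str = "storey") -> np.ndarray:
    """Adjust p-values for multiple testing; output order matches input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method == "storey":
        return storey_qvalues(p)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AssociationResult:
    """Per-(exon, context) Spearman statistics with q-values."""

    table: pd.DataFrame  # exon_id, context, rho, p, q, n_cells, direction

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr]


def methylation_splicing_association(
    psi: PsiMatrix,
    context_meth: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    method: str = "storey",
) -> AssociationResult:
    """Spearman rho/p/q for every testable (exon, context) pair.

    ``context_meth`` is the (exon_id, context) x cell matrix from
    :func:`scsplice.features.context_methylation_matrix`.  A pair is testable
    when at least ``min_pairs`` cells carry both a PSI value and a
    methylation rate and both sides vary across those cells.
    """
    shared = psi.cells.intersection(context_meth.columns)
    rows = []
    for (exon_id, context), meth_row in context_meth.iterrows():
        if exon_id not in psi.psi.index:
            continue
        x = psi.psi.loc[exon_id, shared].to_numpy(float)
        y = meth_row[shared].to_numpy(float)
        mask = ~np.isnan(x) & ~np.isnan(y)
        n = int(mask.sum())
        if n < min_pairs:
            continue
        xv, yv = x[mask], y[mask]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            continue  # no variation in splicing or methylation
        rho, p = stats.spearmanr(xv, yv)
        rows.append((exon_id, context, float(rho), float(p), n,
                     int(np.sign(rho))))
    table = pd.DataFrame(
        rows, columns=["exon_id", "context", "rho", "p", "n_cells", "direction"]
    )
    table["q"] = adjust_multiple_testing(table["p"].to_numpy(), method) \
        if len(table) else np.empty(0)
    return AssociationResult(table=table)


def replication_assessment(
    discovery: AssociationResult,
    replication: AssociationResult,
    fdr: float = 0.05,
    replication_p: float = 0.05,
) -> dict:
    """Fraction of discovery hits nominally replicated with consistent sign.

    Only discovery hits that are testable in the replication set enter the
    denominator; with no shared keys the fraction is undefined (NaN).
    """
    hits = discovery.significant(fdr).set_index(["exon_id", "context"])
    rep = replication.table.set_index(["exon_id", "context"])
    shared = hits.index.intersection(rep.index)
    if len(shared) == 0:
        return {"n_discovery": len(hits), "n_testable": 0,
                "n_replicated": 0, "fraction": float("nan")}
    sub_d, sub_r = hits.loc[shared], rep.loc[shared]
    replicated = (sub_r["p"] < replication_p) & \
        (np.sign(sub_r["rho"]) == np.sign(sub_d["rho"]))
    return {
        "n_discovery": len(hits),
        "n_testable": len(shared),
        "n_replicated": int(replicated.sum()),
        "fraction": float(replicated.mean()),
    }
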