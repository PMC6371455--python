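"""Expected cross-cell PSI dispersion under the cell and gene models.

Two competing explanations of cross-cell splicing variance are compared:

* **cell model** — every cell expresses a single isoform; the per-cell PSI is
  a Bernoulli indicator with mean p, so the expected SD is sqrt(p(1-p)).
* **gene model** — both isoforms are co-expressed per cell and reads sample
  the inclusion isoform binomially; observed PSI fluctuates with read depth,
  with SD ~ sqrt(p(1-p)/n) at depth n.  The gene-model expectation is
  estimated by Monte Carlo at each exon's observed per-cell read depths,
  averaging the across-cell SD over 400 simulation replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psi import PsiMatrix

DEFAULT_N_SIMS = 400


def expected_sd_cell_model(mean_psi):
    """SD of PSI under the bimodal cell model: sqrt(p(1-p))."""
    p = np.asarray(mean_psi, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("mean PSI must lie in [0, 1]")
    return np.sqrt(p * (1.0 - p))


def expected_sd_gene_model(
    mean_psi: float,
    per_cell_read_counts,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo upper bound on SD under the binomial gene model.

    Each replicate draws inclusion counts Binomial(n_c, p) per cell, forms
    per-cell PSI and takes the across-cell sample SD; the mean over
    ``n_sims`` replicates is returned.
    """
    if not 0.0 <= mean_psi <= 1.0:
        raise ValueError("mean PSI must lie in [0, 1]")
    n = np.asarray(per_cell_read_counts, dtype=int)
    if n.size == 0:
        raise ValueError("empty read-count vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.binomial(n[None, :], mean_psi, size=(n_sims, n.size))
    psi = draws / n[None, :]
    return float(psi.std(axis=1, ddof=1).mean())


def evaluate_models(
    psi: PsiMatrix,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    intermediate_band=(0.2, 0.8),
) -> pd.DataFrame:
    """Per-exon observed SD versus cell-model and gene-model expectations.

    Returns a frame with mean PSI, observed SD, both model SDs, the
    deviation (observed - gene model) and a flag for exons in the
    intermediate splicing band.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for exon_id in psi.exons:
        vals = psi.psi.loc[exon_id]
        obs = vals.dropna()
        if len(obs) < 2:
            raise ValueError(f"{exon_id}: SD undefined with {len(obs)} observation(s)")
        depths = psi.total_reads.loc[exon_id, obs.index].to_numpy()
        p = float(obs.mean())
        observed_sd = float(obs.std(ddof=1))
        gene_sd = expected_sd_gene_model(p, depths, n_sims=n_sims, seed=rng)
        rows.append({
            "exon_id": exon_id,
            "mean_psi": p,
            "observed_sd": observed_sd,
            "cell_model_sd": float(expected_sd_cell_model(p)),
            "gene_model_sd": gene_sd,
            "deviation": observed_sd - gene_sd,
            "intermediate": intermediate_band[0] < p < intermediate_band[1],
        })
    return pd.DataFrame(rows).set_index("exon_id")


def plot_dispersion(table: pd.DataFrame, ax=None):
    """Scatter observed SD against mean PSI with both model curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(table["mean_psi"], table["observed_sd"], s=8, alpha=0.5,
               label="observed")
    grid = np.linspace(0, 1, 200)
    ax.plot(grid, expected_sd_cell_model(grid), "k-", label="cell model")
    order = table["mean_psi"].argsort()
    ax.plot(table["mean_psi"].iloc[order], table["gene_model_sd"].iloc[order],
            "r.", ms=3, label="gene model")
    ax.set_xlabel("mean PSI")
    ax.set_ylabel("SD of PSI across cells")
    ax.legend()
    return ax
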