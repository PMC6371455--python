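"""Single-cell PSI quantification with coverage and cell-count floors.

PSI (percent spliced in) is the raw read ratio inclusion/(inclusion +
exclusion); an entry is quantified only when the total read count reaches
``min_reads`` (default 5), and an exon is kept only when quantified in at
least ``min_cells`` cells (default 10).  Pseudo-bulk PSI is the unweighted
mean of single-cell PSI values; dispersion is the sample (n-1) standard
deviation across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 5
DEFAULT_MIN_CELLS = 10


@dataclass
class PsiMatrix:
    """Exon x cell PSI values (NaN = below the coverage floor) plus the
    matching total-read-count matrix."""

    psi: pd.DataFrame
    total_reads: pd.DataFrame

    @property
    def exons(self):
        return self.psi.index

    @property
    def cells(self):
        return self.psi.columns


def compute_psi_matrix(
    counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> PsiMatrix:
    """Build the PSI matrix from a long-format read-count table.

    Parameters
    ----------
    counts
        Columns exon_id, cell_id, inclusion_reads, exclusion_reads.
    min_reads
        Minimum total reads for a (exon, cell) PSI value to be quantified.
    min_cells
        Minimum number of quantified cells for an exon to be retained.
    """
    if (counts[["inclusion_reads", "exclusion_reads"]] < 0).any().any():
        raise ValueError("negative read counts")
    total = counts["inclusion_reads"] + counts["exclusion_reads"]
    with np.errstate(invalid="ignore"):
        psi = counts["inclusion_reads"] / total
    psi = psi.where(total >= min_reads)

    long = counts[["exon_id", "cell_id"]].assign(psi=psi, total=total)
    psi_mat = long.pivot_table(index="exon_id", columns="cell_id", values="psi",
                               aggfunc="first", dropna=False)
    tot_mat = long.pivot_table(index="exon_id", columns="cell_id", values="total",
                               aggfunc="first", dropna=False).fillna(0).astype(int)
    keep = psi_mat.notna().sum(axis=1) >= min_cells
    return PsiMatrix(psi=psi_mat.loc[keep], total_reads=tot_mat.loc[keep])


def pseudo_bulk_psi(psi: PsiMatrix) -> pd.Series:
    """Per-exon pseudo-bulk PSI: mean of quantified single-cell values.

    Exons with no quantified cell come back NaN.
    """
    return psi.psi.mean(axis=1, skipna=True).rename("bpsi")


def psi_dispersion(psi: PsiMatrix) -> pd.Series:
    """Per-exon standard deviation of PSI across cells (sample SD, ddof=1).

    NaN where fewer than two cells are quantified.
    """
    n = psi.psi.notna().sum(axis=1)
    sd = psi.psi.std(axis=1, ddof=1, skipna=True)
    return sd.where(n >= 2).rename("psi_sd")


def exon_summary(psi: PsiMatrix) -> pd.DataFrame:
    """bPSI, SD and number of quantified cells per exon."""
    return pd.DataFrame({
        "bpsi": pseudo_bulk_psi(psi),
        "psi_sd": psi_dispersion(psi),
        "n_cells": psi.psi.notna().sum(axis=1),
    })
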