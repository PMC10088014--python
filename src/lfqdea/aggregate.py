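"""Peptide-to-protein abundance rollup.

Two estimators are provided:

* :func:`median_polish` — Tukey's median polish of the peptide x sample
  log2-abundance matrix; the protein profile is the overall effect plus the
  per-sample column effects, which makes the estimate robust to outlying
  peptide measurements. Missing cells are simply ignored in the median
  sweeps — no imputation.
* :func:`top_n` — the mean of the N peptides with the highest average
  abundance across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import QuantTable
from .preprocess import UsageError

__all__ = [
    "MedianPolishResult",
    "median_polish_matrix",
    "median_polish",
    "top_n",
    "summarize_counts",
]


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    @property
    def col_profile(self) -> np.ndarray:
        """Per-column (sample) fitted value: overall + column effect."""
        return self.overall + self.col_effects


def _nanmedian(a: np.ndarray, axis: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(a, axis=axis)
    return np.where(np.isnan(med), 0.0, med)


def median_polish_matrix(mat: np.ndarray, max_iter: int = 10,
                         tol: float = 0.01) -> MedianPolishResult:
    """Tukey's median polish of a 2-D array with NaN for missing cells.

    Alternately sweeps row and column medians out of the residual matrix
    until the sum of absolute residuals improves by no more than
    ``tol`` times its current value, or ``max_iter`` sweeps are done.
    """
    z = np.asarray(mat, dtype=float).copy()
    nr, nc = z.shape
    t = 0.0
    r = np.zeros(nr)
    c = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = _nanmedian(z, axis=1)
        z -= rdelta[:, None]
        r += rdelta
        delta = np.median(c)
        c -= delta
        t += delta
        cdelta = _nanmedian(z, axis=0)
        z -= cdelta[None, :]
        c += cdelta
        delta = np.median(r)
        r -= delta
        t += delta
        newsum = float(np.nansum(np.abs(z)))
        if newsum == 0.0 or abs(newsum - oldsum) <= tol * newsum:
            converged = True
            break
        oldsum = newsum
    return MedianPolishResult(overall=t, row_effects=r, col_effects=c,
                              residuals=z, n_iter=it, converged=converged)


def median_polish(table: QuantTable, max_iter: int = 10,
                  tol: float = 0.01) -> QuantTable:
    """Estimate protein abundances by median polish of each peptide matrix.

    For each protein, the peptide x sample matrix is polished and the
    protein abundance in sample ``j`` is ``overall + column_effect_j``.
    Samples without any peptide observation for a protein get no record.
    Single-peptide proteins pass through unchanged.
    """
    if not table.is_peptide_level:
        raise UsageError("median_polish requires a peptide-level table")
    cfg = table.config
    wide = table.data.pivot_table(index=[cfg.protein_col, cfg.peptide_col],
                                  columns=cfg.sample_col,
                                  values=cfg.response_col, aggfunc="mean")
    sample_order = list(wide.columns)
    values = wide.to_numpy()
    proteins = wide.index.get_level_values(0).to_numpy()
    rows = []
    start = 0
    n = len(proteins)
    while start < n:
        stop = start
        while stop < n and proteins[stop] == proteins[start]:
            stop += 1
        block = values[start:stop]
        res = median_polish_matrix(block, max_iter=max_iter, tol=tol)
        observed = ~np.all(np.isnan(block), axis=0)
        profile = res.col_profile
        for j in np.flatnonzero(observed):
            rows.append((proteins[start], sample_order[j], profile[j]))
        start = stop
    out = pd.DataFrame(rows, columns=[cfg.protein_col, cfg.sample_col,
                                      cfg.response_col])
    return _as_protein_table(out, table)


def top_n(table: QuantTable, n: int = 3) -> QuantTable:
    """Protein abundance = per-sample mean of the N overall-strongest peptides.

    Peptides are ranked by their mean abundance across samples, descending,
    ties broken by peptide identifier; per sample the mean is taken over
    the top-N peptides' values present in that sample.
    """
    if not table.is_peptide_level:
        raise UsageError("top_n requires a peptide-level table")
    if n < 1:
        raise UsageError("n must be >= 1")
    cfg = table.config
    means = (table.data.groupby([cfg.protein_col, cfg.peptide_col])[cfg.response_col]
             .mean().reset_index())
    means = means.sort_values([cfg.protein_col, cfg.response_col, cfg.peptide_col],
                              ascending=[True, False, True])
    top = means.groupby(cfg.protein_col).head(n)[[cfg.protein_col, cfg.peptide_col]]
    sel = table.data.merge(top, on=[cfg.protein_col, cfg.peptide_col])
    out = (sel.groupby([cfg.protein_col, cfg.sample_col])[cfg.response_col]
           .mean().reset_index())
    return _as_protein_table(out, table)


def _as_protein_table(records: pd.DataFrame, source: QuantTable) -> QuantTable:
    cfg = source.config
    ann = source.annotation
    records = records.merge(ann, on=cfg.sample_col, how="left")
    new_cfg = cfg.evolve(peptide_col=None)
    return QuantTable(records, new_cfg, annotation=ann)


def summarize_counts(table: QuantTable) -> dict[str, pd.Series]:
    """Per-sample protein counts and (for peptide tables) peptides per protein."""
    cfg = table.config
    out: dict[str, pd.Series] = {}
    if table.n_records == 0:
        out["proteins_per_sample"] = pd.Series(dtype=int)
        if table.is_peptide_level:
            out["peptides_per_protein"] = pd.Series(dtype=int)
        return out
    out["proteins_per_sample"] = (table.data.groupby(cfg.sample_col)[cfg.protein_col]
                                  .nunique())
    if table.is_peptide_level:
        out["peptides_per_protein"] = (table.data
                                       .groupby(cfg.protein_col)[cfg.peptide_col]
                                       .nunique())
    return out
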