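"""The standard differential-expression workflow, end to end.

Chains the library modules in the canonical order: (peptide-level input)
one-hit-wonder filter -> log2 -> robust scaling -> median-polish rollup ->
per-protein linear models -> plain and moderated contrasts, with the
missing-data strategy filling in proteins the linear model could not
estimate, and Benjamini-Hochberg FDR on the merged table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aggregate, preprocess
from .contrasts import (ContrastResults, adjust_fdr, contrasts_missing,
                        merge_contrasts, moderate)
from .data import QuantTable
from .model import ProteinLinearModel, ProteinLMResults, estimate_lod

__all__ = ["DEAResult", "run_dea_pipeline"]


@dataclass
class DEAResult:
    """All artifacts of one differential-expression run."""

    protein_table: QuantTable
    model_results: ProteinLMResults
    plain: ContrastResults
    moderated: ContrastResults
    missing: ContrastResults
    merged: ContrastResults            # moderated preferred, missing added
    scale_params: preprocess.ScaleParams | None
    a_lod: float | None

    def summary(self) -> str:
        parts = [self.model_results.summary(), "", self.merged.summary()]
        return "\n".join(parts)


def run_dea_pipeline(table: QuantTable, contrasts: list[str],
                     min_peptides: int = 2, normalize: bool = True,
                     reference_proteins=None,
                     aggregation: str = "median_polish",
                     top_n: int = 3,
                     formula: str | None = None,
                     lod: float | None = None,
                     moderate_missing: bool = True) -> DEAResult:
    """Run the standard workflow on a linear-scale quantification table.

    Parameters
    ----------
    table
        Linear-scale QuantTable (peptide or protein level), e.g. straight
        from one of the readers or the simulator.
    contrasts
        Contrast specification strings over group levels, e.g.
        ``["e - d", "d - c"]``.
    min_peptides
        Minimum distinct peptides per protein (peptide-level input only).
    normalize
        Apply robust scaling after the log2 transform.
    reference_proteins
        Optional constant-concentration protein subset anchoring the
        scaling.
    aggregation
        ``"median_polish"``, ``"top_n"`` or ``"none"`` (protein-level
        input is never aggregated).
    formula
        Model formula; defaults to the product of the configured factors.
    lod
        Detection-limit abundance override for the missing-data strategy.
    moderate_missing
        Also apply variance moderation to the missing-data results before
        merging.
    """
    if table.is_peptide_level:
        if min_peptides > 1:
            table = preprocess.filter_min_peptides(table, min_peptides)
    work = preprocess.log2_transform(table) if not table.config.log_transformed \
        else table
    scale_params = None
    if normalize:
        work, scale_params = preprocess.robust_scale(
            work, reference_proteins=reference_proteins)
    if work.is_peptide_level and aggregation != "none":
        if aggregation == "median_polish":
            protein_table = aggregate.median_polish(work)
        elif aggregation == "top_n":
            protein_table = aggregate.top_n(work, n=top_n)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    else:
        protein_table = work

    model = ProteinLinearModel(protein_table, formula=formula)
    fitted = model.fit()
    plain = adjust_fdr(fitted.contrasts(contrasts))
    moderated = adjust_fdr(moderate(plain))

    a_lod = lod
    if a_lod is None:
        try:
            a_lod = estimate_lod(protein_table).a_lod
        except ValueError:
            a_lod = None
    if a_lod is not None:
        missing = contrasts_missing(protein_table, contrasts,
                                    design=model.design, lod=a_lod)
        if moderate_missing and len(missing):
            missing = moderate(missing)
        missing = adjust_fdr(missing)
    else:
        missing = ContrastResults(pd.DataFrame())
    merged = adjust_fdr(merge_contrasts(moderated, missing))
    return DEAResult(protein_table=protein_table, model_results=fitted,
                     plain=plain, moderated=moderated, missing=missing,
                     merged=merged, scale_params=scale_params, a_lod=a_lod)
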