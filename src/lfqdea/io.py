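"""Readers for common quantification-software outputs.

Supported inputs:

* MaxQuant ``peptide.txt`` — wide TSV with one ``Intensity <sample>``
  column per sample (peptide level),
* FragPipe ``combined_protein.tsv`` — wide TSV with one intensity column
  per sample (protein level),
* generic tidy long tables (MSstats-style TSV/CSV) described by an
  :class:`~lfqdea.data.AnalysisConfig`.

All readers return a :class:`~lfqdea.data.QuantTable` on the linear
intensity scale with zero/absent intensities dropped, ready for
:func:`~lfqdea.preprocess.log2_transform`.

The sample annotation is a table with a ``sample`` column plus one column
per grouping factor; every sample in the input must be annotated and vice
versa.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import AnalysisConfig, QuantTable, ValidationError

__all__ = [
    "FormatError",
    "AnnotationError",
    "read_annotation",
    "read_maxquant_peptides",
    "read_fragpipe_combined_protein",
    "read_long_table",
    "write_long_table",
]


class FormatError(ValueError):
    """The input file does not match the expected dialect."""


class AnnotationError(ValueError):
    """Sample annotation and input file do not cover the same samples."""


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_annotation(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-annotation table (column ``sample`` + factor columns)."""
    ann = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    if "sample" not in ann.columns:
        raise FormatError("annotation file must contain a 'sample' column")
    if ann.shape[1] < 2:
        raise FormatError("annotation file must contain at least one factor column")
    return ann


def _coerce_annotation(annotation: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(annotation, (str, Path)):
        annotation = read_annotation(annotation)
    if "sample" not in annotation.columns:
        raise FormatError("annotation must contain a 'sample' column")
    return annotation.astype(str)


def _check_samples(file_samples: list[str], annotation: pd.DataFrame) -> None:
    ann_samples = set(annotation["sample"])
    unannotated = sorted(set(file_samples) - ann_samples)
    if unannotated:
        raise AnnotationError(f"samples present in the input but missing from "
                              f"the annotation: {unannotated}")
    absent = sorted(ann_samples - set(file_samples))
    if absent:
        raise AnnotationError(f"annotated samples without an intensity column "
                              f"in the input: {absent}")


def _wide_to_long(df: pd.DataFrame, id_vars: list[str], sample_cols: dict[str, str],
                  annotation: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide intensity block; drop zero/NaN intensities."""
    long = df[id_vars + list(sample_cols)].melt(
        id_vars=id_vars, var_name="_col", value_name="intensity")
    long["sample"] = long["_col"].map(sample_cols)
    long = long.drop(columns="_col")
    long["intensity"] = pd.to_numeric(long["intensity"], errors="coerce")
    long = long[long["intensity"].to_numpy() > 0]
    return long.merge(annotation, on="sample", how="left")


def read_maxquant_peptides(path: str | Path,
                           annotation: pd.DataFrame | str | Path,
                           intensity_prefix: str = "Intensity ") -> QuantTable:
    """Read a MaxQuant ``peptide.txt`` into a peptide-level QuantTable.

    Rows flagged as reverse decoys or potential contaminants are dropped.
    The protein identifier is the "Leading razor protein" when that column
    is present, otherwise the first entry of "Proteins" (a peptide must map
    to exactly one protein for the peptide-to-protein rollup).
    """
    annotation = _coerce_annotation(annotation)
    df = pd.read_csv(path, sep="\t", low_memory=False)
    if "Sequence" not in df.columns:
        raise FormatError("MaxQuant peptide.txt must contain a 'Sequence' column")
    if "Leading razor protein" in df.columns:
        df["_protein"] = df["Leading razor protein"].astype(str)
    elif "Proteins" in df.columns:
        df["_protein"] = df["Proteins"].astype(str).str.split(";").str[0]
    else:
        raise FormatError("MaxQuant peptide.txt must contain a "
                          "'Leading razor protein' or 'Proteins' column")
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            df = df[df[flag].astype(str) != "+"]
    sample_cols = {c: c[len(intensity_prefix):] for c in df.columns
                   if c.startswith(intensity_prefix) and c != intensity_prefix.strip()}
    _check_samples(list(sample_cols.values()), annotation)
    long = _wide_to_long(df.rename(columns={"Sequence": "peptide",
                                            "_protein": "protein"}),
                         ["protein", "peptide"], sample_cols, annotation)
    config = AnalysisConfig(sample_col="sample",
                            group_cols=tuple(c for c in annotation.columns if c != "sample"),
                            protein_col="protein", peptide_col="peptide",
                            response_col="intensity", log_transformed=False)
    return QuantTable(long, config, annotation=annotation)


def read_fragpipe_combined_protein(path: str | Path,
                                   annotation: pd.DataFrame | str | Path,
                                   intensity_suffix: str = " Total Intensity"
                                   ) -> QuantTable:
    """Read a FragPipe ``combined_protein.tsv`` into a protein-level table.

    Sample columns are those ending with ``intensity_suffix`` (the prefix is
    taken as the sample name); the suffix is configurable because FragPipe
    versions differ in column naming.
    """
    annotation = _coerce_annotation(annotation)
    df = pd.read_csv(path, sep="\t", low_memory=False)
    if "Protein" not in df.columns:
        raise FormatError("FragPipe combined_protein.tsv must contain a "
                          "'Protein' column")
    sample_cols = {c: c[:-len(intensity_suffix)] for c in df.columns
                   if c.endswith(intensity_suffix)}
    if not sample_cols:
        raise FormatError(f"no columns ending with {intensity_suffix!r} found")
    _check_samples(list(sample_cols.values()), annotation)
    long = _wide_to_long(df.rename(columns={"Protein": "protein"}),
                         ["protein"], sample_cols, annotation)
    config = AnalysisConfig(sample_col="sample",
                            group_cols=tuple(c for c in annotation.columns if c != "sample"),
                            protein_col="protein", peptide_col=None,
                            response_col="intensity", log_transformed=False)
    return QuantTable(long, config, annotation=annotation)


def read_long_table(path: str | Path, config: AnalysisConfig,
                    annotation: pd.DataFrame | None = None,
                    sep: str | None = None) -> QuantTable:
    """Read a generic tidy long table described by ``config``.

    Zero (linear scale only) and missing abundances are dropped; the result
    is validated and a :class:`~lfqdea.data.ValidationError` carrying the
    full violation list is raised if any invariant fails.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), low_memory=False)
    missing = [c for c in config.columns if c not in df.columns]
    if missing:
        raise FormatError(f"input is missing configured columns: {missing}")
    df[config.response_col] = pd.to_numeric(df[config.response_col], errors="coerce")
    vals = df[config.response_col].to_numpy(dtype=float)
    keep = np.isfinite(vals) if config.log_transformed else vals > 0
    table = QuantTable(df.loc[keep], config, annotation=annotation)
    violations = table.validate()
    if violations:
        raise ValidationError("invalid long table:\n- " + "\n- ".join(violations))
    return table


def write_long_table(table: QuantTable, path: str | Path) -> None:
    """Write the records of a QuantTable as a tidy TSV/CSV."""
    table.data.to_csv(path, sep=_infer_sep(path, None), index=False)
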