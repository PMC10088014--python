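"""Tidy data model for label-free quantification tables.

All downstream operations work on a :class:`QuantTable` — a long ("tidy")
table with one row per observed abundance — together with an
:class:`AnalysisConfig` that maps the table's column names onto semantic
roles (sample, grouping factors, protein, optional peptide, response).
Mapping columns to roles once up front means that filtering, scaling,
rollup, modelling and benchmarking never take column-name arguments.

Missing observations are represented by the *absence* of a record, never by
a sentinel value: a zero intensity reported by quantification software is
dropped at read time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnalysisConfig",
    "QuantTable",
    "ConfigError",
    "ValidationError",
    "CELL_SEP",
]

#: separator used to build a group-cell key from multiple factor levels
CELL_SEP = ":"


class ConfigError(ValueError):
    """Raised when an AnalysisConfig is internally inconsistent."""


class ValidationError(ValueError):
    """Raised when a table violates the tidy-table invariants."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Maps column names of a quantification table to semantic roles.

    Parameters
    ----------
    sample_col
        Column holding the (opaque) sample identifier.
    group_cols
        Ordered grouping-factor columns; at least one is required. The
        first level of each factor (lexicographic, unless ``level_order``
        is given) is the reference level for model coding.
    protein_col
        Column holding the protein identifier.
    response_col
        Column holding the abundance value.
    peptide_col
        Column holding the peptide identifier; ``None`` for protein-level
        tables.
    log_transformed
        Whether the response is on the log2 scale. On the linear scale
        abundances must be strictly positive; on the log2 scale they must
        be finite.
    level_order
        Optional explicit level order per factor, e.g.
        ``{"group": ("ctrl", "treated")}``.
    """

    sample_col: str = "sample"
    group_cols: tuple[str, ...] = ("group",)
    protein_col: str = "protein"
    response_col: str = "intensity"
    peptide_col: str | None = None
    log_transformed: bool = False
    level_order: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_cols", tuple(self.group_cols))
        if not self.group_cols:
            raise ConfigError("at least one grouping-factor column is required")
        roles = [self.sample_col, self.protein_col, self.response_col,
                 *self.group_cols]
        if self.peptide_col is not None:
            roles.append(self.peptide_col)
        reused = sorted({c for c in roles if roles.count(c) > 1})
        if reused:
            raise ConfigError(f"column roles must name distinct columns; reused: {reused}")

    # ------------------------------------------------------------------ roles
    @property
    def is_peptide_level(self) -> bool:
        return self.peptide_col is not None

    @property
    def id_cols(self) -> list[str]:
        """Analyte identifier columns (protein, plus peptide when present)."""
        cols = [self.protein_col]
        if self.peptide_col is not None:
            cols.append(self.peptide_col)
        return cols

    @property
    def key_cols(self) -> list[str]:
        """Columns forming the unique record key."""
        return [*self.id_cols, self.sample_col]

    @property
    def columns(self) -> list[str]:
        """All role columns in canonical order."""
        return [*self.key_cols, *self.group_cols, self.response_col]

    def evolve(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = {
            "sample_col": self.sample_col,
            "group_cols": list(self.group_cols),
            "protein_col": self.protein_col,
            "response_col": self.response_col,
            "peptide_col": self.peptide_col,
            "log_transformed": self.log_transformed,
        }
        if self.level_order is not None:
            d["level_order"] = {k: list(v) for k, v in self.level_order.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "group_cols" in d:
            d["group_cols"] = tuple(d["group_cols"])
        if d.get("level_order") is not None:
            d["level_order"] = {k: tuple(v) for k, v in d["level_order"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class QuantTable:
    """A tidy long table of abundance records plus its column-role config.

    One row per observed (protein [, peptide], sample) abundance. The
    sample annotation (sample -> factor levels) is carried separately so
    that groups remain known even when every observation of a group has
    been dropped for some protein.
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig,
                 annotation: pd.DataFrame | None = None):
        missing = [c for c in config.columns if c not in data.columns]
        if missing:
            raise ValidationError(f"table is missing configured columns: {missing}")
        self.config = config
        self.data = data.loc[:, config.columns].reset_index(drop=True)
        if annotation is None:
            annotation = self.data[[config.sample_col, *config.group_cols]]
        else:
            miss = [c for c in (config.sample_col, *config.group_cols)
                    if c not in annotation.columns]
            if miss:
                raise ValidationError(f"annotation is missing columns: {miss}")
            annotation = annotation[[config.sample_col, *config.group_cols]]
        self.annotation = annotation.drop_duplicates().reset_index(drop=True)

    # ---------------------------------------------------------------- basics
    @property
    def is_peptide_level(self) -> bool:
        return self.config.is_peptide_level

    @property
    def samples(self) -> list[str]:
        return list(self.annotation[self.config.sample_col])

    @property
    def n_records(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        level = "peptide" if self.is_peptide_level else "protein"
        return (f"QuantTable({level}-level, {self.n_records} records, "
                f"{self.data[self.config.protein_col].nunique()} proteins, "
                f"{len(self.samples)} samples)")

    def group_levels(self, factor: str) -> list[str]:
        """Ordered levels of a grouping factor (first level = reference)."""
        if factor not in self.config.group_cols:
            raise ConfigError(f"unknown grouping factor: {factor!r}")
        if self.config.level_order and factor in self.config.level_order:
            return list(self.config.level_order[factor])
        return sorted(self.annotation[factor].astype(str).unique())

    def cell_of_sample(self) -> pd.Series:
        """Sample -> group-cell key (factor levels joined by ':')."""
        ann = self.annotation
        cells = ann[list(self.config.group_cols)].astype(str).agg(CELL_SEP.join, axis=1)
        return pd.Series(cells.values, index=ann[self.config.sample_col].values,
                         name="cell")

    def with_data(self, data: pd.DataFrame,
                  config: AnalysisConfig | None = None) -> "QuantTable":
        """New table with replaced records (same annotation)."""
        cfg = config if config is not None else self.config
        ann = self.annotation
        if config is not None and (config.sample_col != self.config.sample_col
                                   or config.group_cols != self.config.group_cols):
            ann = None
        return QuantTable(data, cfg, annotation=ann)

    # ------------------------------------------------------------ validation
    def validate(self) -> list[str]:
        """Check the tidy-table invariants; one message per violation."""
        cfg = self.config
        out: list[str] = []
        dup = self.data.duplicated(cfg.key_cols, keep=False)
        if dup.any():
            keys = (self.data.loc[dup, cfg.key_cols]
                    .drop_duplicates().head(5).to_dict("records"))
            out.append(f"duplicate record keys ({int(dup.sum())} rows), e.g. {keys}")
        resp = self.data[cfg.response_col]
        if cfg.log_transformed:
            bad = ~np.isfinite(resp.to_numpy(dtype=float))
            if bad.any():
                out.append(f"non-finite log2 abundances in {int(bad.sum())} rows")
        else:
            vals = resp.to_numpy(dtype=float)
            bad = ~(vals > 0)
            if bad.any():
                out.append("non-positive or missing abundances on the linear "
                           f"scale in {int(bad.sum())} rows")
        ann = self.annotation
        dup_s = ann[cfg.sample_col][ann[cfg.sample_col].duplicated()]
        if len(dup_s):
            out.append("samples mapped to more than one group level: "
                       f"{sorted(dup_s.unique())}")
        known = set(ann[cfg.sample_col])
        in_data = set(self.data[cfg.sample_col].unique())
        unknown = sorted(in_data - known)
        if unknown:
            out.append(f"samples present in data but not annotated: {unknown}")
        # data group labels must agree with the annotation
        pairs = self.data[[cfg.sample_col, *cfg.group_cols]].drop_duplicates()
        merged = pairs.merge(ann.drop_duplicates(cfg.sample_col),
                             on=cfg.sample_col, suffixes=("", "_ann"))
        for f in cfg.group_cols:
            mism = merged[merged[f].astype(str) != merged[f + "_ann"].astype(str)]
            if len(mism):
                out.append(f"factor {f!r} levels in data disagree with the "
                           f"annotation for samples {sorted(mism[cfg.sample_col].unique())}")
        return out

    def complete_cases(self) -> "QuantTable":
        """Drop records with a missing abundance; keep the full annotation."""
        resp = self.data[self.config.response_col]
        keep = np.isfinite(resp.to_numpy(dtype=float))
        return QuantTable(self.data.loc[keep], self.config, annotation=self.annotation)

    # ------------------------------------------------------------------- io
    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def annotation_to_tsv(self, path: str | Path) -> None:
        self.annotation.to_csv(path, sep="\t", index=False)
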