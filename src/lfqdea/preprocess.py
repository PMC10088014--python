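"""Filtering, log2 transformation and robust scaling of abundances.

Robust scaling is a robust z-score: per sample the location is the median
x-tilde of the sample's log2 abundances and the scale is the (normal
consistent) median absolute deviation S-tilde.  To keep group differences
interpretable on the log2 scale, the z-score is multiplied by the mean
scale over all samples and shifted by the mean location:

    scaled = (x - x_tilde_s) / S_tilde_s * mean(S_tilde) + mean(x_tilde)

Optionally, location and scale are estimated from a reference subset of
proteins whose concentration is known to be constant across samples (for a
two-species spike-in: the background species) and then applied to all
records of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.stats import median_abs_deviation

from .data import QuantTable

__all__ = [
    "ScaleParams",
    "DegenerateScaleError",
    "UsageError",
    "filter_min_peptides",
    "log2_transform",
    "robust_scale",
]


class UsageError(ValueError):
    """An operation was applied to a table of the wrong level/state."""


class DegenerateScaleError(ValueError):
    """A sample's abundance spread is zero; robust scaling is undefined."""


@dataclass
class ScaleParams:
    """Per-sample robust location/scale and their across-sample means."""

    locations: pd.Series   # index: sample -> median log2 abundance
    scales: pd.Series      # index: sample -> MAD (normal consistent)
    mean_location: float
    mean_scale: float
    n_reference: pd.Series | None = None  # reference observations per sample

    def to_dict(self) -> dict:
        d = {
            "locations": {str(k): float(v) for k, v in self.locations.items()},
            "scales": {str(k): float(v) for k, v in self.scales.items()},
            "mean_location": float(self.mean_location),
            "mean_scale": float(self.mean_scale),
        }
        if self.n_reference is not None:
            d["n_reference"] = {str(k): int(v) for k, v in self.n_reference.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleParams":
        nref = d.get("n_reference")
        return cls(locations=pd.Series(d["locations"]),
                   scales=pd.Series(d["scales"]),
                   mean_location=float(d["mean_location"]),
                   mean_scale=float(d["mean_scale"]),
                   n_reference=pd.Series(nref) if nref is not None else None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScaleParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def filter_min_peptides(table: QuantTable, min_peptides: int = 2) -> QuantTable:
    """Keep proteins identified by at least ``min_peptides`` distinct peptides.

    With the default of 2 this removes "one-hit wonders" — proteins with a
    single peptide assignment, whose quantification is unreliable. Peptides
    are counted across all samples.
    """
    if not table.is_peptide_level:
        raise UsageError("filter_min_peptides requires a peptide-level table")
    if min_peptides < 1:
        raise UsageError("min_peptides must be >= 1")
    cfg = table.config
    counts = table.data.groupby(cfg.protein_col)[cfg.peptide_col].nunique()
    keep = counts.index[counts >= min_peptides]
    data = table.data[table.data[cfg.protein_col].isin(set(keep))]
    return table.with_data(data)


def log2_transform(table: QuantTable) -> QuantTable:
    """Replace linear-scale abundances by their log2; flips the config flag."""
    cfg = table.config
    if cfg.log_transformed:
        raise UsageError("table is already log2 transformed")
    vals = table.data[cfg.response_col].to_numpy(dtype=float)
    if not (vals > 0).all():
        raise UsageError("all abundances must be strictly positive before log2")
    data = table.data.copy()
    data[cfg.response_col] = np.log2(vals)
    return table.with_data(data, config=cfg.evolve(log_transformed=True))


def robust_scale(table: QuantTable,
                 reference_proteins: Iterable[str] | None = None
                 ) -> tuple[QuantTable, ScaleParams]:
    """Robustly scale log2 abundances sample by sample.

    Parameters
    ----------
    table
        A log2-transformed QuantTable (peptide or protein level).
    reference_proteins
        Optional set of protein ids from which each sample's location and
        scale are estimated (every sample needs >= 2 reference
        observations); the transformation is applied to all records.

    Returns
    -------
    (scaled_table, params)
    """
    cfg = table.config
    if not cfg.log_transformed:
        raise UsageError("robust_scale requires a log2-transformed table")
    data = table.data
    if reference_proteins is not None:
        ref_set = set(reference_proteins)
        ref = data[data[cfg.protein_col].isin(ref_set)]
    else:
        ref = data

    grp = ref.groupby(cfg.sample_col)[cfg.response_col]
    nref = grp.size()
    samples_in_data = data[cfg.sample_col].unique()
    if reference_proteins is not None:
        short = sorted(set(samples_in_data) - set(nref.index[nref >= 2]))
        if short:
            raise UsageError("samples with fewer than 2 reference observations: "
                             f"{short}")
    loc = grp.median()
    scale = grp.apply(lambda x: median_abs_deviation(x, scale="normal"))
    degenerate = sorted(scale.index[~(scale.to_numpy() > 0)])
    if degenerate:
        raise DegenerateScaleError(f"zero abundance spread in samples: {degenerate}")

    mean_scale = float(scale.mean())
    mean_loc = float(loc.mean())
    out = data.copy()
    s = out[cfg.sample_col]
    z = (out[cfg.response_col].to_numpy(dtype=float)
         - loc.reindex(s).to_numpy()) / scale.reindex(s).to_numpy()
    out[cfg.response_col] = z * mean_scale + mean_loc
    params = ScaleParams(locations=loc, scales=scale, mean_location=mean_loc,
                         mean_scale=mean_scale,
                         n_reference=nref if reference_proteins is not None else None)
    return table.with_data(out), params
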