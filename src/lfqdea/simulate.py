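"""Synthetic two-species spike-in experiments with known ground truth.

The generator emulates a benchmark design in which a lysate of one
organism is spiked at several known concentrations into a constant
background proteome of another organism: background proteins have a true
between-group log2 difference of 0, spike proteins of
``log2(level_g1 / level_g2)``.  The default design uses five dilution
groups at 3, 4.5, 6, 7.5 and 9 percent spike (annotated ``a``-``e`` from
smallest to largest) with four technical replicates each, i.e. 20
samples; comparing the two largest dilutions gives an expected linear
ratio of 9/7.5 = 1.2 for spike proteins and 1 for the background.

Peptide-level log2 abundances are generated additively —

    base_protein + peptide_offset + sample_shift + spike_effect + noise

— with per-protein residual standard deviations drawn from a scaled
inverse chi-square distribution (so empirical-Bayes variance shrinkage
has a true prior to recover) and missing-not-at-random dropout: a record
is censored with logistic probability as its value falls below the limit
of detection.  Intensities are reported on the linear scale, like the raw
output of quantification software.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import AnalysisConfig, QuantTable

__all__ = ["SimParams", "SimOutput", "simulate_experiment",
           "default_ionstar_design", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = ["protein", "label", "contrast", "expected_log2_diff"]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-species spike-in generator.

    Defaults reproduce the dilution-series design described in the module
    docstring; abundance units are log2 intensities.
    """

    n_background: int = 1000
    n_spike: int = 200
    spike_levels: tuple[float, ...] = (3.0, 4.5, 6.0, 7.5, 9.0)
    n_reps: int = 4
    peptides_per_protein_mean: float = 8.0   # shifted Poisson, min 1
    base_mean: float = 20.0                  # protein base log2 abundance
    base_sd: float = 2.5
    peptide_sd: float = 1.5                  # peptide ionisation offset
    sample_sd: float = 0.2                   # per-sample systematic shift
    residual_prior_df: float = 4.0           # d0 of the variance prior
    residual_prior_scale: float = 0.15       # s0 (sd scale) of the prior
    lod: float = 14.0                        # log2 limit of detection
    dropout_width: float = 1.0               # logistic censoring width
    dropout: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_background < 1 or self.n_spike < 0 or self.n_reps < 1:
            raise ValueError("counts must be positive")
        if len(set(self.spike_levels)) != len(self.spike_levels) or \
                any(l <= 0 for l in self.spike_levels):
            raise ValueError("spike levels must be distinct and positive")
        if self.peptides_per_protein_mean < 1:
            raise ValueError("peptides_per_protein_mean must be >= 1")

    @property
    def groups(self) -> list[str]:
        return list(string.ascii_lowercase[:len(self.spike_levels)])

    @property
    def n_samples(self) -> int:
        return len(self.spike_levels) * self.n_reps

    def evolve(self, **changes) -> "SimParams":
        return replace(self, **changes)


def default_ionstar_design(**overrides) -> SimParams:
    """The five-group dilution-series design (a-e at 3/4.5/6/7.5/9%, 4 reps)."""
    return SimParams(**overrides)


@dataclass
class SimOutput:
    """Simulated experiment: observed table, censoring-free table, truth."""

    table: QuantTable            # linear-scale, censored (observed) records
    complete_table: QuantTable   # linear-scale, pre-censoring, for oracles
    truth_labels: pd.DataFrame   # protein, label (changed/unchanged)
    params: SimParams

    def ground_truth(self, contrasts) -> pd.DataFrame:
        """Expected log2 differences per (protein, contrast).

        ``contrasts`` are specification strings over group names, e.g.
        ``"e - d"``; background proteins have expected difference 0.
        """
        from .contrasts import parse_linear_expression
        p = self.params
        level_of = dict(zip(p.groups, p.spike_levels))
        rows = []
        for expr in contrasts:
            weights = parse_linear_expression(expr)
            unknown = sorted(set(weights) - set(level_of))
            if unknown:
                raise ValueError(f"unknown groups in contrast {expr!r}: {unknown}")
            delta = sum(w * np.log2(level_of[g]) for g, w in weights.items())
            for _, r in self.truth_labels.iterrows():
                rows.append((r["protein"], r["label"], expr,
                             float(delta) if r["label"] == "changed" else 0.0))
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_experiment(params: SimParams | None = None) -> SimOutput:
    """Generate one experiment; deterministic for a given ``params.seed``."""
    p = params if params is not None else SimParams()
    rng = np.random.default_rng(p.seed)

    groups = p.groups
    samples = [f"{g}{r + 1}" for g in groups for r in range(p.n_reps)]
    group_of_sample = np.repeat(groups, p.n_reps)
    annotation = pd.DataFrame({"sample": samples, "group": group_of_sample})

    n_prot = p.n_background + p.n_spike
    is_spike = np.arange(n_prot) < p.n_spike
    proteins = np.where(is_spike,
                        [f"ECOLI_{i:05d}" for i in range(n_prot)],
                        [f"HUMAN_{i:05d}" for i in range(n_prot)])

    n_pep = 1 + rng.poisson(p.peptides_per_protein_mean - 1.0, size=n_prot)
    base = rng.normal(p.base_mean, p.base_sd, size=n_prot)
    sigma = p.residual_prior_scale * np.sqrt(
        p.residual_prior_df / rng.chisquare(p.residual_prior_df, size=n_prot))
    shift = rng.normal(0.0, p.sample_sd, size=p.n_samples)
    log2_level = np.log2(np.asarray(p.spike_levels) / p.spike_levels[0])
    effect_by_group = {g: (log2_level[i]) for i, g in enumerate(groups)}
    sample_effect = np.array([effect_by_group[g] for g in group_of_sample])

    total_pep = int(n_pep.sum())
    prot_idx = np.repeat(np.arange(n_prot), n_pep)
    pep_within = np.concatenate([np.arange(k) for k in n_pep])
    offsets = rng.normal(0.0, p.peptide_sd, size=total_pep)

    ns = p.n_samples
    # (total_pep x n_samples) matrix of log2 values
    values = (base[prot_idx][:, None] + offsets[:, None]
              + shift[None, :]
              + np.where(is_spike[prot_idx][:, None],
                         sample_effect[None, :], 0.0)
              + rng.normal(0.0, 1.0, size=(total_pep, ns))
              * sigma[prot_idx][:, None])

    if p.dropout:
        censor = rng.random((total_pep, ns)) < expit((p.lod - values)
                                                     / p.dropout_width)
    else:
        censor = np.zeros_like(values, dtype=bool)

    pep_names = np.array([f"{proteins[i]}_pep{j:02d}"
                          for i, j in zip(prot_idx, pep_within)])
    long = pd.DataFrame({
        "protein": np.repeat(proteins[prot_idx], ns),
        "peptide": np.repeat(pep_names, ns),
        "sample": np.tile(samples, total_pep),
        "group": np.tile(group_of_sample, total_pep),
        "intensity": np.power(2.0, values).ravel(),
    })
    censored = censor.ravel()

    config = AnalysisConfig(sample_col="sample", group_cols=("group",),
                            protein_col="protein", peptide_col="peptide",
                            response_col="intensity", log_transformed=False)
    table = QuantTable(long.loc[~censored], config, annotation=annotation)
    complete = QuantTable(long, config, annotation=annotation)
    truth = pd.DataFrame({"protein": proteins,
                          "label": np.where(is_spike, "changed", "unchanged")})
    return SimOutput(table=table, complete_table=complete,
                     truth_labels=truth, params=p)
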