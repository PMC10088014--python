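"""Per-protein fixed-effects linear models.

The modelling surface follows the Model/Results convention: a
:class:`ProteinLinearModel` is built from a :class:`~lfqdea.data.QuantTable`
and a formula over the annotated grouping factors; ``fit()`` returns a
:class:`ProteinLMResults` holding one ordinary-least-squares fit per
analyte (protein, or peptide for peptide-level tables), from which group
contrasts and their inferential statistics are computed (see
:mod:`lfqdea.contrasts`).

Designs use treatment (reference-level) coding with a deterministic term
naming scheme: ``Intercept``, ``factor:level`` for main effects and
``f1:l1×f2:l2`` for two-way interactions.  Unbalanced designs are fitted
as-is; coefficients that become inestimable because a whole group is
unobserved are dropped and flagged rather than raising — whole-group
dropout is routine in label-free data and is handled downstream by the
missing-data contrast strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CELL_SEP, AnalysisConfig, QuantTable

__all__ = [
    "Design",
    "DesignError",
    "ModelFit",
    "PooledVariance",
    "LodEstimate",
    "build_design",
    "fit_protein",
    "pooled_variance",
    "estimate_lod",
    "ProteinLinearModel",
    "ProteinLMResults",
]


class DesignError(ValueError):
    """The formula or annotation cannot produce a valid design."""


@dataclass
class Design:
    """A fixed-effects design matrix over annotated samples.

    Attributes
    ----------
    matrix
        Samples x terms indicator matrix (treatment coding, intercept
        included).
    terms
        Column names of ``matrix``.
    cell_of
        Sample -> group-cell key (levels of the formula's factors joined
        by ':').
    cell_rows
        One design row per group cell; ``cell_rows @ beta`` gives the cell
        means, which is how contrast weight vectors are derived.
    """

    matrix: pd.DataFrame
    terms: list[str]
    cell_of: pd.Series
    cell_rows: pd.DataFrame
    formula: str
    factors: list[str]
    levels: dict[str, list[str]]

    @property
    def cells(self) -> list[str]:
        return list(self.cell_rows.index)


def _parse_formula(formula: str, known_factors: list[str]) -> list[tuple[str, ...]]:
    """Expand a formula into a list of terms (1-tuples = main effects)."""
    rhs = formula.split("~")[-1].strip()
    if not rhs:
        raise DesignError("empty formula")
    terms: list[tuple[str, ...]] = []
    for part in (p.strip() for p in rhs.split("+")):
        if not part:
            raise DesignError(f"malformed formula: {formula!r}")
        if "*" in part:
            facs = [f.strip() for f in part.split("*")]
            for f in facs:
                _add_term(terms, (f,))
            _add_term(terms, tuple(facs))
        elif ":" in part:
            _add_term(terms, tuple(f.strip() for f in part.split(":")))
        else:
            _add_term(terms, (part,))
    for t in terms:
        for f in t:
            if f not in known_factors:
                raise DesignError(f"unknown factor {f!r}; annotated factors: "
                                  f"{known_factors}")
        if len(t) > 2:
            raise DesignError("interactions deeper than two factors are not supported")
    return terms


def _add_term(terms: list, t: tuple) -> None:
    if t not in terms:
        terms.append(t)


def build_design(annotation: pd.DataFrame, config: AnalysisConfig,
                 formula: str | None = None) -> Design:
    """Build a treatment-coded design matrix from the sample annotation.

    The default formula is the product of all configured grouping factors
    (main effects plus interaction for two factors).
    """
    factors = list(config.group_cols)
    if formula is None:
        formula = " * ".join(factors)
    terms = _parse_formula(formula, factors)
    used = sorted({f for t in terms for f in t}, key=factors.index)

    ann = annotation.drop_duplicates(config.sample_col).set_index(config.sample_col)
    levels: dict[str, list[str]] = {}
    for f in used:
        if config.level_order and f in config.level_order:
            levels[f] = list(config.level_order[f])
        else:
            levels[f] = sorted(ann[f].astype(str).unique())

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(ann))}
    for t in terms:
        if len(t) == 1:
            f = t[0]
            for lvl in levels[f][1:]:
                cols[f"{f}:{lvl}"] = (ann[f].astype(str) == lvl).to_numpy(float)
        else:
            f1, f2 = t
            for l1 in levels[f1][1:]:
                for l2 in levels[f2][1:]:
                    name = f"{f1}:{l1}×{f2}:{l2}"
                    cols[name] = ((ann[f1].astype(str) == l1)
                                  & (ann[f2].astype(str) == l2)).to_numpy(float)
    matrix = pd.DataFrame(cols, index=ann.index)
    cell_of = ann[used].astype(str).agg(CELL_SEP.join, axis=1)
    cell_rows = matrix.groupby(cell_of).first()
    cell_rows = cell_rows.loc[sorted(cell_rows.index)]
    return Design(matrix=matrix, terms=list(matrix.columns), cell_of=cell_of,
                  cell_rows=cell_rows, formula=formula, factors=used,
                  levels=levels)


@dataclass
class ModelFit:
    """Everything a contrast needs from one analyte's OLS fit.

    Rank-deficient designs (whole groups unobserved) are fitted with the
    pseudoinverse: ``beta`` is the minimum-norm solution and
    ``cov_unscaled`` the generalized inverse (X'X)^+, so that c'beta and
    c'(X'X)^+c are correct for every *estimable* contrast c — a contrast
    is estimable iff c lies in the row space of the observed design,
    which ``is_estimable`` tests via the projection X^+X.
    """

    analyte: object
    beta: pd.Series                 # minimum-norm OLS solution
    cov_unscaled: pd.DataFrame      # (X'X)^+ over all terms
    sigma: float                    # residual sd (NaN when df == 0)
    df: int                         # residual degrees of freedom
    n_obs: int
    estimable: pd.Series            # bool per coefficient
    group_n: pd.Series              # per-cell observation count (0 incl.)
    group_mean: pd.Series
    group_sd: pd.Series
    _proj: np.ndarray | None = None  # X^+X row-space projection

    @property
    def fully_estimable(self) -> bool:
        return bool(self.estimable.all())

    def is_estimable(self, c: np.ndarray, atol: float = 1e-8) -> bool:
        """Whether the coefficient-weight vector c is estimable."""
        c = np.asarray(c, dtype=float)
        if self._proj is None:
            return bool(self.estimable[np.abs(c) > 0].all()) if np.any(c) else True
        return bool(np.max(np.abs(self._proj @ c - c)) <= atol * max(
            1.0, float(np.max(np.abs(c)))))


@dataclass
class PooledVariance:
    """Pooled within-group variance, weighted by group degrees of freedom."""

    s2: float
    group_n: dict
    n: int
    n_groups: int
    defined: bool

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.s2)) if self.defined else float("nan")


@dataclass
class LodEstimate:
    """Expected log2 abundance at the limit of detection.

    Estimated as the median abundance over all (protein, group) cells in
    which the protein was observed in exactly one sample — those
    observations sit right at the detection floor.
    """

    a_lod: float
    n_cells: int


class _OlsCache:
    """Shared OLS factorizations keyed by the observed-sample pattern."""

    def __init__(self, X: np.ndarray, terms: list[str]):
        self.X = X
        self.terms = terms
        self._store: dict[bytes, tuple] = {}

    def get(self, mask: np.ndarray):
        key = mask.tobytes()
        hit = self._store.get(key)
        if hit is None:
            hit = self._factorize(mask)
            self._store[key] = hit
        return hit

    def _factorize(self, mask: np.ndarray):
        Xm = self.X[mask]
        if Xm.shape[0] == 0:
            k = Xm.shape[1]
            return Xm, np.zeros((k, 0)), np.zeros((k, k)), np.zeros((k, k)), 0
        pinv = np.linalg.pinv(Xm)               # min-norm / generalized inverse
        cov_unscaled = pinv @ pinv.T            # (X'X)^+ ; = (X'X)^-1 at full rank
        proj = pinv @ Xm                        # projection onto the row space
        rank = int(round(np.trace(proj)))
        return Xm, pinv, cov_unscaled, proj, rank


def _finish_fit(analyte, y: np.ndarray, mask: np.ndarray, cache: _OlsCache,
                group_n: pd.Series, group_mean: pd.Series,
                group_sd: pd.Series) -> ModelFit:
    Xm, pinv, cov, proj, rank = cache.get(mask)
    terms = cache.terms
    yv = y[mask]
    n_obs = int(mask.sum())
    if n_obs and rank:
        b = pinv @ yv
        resid = yv - Xm @ b
        df = n_obs - rank
        sigma = float(np.sqrt(float(resid @ resid) / df)) if df > 0 \
            else float("nan")
    else:
        b = np.full(len(terms), np.nan)
        df, sigma = 0, float("nan")
    beta = pd.Series(b, index=terms, dtype=float)
    # a single coefficient is estimable iff its unit vector lies in the
    # row space, i.e. the projection leaves it unchanged
    est = np.max(np.abs(proj - np.eye(len(terms))), axis=0) <= 1e-8
    estimable = pd.Series(est, index=terms)
    cov_df = pd.DataFrame(cov, index=terms, columns=terms)
    return ModelFit(analyte=analyte, beta=beta, cov_unscaled=cov_df,
                    sigma=sigma, df=int(df), n_obs=n_obs, estimable=estimable,
                    group_n=group_n, group_mean=group_mean, group_sd=group_sd,
                    _proj=proj)


def fit_protein(y: pd.Series, design: Design, analyte: object = None) -> ModelFit:
    """OLS fit of one analyte's observed abundances against the design.

    ``y`` is indexed by sample; only samples present in the design are
    used. Group summary statistics (n, mean, sd per cell) are always
    computed from the raw values, independent of estimability.
    """
    y = y.dropna()
    y = y[y.index.isin(design.matrix.index)]
    order = design.matrix.index
    yfull = y.reindex(order)
    mask = yfull.notna().to_numpy()
    cache = _OlsCache(design.matrix.to_numpy(), list(design.matrix.columns))
    cells = design.cell_of.reindex(order)
    obs = pd.DataFrame({"y": yfull.to_numpy(), "cell": cells.to_numpy()}).dropna(subset=["y"])
    g = obs.groupby("cell")["y"]
    all_cells = design.cells
    group_n = g.size().reindex(all_cells, fill_value=0).astype(int)
    group_mean = g.mean().reindex(all_cells)
    group_sd = g.std(ddof=1).reindex(all_cells)
    return _finish_fit(analyte, yfull.to_numpy(dtype=float), mask, cache,
                       group_n, group_mean, group_sd)


def pooled_variance(fit: ModelFit) -> PooledVariance:
    """Degrees-of-freedom-weighted pooled variance over groups with n >= 2."""
    n = fit.group_n
    sd = fit.group_sd
    use = n[n >= 2].index
    if len(use) == 0:
        return PooledVariance(s2=float("nan"), group_n=n.to_dict(),
                              n=int(n.sum()), n_groups=int((n > 0).sum()),
                              defined=False)
    w = (n[use] - 1).to_numpy(dtype=float)
    s2 = float((w * sd[use].to_numpy() ** 2).sum() / w.sum())
    return PooledVariance(s2=s2, group_n=n.to_dict(), n=int(n.sum()),
                          n_groups=int((n > 0).sum()), defined=True)


def estimate_lod(table: QuantTable) -> LodEstimate:
    """Estimate the expected abundance at the limit of detection.

    Collects, over all proteins, the abundance of every (protein, group)
    cell with exactly one observation and returns the median. Intended for
    protein-level log2 tables.
    """
    cfg = table.config
    cell = table.cell_of_sample()
    df = table.data.copy()
    df["_cell"] = df[cfg.sample_col].map(cell)
    g = df.groupby([*cfg.id_cols, "_cell"])[cfg.response_col]
    counts = g.size()
    singles = counts[counts == 1].index
    if len(singles) == 0:
        raise ValueError("no (protein, group) cell with exactly one observation; "
                         "supply the detection-limit abundance explicitly")
    vals = g.first().loc[singles]
    return LodEstimate(a_lod=float(np.median(vals.to_numpy())),
                       n_cells=int(len(singles)))


class ProteinLinearModel:
    """Per-analyte fixed-effects linear model for a quantification table.

    Parameters
    ----------
    table
        A log2-scale QuantTable. For protein-level tables one model per
        protein is fitted; for peptide-level tables one model per
        (protein, peptide), which is the input the peptide-rollup contrast
        strategy needs.
    formula
        Formula over the annotated grouping factors, e.g. ``"group"`` or
        ``"treatment * timepoint"``. Defaults to the product of all
        configured factors.

    Examples
    --------
    >>> model = ProteinLinearModel(protein_table, formula="group")
    >>> res = model.fit()
    >>> contrasts = res.contrasts(["e - d"], moderated=True)
    """

    def __init__(self, table: QuantTable, formula: str | None = None):
        self.table = table.complete_cases()
        self.design = build_design(self.table.annotation, self.table.config,
                                   formula)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, config: AnalysisConfig,
                       formula: str | None = None,
                       annotation: pd.DataFrame | None = None) -> "ProteinLinearModel":
        return cls(QuantTable(data, config, annotation=annotation), formula)

    @property
    def formula(self) -> str:
        return self.design.formula

    def fit(self) -> "ProteinLMResults":
        cfg = self.table.config
        design = self.design
        sample_order = list(design.matrix.index)
        wide = self.table.data.pivot_table(index=cfg.id_cols,
                                           columns=cfg.sample_col,
                                           values=cfg.response_col,
                                           aggfunc="mean")
        wide = wide.reindex(columns=sample_order)
        values = wide.to_numpy(dtype=float)
        cache = _OlsCache(design.matrix.to_numpy(), list(design.matrix.columns))

        # group stats for all analytes in one pass
        cell = design.cell_of
        long = self.table.data.copy()
        long["_cell"] = long[cfg.sample_col].map(cell)
        g = long.groupby([*cfg.id_cols, "_cell"])[cfg.response_col]
        stats = pd.DataFrame({"n": g.size(), "mean": g.mean(),
                              "sd": g.std(ddof=1)})
        all_cells = design.cells
        stats_by_analyte: dict = {}
        nlev = len(cfg.id_cols)
        lev = 0 if nlev == 1 else list(range(nlev))
        for key, sub in stats.groupby(level=lev):
            stats_by_analyte[key] = sub.droplevel(lev).reindex(all_cells)

        fits: dict = {}
        for i, analyte in enumerate(wide.index):
            y = values[i]
            mask = np.isfinite(y)
            st = stats_by_analyte[analyte]
            group_n = st["n"].fillna(0).astype(int)
            fits[analyte] = _finish_fit(analyte, y, mask, cache,
                                        group_n, st["mean"], st["sd"])
        return ProteinLMResults(self, fits)


class ProteinLMResults:
    """Results container for :class:`ProteinLinearModel.fit`.

    Carries one :class:`ModelFit` per analyte; contrasts between groups are
    computed via :meth:`contrasts` (see :mod:`lfqdea.contrasts` for the
    individual strategies).
    """

    def __init__(self, model: ProteinLinearModel, fits: dict):
        self.model = model
        self.fits = fits

    @property
    def design(self) -> Design:
        return self.model.design

    @property
    def table(self) -> QuantTable:
        return self.model.table

    def __len__(self) -> int:
        return len(self.fits)

    def sigma_frame(self) -> pd.DataFrame:
        """Residual variance and df per analyte (input to moderation)."""
        rows = [(f.analyte, f.sigma ** 2, f.df, f.n_obs)
                for f in self.fits.values()]
        return pd.DataFrame(rows, columns=["analyte", "sigma2", "df", "n_obs"])

    def coefficients(self) -> pd.DataFrame:
        """One row per analyte x term: estimate and estimability."""
        recs = []
        for f in self.fits.values():
            for term, b in f.beta.items():
                recs.append((f.analyte, term, b, bool(f.estimable[term]),
                             f.sigma, f.df))
        return pd.DataFrame(recs, columns=["analyte", "term", "estimate",
                                           "estimable", "sigma", "df"])

    def contrasts(self, specs, moderated: bool = False):
        """Estimate the given contrasts for every analyte.

        ``specs`` is a list of contrast specification strings (e.g.
        ``"e - d"``) or :class:`~lfqdea.contrasts.ContrastSpec`. With
        ``moderated=True`` empirical-Bayes variance shrinkage is applied.
        """
        from . import contrasts as _c
        res = _c.linear_model_contrasts(self, specs)
        if moderated:
            res = _c.moderate(res)
        return res

    def summary(self) -> str:
        sf = self.sigma_frame()
        n_full = sum(f.fully_estimable for f in self.fits.values())
        lines = [
            "Per-analyte linear model results",
            "================================",
            f"formula:            {self.model.formula}",
            f"terms:              {', '.join(self.design.terms)}",
            f"analytes fitted:    {len(self.fits)}",
            f"fully estimable:    {n_full}",
            f"samples:            {len(self.design.matrix)}",
            f"median residual sd: {np.nanmedian(np.sqrt(sf['sigma2'])):.4f}",
            f"median residual df: {np.nanmedian(sf['df']):.1f}",
        ]
        return "\n".join(lines)
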