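"""Group-difference estimation under four inferential strategies.

Given per-analyte linear-model fits, a contrast is a weight vector ``c``
over model coefficients such that ``c' beta`` equals a requested
difference of group means.  Four strategies are provided:

* **plain** — ``diff = c' beta``, ``se = sigma * sqrt(c' (X'X)^-1 c)``,
  t-distributed with the model's residual df;
* **moderated** — empirical-Bayes variance shrinkage: the per-analyte
  residual variances are modelled as draws from a scaled inverse
  chi-square prior whose parameters (d0, s0^2) are estimated from all
  analytes by moment matching on the log scale; the posterior variance
  ``(d0*s0^2 + df*s^2) / (d0 + df)`` replaces ``s^2`` and the t-statistic
  gains ``d0`` degrees of freedom;
* **missing** — difference of group means with the mean of a completely
  unobserved group substituted by the expected abundance at the limit of
  detection (A_LOD), pooled-variance standard error, and a cross-protein
  median pooled variance as last-resort fallback — no imputation of
  individual values;
* **ropeca** — protein-level rollup of peptide-level results: the median
  signed-rescaled peptide p-value is mapped through the Beta distribution
  of the median order statistic to a protein-level regulation probability.

``merge_contrasts`` combines two strategies, preferring the first where
both produced an estimate, and ``adjust_fdr`` applies Benjamini-Hochberg
within each contrast.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .data import QuantTable
from .model import Design, ModelFit, ProteinLMResults

__all__ = [
    "ContrastError",
    "ContrastSpec",
    "ContrastResults",
    "ModerationParams",
    "parse_linear_expression",
    "parse_contrast",
    "contrast_plain",
    "linear_model_contrasts",
    "estimate_variance_prior",
    "moderate",
    "contrasts_missing",
    "ropeca",
    "merge_contrasts",
    "adjust_fdr",
]

#: canonical output columns, in the order they are written to TSV
RESULT_COLUMNS = ["protein", "contrast", "diff", "se", "df", "statistic",
                  "p_value", "FDR", "method", "n_per_group", "lod_substituted"]

#: upper bound beyond which the prior df is treated as infinite
D0_CAP = 1e6


class ContrastError(ValueError):
    """A contrast specification cannot be resolved against the design."""


# --------------------------------------------------------------------------
# contrast specification parsing
# --------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(?P<num>\d+(?:\.\d+)?)"
                    r"|(?P<id>[A-Za-z_][A-Za-z0-9_.:\-]*)"
                    r"|(?P<op>[+\-*()]))")


def _tokenize(expr: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ContrastError(f"cannot parse contrast near {expr[pos:]!r}")
        if m.group("num"):
            tokens.append(("num", m.group("num")))
        elif m.group("id"):
            tokens.append(("id", m.group("id")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for linear expressions over group levels."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def parse(self):
        const, weights = self.expr()
        if self.i != len(self.tokens):
            raise ContrastError(f"unexpected token {self.peek()[1]!r}")
        return const, weights

    def expr(self):
        const, weights = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            _, op = self.next()
            c2, w2 = self.term()
            sign = 1.0 if op == "+" else -1.0
            const += sign * c2
            for k, v in w2.items():
                weights[k] = weights.get(k, 0.0) + sign * v
        return const, weights

    def term(self):
        const, weights = self.atom()
        while self.peek() == ("op", "*"):
            self.next()
            c2, w2 = self.atom()
            if weights and w2:
                raise ContrastError("products of group levels are not a "
                                    "linear contrast")
            if w2:
                weights = {k: const * v for k, v in w2.items()}
                const = 0.0
            else:
                weights = {k: c2 * v for k, v in weights.items()}
                const = const * c2
        return const, weights

    def atom(self):
        kind, val = self.next()
        if kind == "num":
            return float(val), {}
        if kind == "id":
            return 0.0, {val: 1.0}
        if (kind, val) == ("op", "("):
            const, weights = self.expr()
            if self.next() != ("op", ")"):
                raise ContrastError("unbalanced parentheses")
            return const, weights
        if (kind, val) == ("op", "-"):
            const, weights = self.atom()
            return -const, {k: -v for k, v in weights.items()}
        raise ContrastError(f"unexpected token {val!r}")


def parse_linear_expression(expr: str) -> dict[str, float]:
    """Parse e.g. ``"e - d"`` into weights over group-cell names."""
    const, weights = _Parser(_tokenize(expr)).parse()
    if abs(const) > 1e-12:
        raise ContrastError(f"contrast {expr!r} has a non-zero constant term")
    return {k: v for k, v in weights.items() if v != 0.0} or dict.fromkeys(
        (w for w in weights), 0.0) or {}


@dataclass
class ContrastSpec:
    """A named contrast resolved against a design.

    ``cell_weights`` are the weights over group cells and ``c`` is the
    induced weight vector over model coefficients, so that ``c' beta``
    equals the weighted combination of cell means under treatment coding.
    """

    name: str
    expression: str
    cell_weights: dict[str, float]
    c: pd.Series

    @property
    def is_difference(self) -> bool:
        return abs(sum(self.cell_weights.values())) < 1e-9


def parse_contrast(expr: str, design: Design, name: str | None = None) -> ContrastSpec:
    """Resolve a contrast specification string against a design.

    Identifiers refer to group cells (for one factor: the level names; for
    two factors: ``level1:level2``).
    """
    weights = parse_linear_expression(expr)
    unknown = sorted(set(weights) - set(design.cells))
    if unknown:
        raise ContrastError(f"unknown group level(s) {unknown}; available "
                            f"cells: {design.cells}")
    c = pd.Series(0.0, index=design.terms)
    for cell, w in weights.items():
        c = c + w * design.cell_rows.loc[cell]
    return ContrastSpec(name=name or expr, expression=expr,
                        cell_weights=weights, c=c)


def _resolve_specs(specs, design: Design) -> list[ContrastSpec]:
    out = []
    for s in specs:
        out.append(s if isinstance(s, ContrastSpec) else parse_contrast(s, design))
    return out


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------

class ContrastResults:
    """A table of per-(protein, contrast) difference estimates.

    Wraps a DataFrame with the canonical columns plus internal columns
    (residual sd ``sigma``, unscaled contrast sd ``sd_unscaled``) needed
    for moderation. ``to_tsv`` writes the canonical columns only.
    """

    def __init__(self, frame: pd.DataFrame,
                 moderation: "ModerationParams | None" = None):
        for col in RESULT_COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan if col not in ("method", "n_per_group") else ""
        self.frame = frame.reset_index(drop=True)
        self.moderation = moderation

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        methods = sorted(self.frame["method"].unique())
        return (f"ContrastResults({len(self.frame)} rows, "
                f"{self.frame['protein'].nunique()} proteins, "
                f"contrasts={sorted(self.frame['contrast'].unique())}, "
                f"methods={methods})")

    @property
    def contrast_names(self) -> list[str]:
        return sorted(self.frame["contrast"].unique())

    def adjust_fdr(self) -> "ContrastResults":
        return adjust_fdr(self)

    def merge(self, fallback: "ContrastResults") -> "ContrastResults":
        return merge_contrasts(self, fallback)

    def to_tsv(self, path) -> None:
        self.frame[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ContrastResults":
        return cls(pd.read_csv(path, sep="\t"))

    def summary(self, fdr: float = 0.05) -> str:
        f = self.frame
        lines = ["Contrast results", "================"]
        for name, sub in f.groupby("contrast"):
            n_sig = int((sub["FDR"] <= fdr).sum()) if sub["FDR"].notna().any() else 0
            lines.append(
                f"{name}: {len(sub)} proteins, median diff "
                f"{np.nanmedian(sub['diff']):+.3f}, {n_sig} at FDR<={fdr:g}")
        if self.moderation is not None:
            m = self.moderation
            d0 = "inf" if np.isinf(m.d0) else f"{m.d0:.2f}"
            lines.append(f"moderation prior: d0={d0}, s0^2={m.s02:.4g}")
        return "\n".join(lines)


def _p_two_sided(t: float, df: float) -> float:
    if not np.isfinite(t):
        return 0.0
    if np.isinf(df):
        return float(2.0 * sps.norm.sf(abs(t)))
    return float(2.0 * sps.t.sf(abs(t), df))


def _fmt_groups(cells: list[str], ns: dict) -> str:
    return ",".join(f"{c}:{int(ns.get(c, 0))}" for c in cells)


# --------------------------------------------------------------------------
# plain linear-model contrasts
# --------------------------------------------------------------------------

def contrast_plain(fit: ModelFit, spec: ContrastSpec) -> dict | None:
    """Contrast estimate from one OLS fit; None when inestimable.

    Returns a result-row dict (diff, se, df, statistic, p_value, ...), or
    ``None`` when a weighted coefficient is inestimable or the residual
    variance is undefined (df < 1) — the caller may fall back to the
    missing-data strategy.
    """
    ck = spec.c.reindex(fit.beta.index).fillna(0.0).to_numpy()
    if not fit.is_estimable(ck):
        return None
    if fit.df < 1 or not np.isfinite(fit.sigma):
        return None
    diff = float(ck @ fit.beta.to_numpy())
    cvc = float(ck @ fit.cov_unscaled.to_numpy() @ ck)
    sd_unscaled = float(np.sqrt(max(cvc, 0.0)))
    se = fit.sigma * sd_unscaled
    if se > 0:
        t = diff / se
        p = _p_two_sided(t, fit.df)
    elif diff == 0.0:
        t, p = 0.0, 1.0
    else:
        t = float(np.sign(diff) * np.inf)
        p = 0.0
    cells = sorted(spec.cell_weights)
    return {"contrast": spec.name, "diff": diff, "se": se, "df": float(fit.df),
            "statistic": t, "p_value": p, "method": "plain",
            "n_per_group": _fmt_groups(cells, fit.group_n.to_dict()),
            "lod_substituted": False, "sigma": fit.sigma,
            "sd_unscaled": sd_unscaled}


def linear_model_contrasts(results: ProteinLMResults, specs) -> ContrastResults:
    """Plain contrasts for every analyte in a fitted model set."""
    design = results.design
    specs = _resolve_specs(specs, design)
    peptide_level = results.table.is_peptide_level
    rows = []
    for analyte, fit in results.fits.items():
        for spec in specs:
            row = contrast_plain(fit, spec)
            if row is None:
                continue
            if peptide_level:
                row["protein"], row["peptide"] = analyte
            else:
                row["protein"] = analyte
            rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=RESULT_COLUMNS)
    return ContrastResults(frame)


# --------------------------------------------------------------------------
# empirical-Bayes moderation
# --------------------------------------------------------------------------

@dataclass
class ModerationParams:
    """Scaled inverse chi-square prior for residual variances.

    ``d0`` is the prior degrees of freedom (may be infinite) and ``s02``
    the prior variance; the posterior for an analyte with sample variance
    ``s2`` on ``df`` degrees of freedom is
    ``(d0*s02 + df*s2) / (d0 + df)``.
    """

    d0: float
    s02: float

    def posterior(self, s2, df):
        s2 = np.asarray(s2, dtype=float)
        df = np.asarray(df, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s02)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s02 + df * s2) / (self.d0 + df)


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Fit the scaled inverse chi-square prior to observed variances.

    Moment matching on the log scale: given ``s2 ~ s02 * F(df, d0)``, the
    variance of ``log(s2)`` in excess of the trigamma term implied by the
    residual df identifies ``d0``, and the mean identifies ``s02``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least 2 positive variances to fit a prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if d0 > D0_CAP:
            d0 = float("inf")
    else:
        d0 = float("inf")
    if np.isinf(d0):
        s02 = float(np.exp(emean))
    else:
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s02=s02)


def moderate(results: ContrastResults, min_analytes: int = 10) -> ContrastResults:
    """Empirical-Bayes variance moderation of contrast results.

    The prior is estimated from the distinct per-analyte (variance, df)
    pairs; each row's standard error is rescaled by the posterior standard
    deviation and the t-statistic gains the prior degrees of freedom.
    With fewer than ``min_analytes`` usable variances the input is
    returned unchanged with a warning.
    """
    frame = results.frame.copy()
    if "sigma" not in frame.columns or frame["sigma"].isna().all():
        raise ContrastError("results carry no residual variances; moderation "
                            "applies to plain or missing-data contrasts")
    id_cols = ["protein", "peptide"] if "peptide" in frame.columns and \
        frame.get("peptide") is not None and frame["peptide"].notna().any() else ["protein"]
    per = frame.drop_duplicates(id_cols)[["sigma", "df", *id_cols]]
    s2 = per["sigma"].to_numpy() ** 2
    dfv = per["df"].to_numpy(dtype=float)
    usable = np.isfinite(s2) & (s2 > 0) & (dfv > 0)
    if usable.sum() < min_analytes:
        warnings.warn("too few analytes with a defined residual variance; "
                      "returning unmoderated results")
        return ContrastResults(frame, moderation=None)
    if np.allclose(s2[usable], s2[usable][0]):
        params = ModerationParams(d0=float("inf"), s02=float(s2[usable][0]))
    else:
        params = estimate_variance_prior(s2[usable], dfv[usable])

    sig2 = frame["sigma"].to_numpy(dtype=float) ** 2
    dfr = frame["df"].to_numpy(dtype=float)
    post = params.posterior(sig2, dfr)
    # analytes with undefined residual variance shrink fully to the prior
    undef = ~np.isfinite(sig2)
    post[undef] = params.s02
    sd_u = frame["sd_unscaled"].to_numpy(dtype=float)
    se_mod = np.sqrt(post) * sd_u
    diff = frame["diff"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_mod > 0, diff / se_mod,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    df_mod = dfr + params.d0
    p = np.array([_p_two_sided(ti, dfi) if np.isfinite(ti) or True else np.nan
                  for ti, dfi in zip(t, df_mod)])
    p[(se_mod == 0) & (diff == 0)] = 1.0
    frame["se"] = se_mod
    frame["df"] = df_mod
    frame["statistic"] = t
    frame["p_value"] = p
    frame["sigma"] = np.sqrt(post)
    frame["method"] = frame["method"].astype(str) + "_moderated"
    frame["method"] = frame["method"].replace({"plain_moderated": "moderated"})
    return ContrastResults(frame, moderation=params)


# --------------------------------------------------------------------------
# missing-data (LOD) contrasts
# --------------------------------------------------------------------------

def contrasts_missing(table: QuantTable, specs, design: Design | None = None,
                      lod: "float | None" = None) -> ContrastResults:
    """Group-mean contrasts tolerant of completely unobserved groups.

    For each protein and contrast, group means are taken from the data; a
    group without any observation gets the expected abundance at the limit
    of detection, A_LOD, as its mean, and any observed mean below A_LOD is
    raised to A_LOD (an estimate below the detection floor carries no
    directional information).  The standard error uses the protein's
    pooled variance over groups with data, falling back to the median
    pooled variance of all other proteins, with a substituted group
    counted as a single pseudo-observation.

    Parameters
    ----------
    table
        Protein-level log2 QuantTable.
    specs
        Contrast specification strings or ContrastSpec objects.
    design
        Optional design (defaults to the product of configured factors).
    lod
        A_LOD override; estimated from the table's singleton cells via
        :func:`lfqdea.model.estimate_lod` when omitted.
    """
    from .model import build_design, estimate_lod as _est_lod

    cfg = table.config
    table = table.complete_cases()
    if design is None:
        design = build_design(table.annotation, cfg)
    specs = _resolve_specs(specs, design)
    if lod is None:
        lod = _est_lod(table).a_lod
    a_lod = float(lod)

    cell = design.cell_of
    df = table.data.copy()
    df["_cell"] = df[cfg.sample_col].map(cell)
    g = df.groupby([cfg.protein_col, "_cell"])[cfg.response_col]
    stats = pd.DataFrame({"n": g.size(), "mean": g.mean(), "sd": g.std(ddof=1)})

    # per-protein pooled variance, and its cross-protein median fallback
    pooled: dict[str, float] = {}
    by_protein: dict[str, pd.DataFrame] = {}
    for prot, sub in stats.groupby(level=0):
        sub = sub.droplevel(0)
        by_protein[prot] = sub
        use = sub[sub["n"] >= 2]
        if len(use):
            w = (use["n"] - 1).to_numpy(dtype=float)
            pooled[prot] = float((w * use["sd"].to_numpy() ** 2).sum() / w.sum())
    median_pooled = float(np.median(list(pooled.values()))) if pooled else float("nan")

    rows = []
    for prot, sub in by_protein.items():
        full = sub.reindex(design.cells)
        n = full["n"].fillna(0).astype(int)
        means = full["mean"]
        for spec in specs:
            cells = sorted(spec.cell_weights)
            n_ref = n[cells]
            if (n_ref == 0).all():
                continue
            substituted = False
            mvals, nvals = {}, {}
            for cname in cells:
                if n_ref[cname] == 0:
                    mvals[cname] = a_lod
                    nvals[cname] = 1
                    substituted = True
                else:
                    m = float(means[cname])
                    if m < a_lod:
                        m = a_lod
                        substituted = True
                    mvals[cname] = m
                    nvals[cname] = int(n_ref[cname])
            diff = float(sum(w * mvals[cname]
                             for cname, w in spec.cell_weights.items()))
            s2 = pooled.get(prot, median_pooled)
            if not np.isfinite(s2):
                continue
            sd_unscaled = float(np.sqrt(sum(w * w / nvals[cname]
                                            for cname, w in spec.cell_weights.items())))
            se = float(np.sqrt(s2)) * sd_unscaled
            observed = [cname for cname in cells if n_ref[cname] > 0]
            df_c = max(int(n_ref[observed].sum()) - len(observed), 1)
            if se > 0:
                t = diff / se
                p = _p_two_sided(t, df_c)
            elif diff == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(diff) * np.inf), 0.0
            rows.append({"protein": prot, "contrast": spec.name, "diff": diff,
                         "se": se, "df": float(df_c), "statistic": t,
                         "p_value": p, "method": "missing",
                         "n_per_group": _fmt_groups(cells, n_ref.to_dict()),
                         "lod_substituted": substituted,
                         "sigma": float(np.sqrt(s2)),
                         "sd_unscaled": sd_unscaled})
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=RESULT_COLUMNS)
    return ContrastResults(frame)


# --------------------------------------------------------------------------
# peptide-level rollup (ROPECA)
# --------------------------------------------------------------------------

def ropeca(peptide_results: ContrastResults) -> ContrastResults:
    """Roll peptide-level contrasts up to protein-level probabilities.

    Each peptide p-value is rescaled to one-sided form using the sign of
    its fold-change (p/2 for positive, 1 - p/2 otherwise); the median
    rescaled value over the protein's d peptides (upper median for even d)
    is mapped through the Beta CDF of the i-th order statistic of d
    uniforms, i = ceil((d+1)/2), and symmetrised back to a two-sided
    value.  The protein difference is the median peptide difference, the
    reported statistic the median peptide t, and the ``df`` column carries
    the number of peptides d.

    The resulting values are regulation probabilities, not calibrated
    p-values: under the null they are non-uniform for d >= 3, so BH-style
    FDR estimates computed from them are biased (conservative FDP control
    should not be assumed).
    """
    frame = peptide_results.frame
    if "peptide" not in frame.columns:
        raise ContrastError("ropeca needs peptide-level contrast results")
    rows = []
    for (prot, cname), sub in frame.groupby(["protein", "contrast"]):
        ok = sub[np.isfinite(sub["p_value"].astype(float))
                 & np.isfinite(sub["diff"].astype(float))]
        d = len(ok)
        if d == 0:
            continue
        p = ok["p_value"].to_numpy(dtype=float)
        b = ok["diff"].to_numpy(dtype=float)
        p_tilde = np.where(b > 0, p / 2.0, 1.0 - p / 2.0)
        i = int(np.ceil((d + 1) / 2.0))
        p_med = float(np.sort(p_tilde)[i - 1])
        q = float(sps.beta.cdf(p_med, i, d - i + 1))
        p_prot = float(2.0 * min(q, 1.0 - q))
        rows.append({"protein": prot, "contrast": cname,
                     "diff": float(np.median(b)), "se": np.nan, "df": float(d),
                     "statistic": float(np.median(ok["statistic"].to_numpy(dtype=float))),
                     "p_value": p_prot, "method": "ropeca",
                     "n_per_group": "", "lod_substituted": False})
    frame_out = pd.DataFrame(rows)
    if frame_out.empty:
        frame_out = pd.DataFrame(columns=RESULT_COLUMNS)
    return ContrastResults(frame_out)


# --------------------------------------------------------------------------
# merging and FDR
# --------------------------------------------------------------------------

def merge_contrasts(preferred: ContrastResults,
                    fallback: ContrastResults) -> ContrastResults:
    """Union of two result sets keyed by (protein, contrast).

    Where both strategies produced an estimate the preferred one wins; the
    per-row ``method`` tag records which strategy each estimate came from.
    """
    merged = pd.concat([preferred.frame, fallback.frame], ignore_index=True)
    merged = merged.drop_duplicates(subset=["protein", "contrast"], keep="first")
    return ContrastResults(merged.reset_index(drop=True),
                           moderation=preferred.moderation)


def adjust_fdr(results: ContrastResults) -> ContrastResults:
    """Benjamini-Hochberg step-up, applied within each contrast separately."""
    frame = results.frame.copy()
    fdr = np.full(len(frame), np.nan)
    for cname, sub in frame.groupby("contrast"):
        p = sub["p_value"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if ok.any():
            _, q, _, _ = multipletests(p[ok], method="fdr_bh")
            idx = sub.index.to_numpy()[ok]
            fdr[frame.index.get_indexer(idx)] = q
    frame["FDR"] = fdr
    return ContrastResults(frame, moderation=results.moderation)
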