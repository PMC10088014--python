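"""Scoring contrast results against a known ground truth.

For a spike-in benchmark, every protein carries a class label ("changed"
for the spiked species, "unchanged" for the background) and an expected
log2 difference per contrast.  Three ranking statistics are assessed: the
estimated difference (|log2 fold-change|), the t-statistic (|t|) and the
p-value (ranked by 1 - p).  Sweeping a threshold over a ranking statistic
gives, per threshold, a confusion matrix and from it TPR = TP/P,
FPR = FP/N and the false discovery proportion FDP = FP/max(R, 1); the ROC
curve and its standardized partial area at a configurable FPR limit
summarize the sweep, and the FDR-vs-FDP curve checks whether the model's
FDR estimates are honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "BenchmarkError",
    "ConfusionCounts",
    "BenchmarkCurves",
    "ranking_statistics",
    "confusion_at",
    "roc_points",
    "partial_auc",
    "benchmark_contrasts",
    "fdr_calibration",
    "plot_roc",
]

#: ranking statistics: result column -> transform to "larger = more evidence"
STATISTICS = {
    "diff": lambda f: f["diff"].abs(),
    "statistic": lambda f: f["statistic"].abs(),
    "scaled_p": lambda f: 1.0 - f["p_value"],
}


class BenchmarkError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """Confusion matrix at one threshold of a ranking statistic."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def P(self) -> int:            # all truly changed proteins
        return self.tp + self.fn

    @property
    def N(self) -> int:            # all truly unchanged proteins
        return self.fp + self.tn

    @property
    def R(self) -> int:            # number called changed
        return self.tp + self.fp

    @property
    def m(self) -> int:
        return self.P + self.N

    @property
    def tpr(self) -> float:
        return self.tp / self.P if self.P else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / self.N if self.N else float("nan")

    @property
    def fdp(self) -> float:
        return self.fp / max(self.R, 1)


@dataclass
class BenchmarkCurves:
    """ROC/pAUC/FDP summaries per ranking statistic."""

    curves: dict          # statistic -> DataFrame(threshold, fpr, tpr, fdp)
    pauc: dict            # statistic -> standardized pAUC at fpr_limit
    fpr_limit: float
    n_scored: int
    n_not_estimated: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [(s, self.fpr_limit, v, self.n_scored, self.n_not_estimated)
                for s, v in self.pauc.items()]
        return pd.DataFrame(rows, columns=["statistic", "fpr_limit", "pauc",
                                           "n_scored", "n_not_estimated"])


def _join_truth(frame: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    labels = truth.drop_duplicates("protein")[["protein", "label"]]
    joined = frame.merge(labels, on="protein", how="left")
    unlabeled = sorted(joined.loc[joined["label"].isna(), "protein"].unique())
    if unlabeled:
        raise BenchmarkError(f"proteins without a truth label: {unlabeled[:10]}"
                             + ("..." if len(unlabeled) > 10 else ""))
    return joined


def ranking_statistics(results) -> pd.DataFrame:
    """Per-(protein, contrast) values of the three ranking statistics.

    Emits the raw diff, t-statistic and signed p-value
    (``sign(diff) * p``) together with the rank values actually swept:
    |diff|, |t| and 1 - p.
    """
    frame = results.frame if hasattr(results, "frame") else results
    ok = frame[np.isfinite(frame["diff"].astype(float))
               & np.isfinite(frame["p_value"].astype(float))].copy()
    out = ok[["protein", "contrast"]].copy()
    out["diff"] = ok["diff"].astype(float)
    out["statistic"] = ok["statistic"].astype(float)
    out["scaled_p"] = np.sign(out["diff"]) * ok["p_value"].astype(float)
    out["rank_diff"] = out["diff"].abs()
    out["rank_statistic"] = out["statistic"].abs()
    out["rank_scaled_p"] = 1.0 - ok["p_value"].astype(float)
    return out


def confusion_at(scores: pd.Series, changed: pd.Series,
                 threshold: float) -> ConfusionCounts:
    """Confusion counts calling "changed" where score >= threshold.

    Tied scores enter or leave the called set together, so curves are
    deterministic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(changed, dtype=bool)
    called = s >= threshold
    return ConfusionCounts(tp=int((called & y).sum()),
                           fp=int((called & ~y).sum()),
                           fn=int((~called & y).sum()),
                           tn=int((~called & ~y).sum()))


def roc_points(scores, changed) -> pd.DataFrame:
    """ROC sweep over all distinct thresholds (plus FDP per threshold)."""
    y = np.asarray(changed, dtype=bool)
    if y.all() or not y.any():
        raise BenchmarkError("both classes must be present to compute a ROC")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    P = int(y.sum())
    N = int((~y).sum())
    tp = tpr * P
    fp = fpr * N
    fdp = fp / np.maximum(tp + fp, 1.0)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr, "fdp": fdp})


def partial_auc(fpr: np.ndarray, tpr: np.ndarray, fpr_limit: float = 0.1) -> float:
    """Trapezoidal area over FPR in [0, fpr_limit], standardized to [0, 1]."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    if fpr_limit <= 0 or fpr_limit > 1:
        raise BenchmarkError("fpr_limit must be in (0, 1]")
    grid = np.unique(np.concatenate([fpr[fpr <= fpr_limit], [fpr_limit]]))
    t = np.interp(grid, fpr, tpr)
    return float(np.trapezoid(t, grid) / fpr_limit)


def benchmark_contrasts(results, truth: pd.DataFrame, fpr_limit: float = 0.1,
                        statistics=("diff", "statistic", "scaled_p"),
                        n_expected: int | None = None) -> BenchmarkCurves:
    """ROC curves and standardized pAUC for each ranking statistic.

    All contrasts are pooled into one curve (pass a single-contrast
    results table for per-contrast curves). ``n_expected`` — the number of
    (protein, contrast) pairs a method could in principle have estimated —
    feeds the "not estimated" tally, because a method that silently skips
    hard proteins gets an unfair ROC advantage.
    """
    ranks = ranking_statistics(results)
    joined = _join_truth(ranks, truth)
    changed = joined["label"] == "changed"
    curves, paucs = {}, {}
    for s in statistics:
        pts = roc_points(joined[f"rank_{s}"], changed)
        curves[s] = pts
        paucs[s] = partial_auc(pts["fpr"].to_numpy(), pts["tpr"].to_numpy(),
                               fpr_limit)
    n_scored = len(joined)
    n_not = (n_expected - n_scored) if n_expected is not None else 0
    return BenchmarkCurves(curves=curves, pauc=paucs, fpr_limit=fpr_limit,
                           n_scored=n_scored, n_not_estimated=int(n_not))


def fdr_calibration(results, truth: pd.DataFrame,
                    grid=(0.01, 0.025, 0.05, 0.1, 0.2)) -> pd.DataFrame:
    """Realized FDP when calling everything with FDR <= q, per grid level q."""
    frame = results.frame if hasattr(results, "frame") else results
    if "FDR" not in frame.columns or frame["FDR"].isna().all():
        raise BenchmarkError("results carry no FDR column; run adjust_fdr first")
    joined = _join_truth(frame[np.isfinite(frame["FDR"].astype(float))], truth)
    changed = (joined["label"] == "changed").to_numpy()
    fdr = joined["FDR"].to_numpy(dtype=float)
    rows = []
    for q in grid:
        called = fdr <= q
        r = int(called.sum())
        fp = int((called & ~changed).sum())
        rows.append((float(q), fp / max(r, 1), r, fp))
    return pd.DataFrame(rows, columns=["fdr_level", "fdp", "n_called", "n_false"])


def plot_roc(curves: BenchmarkCurves, path) -> None:
    """Minimal diagnostic ROC plot (one line per ranking statistic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for s, pts in curves.curves.items():
        ax.plot(pts["fpr"], pts["tpr"],
                label=f"{s} (pAUC{int(curves.fpr_limit * 100)}="
                      f"{curves.pauc[s]:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="gray")
    ax.axvline(curves.fpr_limit, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
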