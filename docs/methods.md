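# Methods

This note documents the statistical procedures implemented in `lfqdea`,
their assumptions and defaults, what the synthetic spike-in generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Data model and preprocessing

All operations run on a tidy long table (one row per observed abundance)
with an `AnalysisConfig` mapping columns to roles. Missing observations
are encoded by record *absence*: zero intensities — which quantification
software reports when a feature was not found — are removed at read
time, before the log2 transform, and no value is ever imputed at the
observation level. Group levels are ordered lexicographically unless an
explicit `level_order` is configured; the first level is the reference
for model coding. Sample identifiers are opaque strings.

**Robust scaling.** Between-sample systematic shifts are removed with a
robust z-score: per sample, location `x̃` = median of the sample's log2
abundances and scale `S̃` = median absolute deviation of the same,
multiplied by 1.4826 so that `S̃` estimates a standard deviation under
normality. Since group differences must stay on the log2 scale, the
z-score is multiplied by the mean scale `S̄` over samples; we also add
back the mean location `M̄`:

    scaled = (x − x̃_s) / S̃_s · S̄ + M̄ .

Re-adding `M̄` is a design choice: it keeps the output interpretable as
absolute log2 intensities (which the detection-limit estimate `A_LOD`
needs), while group differences are unaffected by a constant shared by
all samples. When a reference subset of constant-concentration proteins
is supplied (in a spike-in design: the background species), `x̃` and `S̃`
are estimated from that subset only and the transform is applied to all
records — this is essential when the changing proteins form a large
fraction of the signal, since otherwise the scaling itself absorbs part
of the spike and biases background proteins away from zero. Scaling
requires `S̃ > 0` in every sample and, with a reference set, at least two
reference observations per sample.

**Filtering.** Proteins identified by a single peptide ("one-hit
wonders") are removed before rollup (default `min_peptides = 2`);
single-peptide quantification is dominated by one ionization path and
has no internal consistency check.

## Peptide-to-protein rollup

The default estimator is Tukey's median polish of each protein's
peptide × sample log2 matrix: row (peptide) and column (sample) medians
are swept alternately from the residual matrix, ignoring missing cells,
until the sum of absolute residuals improves by at most `tol` (relative;
default 0.01) or `max_iter` (default 10) sweeps have run — the classic
convention, and bit-identical to R's `stats::medpolish` on complete
matrices (verified in the test suite). The protein profile is
`overall + column effect`, i.e. peptide effects are discarded; samples
with no observed peptide get no protein record. Median polish is robust
to outlying single peptide measurements; exact additive matrices are a
fixed point. Note the stopping rule is about the residual *sum*, not the
medians themselves: residual row/column medians are typically well below
10·tol after convergence but can occasionally exceed it when the rule
stops an iteration early; running the full 10 sweeps drives them below
0.05 on random Gaussian matrices.

Top-N (mean of the N peptides with the highest average abundance, ties
broken by peptide identifier for determinism) is provided as a simpler
alternative.

## Per-protein linear models and contrasts

For each protein, ordinary least squares is fitted to the available
observations of `y = Xβ + ε` with a treatment-coded design over the
annotated grouping factors (formula syntax `"group"`, `"f1 * f2"`,
`"f1 + f2 + f1:f2"`; two-way interactions). Unbalanced designs are
fitted as-is. When whole groups are unobserved the design loses rank;
fits then use the pseudoinverse (minimum-norm `β̂`, generalized-inverse
`(XᵀX)⁺`), and a contrast `c` is declared estimable exactly when `c`
lies in the row space of the observed design (tested via the projection
`X⁺X`). For estimable contrasts `cᵀβ̂` and `cᵀ(XᵀX)⁺c` are invariant to
the generalized inverse, so this loses nothing and never silently
reports a confounded estimate.

Contrast specifications are strings over group cells ("`e - d`",
"`0.5*(d + e) - a`", "`(b:y - b:x) - (a:y - a:x)`" for interactions),
compiled to cell-mean weights and then to coefficient weights, so that a
difference contrast always estimates the difference of group means
regardless of coding.

**Plain.** `diff = cᵀβ̂`, `se = σ̂·sqrt(cᵀ(XᵀX)⁻¹c)`, `t = diff/se`,
two-sided p from the t-distribution with the model's residual df. On a
balanced two-group design this is exactly the pooled two-sample t-test.

**Moderated (empirical Bayes).** The per-protein residual variances
`s²` are modelled as draws from a scaled inverse chi-square prior with
parameters `(d₀, s₀²)`, estimated across proteins by moment matching on
`log s²` against the log-F distribution (digamma/trigamma moments, with
a Newton iteration for the trigamma inverse). The posterior variance

    σ̃² = (d₀·s₀² + df·s²) / (d₀ + df)

replaces `s²` in the t-statistic, and p-values use `df + d₀` degrees of
freedom. `d₀` above 10⁶ is treated as infinite (normal limit; posterior
equals `s₀²`). If all variances are equal the prior is degenerate
(`d₀ = ∞`). Moderation preserves the sign of every statistic; with fewer
than 10 usable variances the input is passed through with a warning.

**Missing-data / detection limit.** If a protein has no observation in
an entire group, a plausible explanation is an abundance below the
limit of detection (LOD), so the group's mean is substituted by the
expected abundance at the LOD, `A_LOD`, estimated as the median
abundance over all (protein, group) cells with exactly one observation
(such cells sit at the detection floor; if none exist the caller must
supply `A_LOD`). An observed mean below `A_LOD` is also raised to
`A_LOD`, so a difference never changes sign below the detection floor.
The variance is the df-weighted pooled variance over the protein's
groups with ≥ 2 observations, falling back to the median pooled
variance across all other proteins; the standard error is
`s_p·sqrt(Σ w²/n)` with a substituted group counted as a single
pseudo-observation (`n = 1` — the least confident choice for an
unobserved mean), and `df = n − n_g` over the groups with observed
data, floored at 1. With both groups observed this reduces to the
classical pooled test on the group means.

**Peptide rollup (regulation probabilities).** Peptide-level contrasts
can be summarized per protein: each peptide p-value is rescaled
one-sided by the sign of its fold-change (`p/2` if positive, `1 − p/2`
otherwise), the median over the protein's `d` peptides is taken (upper
median, `i = ⌈(d+1)/2⌉`, for even `d` — Beta parameters must be
integers), and mapped through the Beta CDF of the i-th order statistic
of `d` uniforms, `q = BetaCDF(p̃_med; i, d−i+1)`, then symmetrised to
`2·min(q, 1−q)`. The protein difference is the median peptide
difference and the reported statistic the median peptide t. **These
values are regulation probabilities, not calibrated p-values**: with
correlated peptides their null distribution piles near the extremes, so
BH-adjusted values computed from them understate the true false
discovery proportion. They are provided for ranking, with that caveat.

**Merging and FDR.** Two strategy outputs merge by (protein, contrast)
with the preferred (linear-model) estimate winning and per-row method
tags recording provenance; the merged table covers every pair estimable
by at least one strategy. Benjamini–Hochberg is applied within each
contrast separately, over the rows with finite p.

## Benchmarking

Given per-protein class labels (changed/unchanged) and expected
differences, three ranking statistics are swept — |diff|, |t| and
`1 − p` — with tied values entering the called set together. Reported:
confusion counts (TP/FP/FN/TN with TPR = TP/P, FPR = FP/N,
FDP = FP/max(R,1)), ROC curves, and partial AUC over FPR ∈ [0, L]
standardized by dividing the trapezoidal area by L (default L = 0.1),
so a perfect ranking scores 1 and a class-independent ranking L/2 ÷ L
… i.e. the diagonal's 0.05 at L = 0.1. FDR-vs-FDP calibration calls
everything at FDR ≤ q over a grid of q and reports the realized FDP.
Proteins with no estimate for a contrast are excluded from the curve but
tallied, because a method that skips hard proteins would otherwise gain
an unfair ROC advantage.

## The spike-in simulator

The generator emulates a two-species spike-in dilution series: a
constant background proteome (default 1000 proteins) plus spike
proteins (default 200) whose concentration varies across groups with
known ratios. Defaults follow the five-group design at 3, 4.5, 6, 7.5
and 9% spike (groups `a`–`e`, smallest to largest) with 4 technical
replicates, i.e. 20 samples; adjacent contrasts have expected linear
ratios 1.5, 4/3, 1.25 and 1.2 — deliberately small effects, where
modelling choices actually matter.

Peptide-level log2 abundances are additive:

    base_q + offset_p + shift_s + spike_effect + ε,   ε ~ N(0, σ_q²)

with protein base `~ N(20, 2.5)` (log2 intensity units), peptide
ionization offset `~ N(0, 1.5)`, per-sample shift `~ N(0, 0.2)`,
peptides per protein `1 + Poisson(7)` (mean 8, min 1), spike effect
`log2(level_g / level_a)` shared by all peptides of a spike protein,
and per-protein residual variances drawn from a scaled inverse
chi-square with `d₀ = 4`, `s₀ = 0.15` — heterogeneous by construction so
that moderation's prior-recovery test is meaningful. Records are
censored with logistic probability `1/(1 + exp((value − LOD)/w))`
(LOD = 14, width w = 1), the MNAR mechanism observed in real LFQ data;
intensities are reported on the linear scale (`2^value`). Output is
deterministic given the seed.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: biological replicate variance (only technical
noise; real variances are larger and power lower at the same n),
correlated peptides within a protein beyond the shared spike effect (no
shared protein × sample noise, no interference or misassigned peptides),
retention-time alignment and match-between-runs artifacts, and
peptide-level MAR missingness from precursor selection. Two consequences
worth naming: (i) the peptide-rollup regulation probabilities are
*nearly* uniform under this generator's null — their variance deficit
relative to uniform (1/12) is marginal here, whereas real data's
correlated peptides produce the strong non-uniformity that makes their
FDR estimates unreliable; (ii) fold-change recovery error (MAE ≈ 0.05 at
defaults) is an optimistic floor.

## Problem sizes and numerical choices

The packaged checks use: 200 proteins for the t-test equivalence
(tolerance 1e-10), 500 random 8×20 matrices for median-polish
convergence, 5000 variances for prior recovery (d₀ within 20%, s₀²
within 10%), a 5000-protein two-group null for calibration
(KS < 0.02), and the default 1200-protein spike-in for the benchmark —
sizes at which the sampling noise of each summary is well below its
acceptance margin. Ties in top-N are broken by peptide identifier;
degenerate inputs (zero residual variance, zero-weight contrasts,
empty groups) yield defined results (`t = 0, p = 1` for a zero
contrast; `p ≈ 0` guarded against division by zero for zero variance)
rather than NaNs. The trigamma inverse uses the standard asymptotic
starting points (`1/√y` for large y, `1/y` for small) with Newton
updates to relative precision 1e-10.

## Known limitations

No mixed-effects models (correlated/repeated measurements should be
aggregated before fitting), no quantile or variance-stabilizing
normalization, no precursor-level (evidence/fragment) readers, at most
two-level analyte hierarchies (peptide → protein), and two-way
interactions at most. The missing-data strategy uses a point estimate
of the detection limit; a probabilistic dropout model would propagate
its uncertainty.
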