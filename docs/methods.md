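# Methods

## The cell-mixture model

All quantitative reasoning in this package starts from one observation
model. A bulk sample is a mixture of a fraction *f* of induced cells and
1 − *f* uninduced cells. If induction multiplies a region's signal
(expression, or a histone-mark density) by a factor *g* in induced cells,
the expected bulk DOX/noDOX ratio is

    h(f, g) = f·g + (1 − f).

For expression we write g = 2^β with β the per-gene log2 silencing
effect, so the bulk log ratio is log2 h(f, 2^β), which is concave in f
and satisfies |log2 h| ≤ |β| with equality at f = 1. Plain DOX-vs-noDOX
log fold changes therefore systematically understate silencing whenever
induction is incomplete, and do so differently in samples with different
induction efficiencies.

### The induction-corrected logFC

The induction model regresses per-feature log2-cpm on the per-sample
induction fraction, with one intercept and one slope per clone
(`Y ~ 0 + clones + clones:induction`); the reported effect is the
unweighted mean of the per-clone slopes. For a clone measured at a single
induction fraction f the slope equals log2 h(f, 2^β)/f — the logFC
linearly extrapolated to complete induction. It removes the
between-sample part of the attenuation (samples with different f become
comparable) but retains the concavity bias of a single-f design: the
slope magnitude is still bounded by |β|, reaching it only at f = 1. Both
properties are asserted by tests (exact recovery on data linear in f;
concavity on noiseless mixture data).

The condition model (`Y = clones + clones:condition`, effect = mean of
the per-clone DOX coefficients) provides the ordinary logFC used for
silencing bins.

### Fitting, weights, moderation

Per-feature weighted least squares on log2-cpm values
(log2((count + 0.5)/(lib·factor + 1)·10⁶)). Precision weights follow the
voom recipe in simplified form: an unweighted per-feature fit gives
residual SDs; a lowess trend (frac = 0.5) of sqrt(SD) against the mean
log2-count is interpolated at each observation's fitted value and
inverted to the fourth power, clipped to [1e−6, 1e6]. With fewer than 10
features, or a saturated design, unit weights are used (warned).

Variance moderation moment-matches a scaled inverse-chi-square prior on
the residual variances through log s²: the prior df d0 comes from
inverting the trigamma function on the excess variance of log s² over
trigamma(df/2) (Newton iteration), the prior scale from the corrected
mean. Non-positive excess yields d0 = ∞ (complete shrinkage to the
common value). Posterior variance (d0·s0² + df·s²)/(d0 + df) feeds a
moderated t with d0 + df degrees of freedom; p-values are BH-adjusted.
A null simulation (2000 features) checks type-I calibration at
p < 0.05 ∈ [0.04, 0.06].

With two clones × two conditions and no replicates both designs are
saturated (residual df = 0): effects are exact interpolants, and the
model returns them without significance statistics rather than failing.
Group-level inference in that regime is rank-based across regions
(Wilcoxon), as in the figures this mirrors.

## ChIP normalization

Between-sample scaling must not be driven by the chromosome that changes.
Factors are computed by trimmed mean of M-values (TMM) over anchoring
regions where no change is expected — autosomal consensus peaks for ChIP,
expressed autosomal genes for RNA — while the library sizes being
rescaled are the full column totals. The implementation follows the
standard recipe exactly: reference sample by 75th-percentile count
fraction closest to the mean; M and A over regions nonzero in both;
two-sided trims of 30 % (M) and 5 % (A); inverse-asymptotic-variance
weights ((N−y)/(N·y) summed over the pair); 2^(weighted trimmed mean),
rescaled to geometric mean 1. Tests pin it to an independently coded
step-by-step computation at 1e−9 on random instances. Because the
variance weights depend on absolute counts, the weighted factors are only
approximately invariant to rescaling a single column; `weighted=False`
(the unweighted trimmed mean, mirroring edgeR's `doWeighting`) is exactly
invariant.

Consensus peaks are the sub-regions covered by at least 2 of the
replicate noDOX peak sets (boundary partition + merge of bookended
pieces); a fold-change ≥ 3 pre-filter applies when per-peak fold changes
are supplied. Windows whose *input* counts fall outside mean ± 1.5
sample-SD in any input sample are discarded (accessibility/mappability
outliers; boundary values retained; the all-inputs rule is the strictest
reading and is configurable). Accumulation is normalized DOX − noDOX per
clone (counts scaled to 10⁷ per effective library), plus the clone
average.

## Promoter classification and integration

The accumulation threshold per mark is mean + sample SD of the
accumulation over *autosomal* promoters in the ΔB+C dataset — autosomes
bound the no-effect distribution; under Gaussian noise ~15.9 % of
autosomal promoters exceed it (calibration-checked). A chrX promoter is
in the `accumulation` category when at least one repressive mark strictly
exceeds its threshold (ties → `no_or_little`). Genes are binned by RNA
logFC into (−∞,−1.5], (−1.5,−1], (−1,−0.5], (−0.5,∞) (upper-bound
inclusive on the left three bins — a documented tie-break; only
measure-zero boundaries are affected). CpG density is the count of CG
dinucleotides divided by length − 1; N bases are excluded from the GC
denominator. Group comparisons use Mann–Whitney (unpaired) or Wilcoxon
signed-rank (paired, FL vs ΔB+C matched by gene), exact for n ≤ 25
without ties, else normal approximation with continuity correction.

## ChIRP-MS scoring

Fold enrichment = DOX/noDOX peptide counts with a zero noDOX count
treated as 1. Isoforms with UniProt annotation score < 3 are dropped;
detection requires fold enrichment ≥ 2.5 in at least one pull-down.
Classification against a reference interactor list: **lost** when the
ΔB+C pull-down has zero peptides (or exactly the control count) and the
FL enrichment is ≥ 4; otherwise **underrepresented** when the ΔB+C
enrichment is below FL; otherwise **retained**. Ranking ties break by
descending FL DOX count, then protein id.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* genome: 4 autosomes + chrX, 10 Mb each; 300 genes (25 % on chrX,
  exact), 70 % initially active, placed in per-chromosome slots
  (deterministic non-overlap); H3K27ac peaks at active TSSs so the
  activity flags are derived, not asserted;
* induction fractions: the study's RNA-FISH measurements — FL 46.64 % /
  59.44 %, ΔB+C 66.30 % / 56.29 %, ΔA 53.2 % / 54.5 % (clone 1/2);
* silencing: β_g ~ Normal(μ, 0.5) clipped at 0 for chrX genes, μ = −2.0
  (FL) and −1.7 (ΔB+C); ΔA is fixed at β ≡ 0 (a literal truncated-normal
  with μ = 0 would silence half-normally and contradict the ΔA
  phenotype);
* deposition gains γ in induced cells, chrX only: FL intergenic/
  promoter/gene-body 6/8/4 (H3K27me3) and 5/6/3 (H2AK119ub) — strong
  chromosome-wide recruitment; ΔB+C all 1 except promoters of high-CpG
  silenced genes (γ = 3, both marks), the passive-recruitment scenario
  the classifier must detect; ΔA all 1;
* counts: NB with variance μ + φμ², φ = 0.05 (a biological-duplicate
  scale dispersion), window baselines log-normal (sd 0.4) with
  class-specific scale, mean window count 100, mean gene count 500,
  clone library factors 1.0/1.35 plus 5 % log-normal jitter; 1.5 % of
  windows carry a 12× accessibility multiplier shared between marks and
  input (what the outlier filter must remove);
* promoter sequences: i.i.d. nucleotides at GC 0.6 (high-CpG class) vs
  0.4 (low), 50/50 — enough to separate CG density cleanly at 4 kb;
* ChIRP table: 200 proteins, Poisson counts with category means
  (noDOX, FL DOX, ΔB+C DOX) = retained (2, 20, 40), underrepresented
  (2, 30, 10), lost (0.5, 20, 0), background (5, 6, 6).

Randomness is drawn from per-operation streams derived from
(seed, stream id), so identical (config, seed) give identical outputs
and adding operations never perturbs earlier draws.

What the generator does **not** emulate: read-level artifacts (fragment
sizes, GC bias, mappability), correlated biological replicate structure
beyond the clone library factor, spatial autocorrelation of marks along
the chromosome, isoform structure (one transcript per gene), and
proteome-scale MS noise. Passing tests therefore demonstrate that the
estimators recover the mixture model's parameters under NB sampling —
not that they are robust to alignment- or protocol-level artifacts.

## Problem sizes and numerics

The test suite and the acceptance script run the study at its default
size (300 genes, ~4,300 regions, three genotypes — a few seconds
end-to-end) and the recovery experiments at 2,000 features; oracle
cross-checks use 25–100 random instances of 50 regions. Tolerances:
1e−9 for algebraic identities (TMM, BH, slopes on noiseless data), ±0.1
for the 2,000-window stochastic mean, rank-test significance at 0.01 for
the genotype contrasts. Ward clustering uses the classic Lance–Williams
update on 1 − Pearson distances with first-in-order tie-breaking; it is
cross-checked against an independent implementation via the square-root
distance transform. The trigamma inversion runs safeguarded Newton with
asymptotic seeds at both ends.

## Known limitations

* The corrected logFC removes between-sample attenuation but not the
  single-f concavity bias; comparisons across genotypes with different
  induction fractions are comparable in slope units, not in β units.
* With duplicate-free saturated designs, per-feature significance is
  unavailable by construction; all significance statements then come
  from cross-region rank tests.
* The outlier filter's mean ± 1.5 SD rule is aggressive on skewed count
  distributions and discards a visible share of legitimate windows; it
  reproduces the intended behaviour rather than an optimal one.
* TMM factors are computed per mark and genotype independently;
  cross-mark consistency is not enforced.
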