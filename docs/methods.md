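# Methods

This note documents the models, the statistical procedures, the defaults
and the numerical choices behind `pufstress`, and what the synthetic-data
tests do and do not demonstrate about real data.

## Growth-rate screening

Wells are modelled as exponential growers inside an automatically
detected logarithmic-phase window.

*Log-phase detection.* The window is the maximal contiguous run of
readings with OD₆₀₀ strictly above the floor (default 0.055) and strictly
below half of that well's maximum OD, truncated at the reading where the
cumulative count of consecutive-pair OD decreases inside the run first
exceeds the cap (default 5). The half-max always refers to the same
well's maximum, never a plate-wide value. All thresholds are exposed as
arguments. Two readings of the decrease rule are defensible — a
cumulative count versus a counter that resets on any increase — and the
cumulative reading is implemented because it is the more literal one;
the window boundaries it produces are reported so the choice is
auditable.

*Exponential fit.* Growth is fitted by ordinary least squares of ln(OD)
on time over the window. Exponential growth is exactly linear in log
space, which makes R² and RMSE well defined; RMSE is computed on the
ln(OD) scale (population form, √(SSE/n)), where the 0.2 validity gate is
dimensionless. A fit is valid only when R² > 0.9, RMSE < 0.2, the window
holds ≥3 readings and the slope is positive; invalid fits carry a
human-readable reason and propagate it when normalization is attempted.
Doubling time is 60·ln 2 / μ minutes with μ in h⁻¹.

*Normalization and aggregation.* The effect of a stressor is
μ_treated / μ_untreated for the same strain and plate, which cancels
medium, temperature and OD-calibration differences; it is invariant to
changing time units or multiplying all ODs by a constant. Replicates are
summarized by mean and sample SD; summaries with n < 3 are flagged as
under-replicated rather than suppressed.

*Blank correction* is a per-plate constant subtraction applied by the
caller before constructing curves if desired; it defaults to off.

## Count normalization and ratio profiles

Genes are first restricted to those with more than 100 reads (strict) in
at least one sample — a background filter that removes genes too shallow
to quantify. Filtering precedes size-factor estimation; the reverse order
is available by composing the functions directly.

Size factors are the median-of-ratios estimator: with geometric mean
g_i of gene i across samples (over the reference genes that have nonzero
counts in every sample), s_j = median_i(c_ij / g_i). Normalized counts
are c_ij / s_j. One subtlety is documented here because it affects a
common sanity check: rescaling one of m samples by a constant c rescales
every gene's geometric mean by c^(1/m), so the normalized matrix is
recovered only up to the global constant c^(1/m) — all between-sample
structure, ratios and downstream calls are unchanged.

Ratio profiles are log₂((x_num + p)/(x_den + p)) with pseudocount
p = 1 (configurable) on normalized counts, pairing T₄₅ (or T_end) with T₀
**within the same replicate batch**. The pseudocount bounds the ratios of
the zero counts that can survive the background filter; at background
levels >100 reads it perturbs true ratios by under 1%.

Replicate QC is pairwise Spearman rank correlation over genes (average
ranks on ties), flagging same-condition replicate pairs below 0.9 by
default. An external quantification (e.g. northern-blot band ratios) is
compared to pipeline ratios by Pearson correlation with the standard
t-distribution p-value.

## Deviation callers

The differential-expression rule is deliberately distribution-light: no
per-gene variance model, no fold-change cutoff, and no p-values — a gene
is "affected" when it deviates from the bulk trend by more than
2 standard deviations of the population.

*Mean deviation* (wild-type stress response): flag gene i when
|r_i − mean(r)| strictly exceeds 2·SD(r), with the sample SD over genes.

*Trend deviation* (knockout vs parent): regress query ratios y on parent
ratios x by OLS and flag genes whose **vertical** residual strictly
exceeds ±2 sample SDs of the residuals. The vertical residual (not the
perpendicular distance) is the standard regression residual and makes
the calls invariant under positive affine transforms of the query axis;
a perpendicular variant would not be. The residual SD includes all genes
in a single pass — no outlier-trimmed refit — so planted or real strong
effects inflate the cutoff slightly; that conservatism is intentional
and matches a single-pass reading of the procedure.

*Degenerate inputs.* If residuals are exactly zero up to floating-point
rounding (points exactly on a line), the residual SD is snapped to zero
and nothing is flagged; SD = 0 flags nothing because the inequalities
are strict.

*Null calibration.* Under Gaussian residuals the strict 2-SD rule flags
P(Z > 2) ≈ 2.28% of genes per tail — about 115 of 5,034 genes. This is
the quantity `scripts/acceptance.py` recomputes by simulation.

*Synergy.* The expected double-deletion log₂ change is the sum of the two
single-deletion log₂ changes against their own parents (the product of
fold changes in linear space) — the standard multiplicative expectation
for independent genetic effects. Observed double-deletion changes are
regressed on this expectation and the same ±2 SD residual rule is
applied; flagged genes are those whose double-deletion response cannot
be explained by the two single deletions acting independently.

*Replicates.* Every caller runs on one replicate batch at a time; batches
are never pooled before fitting, because depth and batch shifts differ
between independent repeats. Consensus keeps items called in ≥2
replicates (configurable), which suppresses the ~2.3%/tail per-replicate
false-positive rate roughly quadratically while retaining genuinely
shifted genes.

## Enrichment and motif scanning

Gene-set enrichment uses the hypergeometric upper tail
P(X ≥ k) = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n), evaluated through the
log-gamma based survival function (stable for N in the thousands and
p-values below 10⁻¹⁵). Enrichment is one-sided by design; a depletion
flag tests the lower tail. Genes absent from the background are dropped
from both the flagged and target sets with a logged warning.

UAAU scanning is a plain overlapping string scan on the RNA alphabet
(DNA input is transliterated T→U); the reverse strand is never searched.
The dual motif pairs **consecutive** UAAU occurrences whose linker
(gap between the end of the first and the start of the second) lies in
[1, 8] nt by default: a linker by definition contains no third motif
start, so a run of three motifs with short gaps chains into two pairs.
Both linker bounds are configurable, as the literature gives "short
linker" without a number. Multi-UAAU enrichment marks genes whose UTR
holds ≥2 occurrences (configurable) and applies the hypergeometric test
of that mark in a target list against a genome-wide background.

## Synthetic data

The generator emulates the study design so every stage can be tested
against planted truth.

*Counts.* Five strains (two parents; *puf1Δ* with parent WT-α, *puf2Δ*
with parent WT-a, and the double deletion compared against WT-α) ×
{T₀, T₄₅, T_end} × n replicate batches. Gene g in sample (strain s,
timepoint t, batch r) has log₂ mean

    baseline_g + shared_{t,g}·[t ≠ T₀] + dev_{s,t}(g) + b_r + log₂ d_{s,t,r}

where b_r ~ N(0, batch_sd) is a gene-independent shift shared by all of
batch r's samples (biological repeats are fully independent experiments,
so the batch effect is modelled at the sample level) and d is a
log-normal depth factor. The double deletion's deviation is the sum of
the two singles' planted deviations plus the planted synergy shift, so
by construction synergy genes depart from the product-of-singles
expectation by exactly the planted amount. Counts are negative binomial
with variance m + d·m² (size 1/d), the standard RNA-seq count model.

Defaults, chosen once as realistic for a well-replicated yeast
experiment and documented as package choices (the study reports read
totals but no per-gene parameters): 5,034 genes; baseline log₂ mean
~ N(7, 2²) (median ≈128 counts, upper tail into the tens of thousands);
dispersion 0.05; batch_sd 0.15; libsize_sd 0.25 (log₂-scale); shared
CaCl₂ response drawn N(0, 1) per gene and stressed timepoint when not
supplied. All randomness descends from one seed via
`SeedSequence.spawn` in a fixed order (parameters, batch effects,
depths, counts), so identical designs and seeds are bit-identical.

*Growth curves.* Logistic OD(t) = K·od₀·e^{μ(t−lag)} /
(K + od₀·(e^{μ(t−lag)} − 1)) after the lag (od₀ before), sampled every
15 min, multiplied by mean-one log-normal noise with the requested CV.
Defaults: od₀ 0.05, K 1.2, μ 0.5 h⁻¹ (doubling ≈83 min, typical rich
medium), lag 1 h, CV 0.02, 16 h duration. Note an interaction between
the logistic model and the half-max window rule: when a curve saturates
near K, the detected window extends to K/2 where growth has already
slowed, so recovered μ underestimates the design value. Recovery tests
therefore use a high capacity so the detected window lies in the truly
exponential region; with real saturating wells the reported μ is the
screen's operational "log-phase rate", exactly as the windowing rule
defines it.

*UTRs.* Uniform-random A/C/G/U backgrounds with UAAU written at the
planted positions; conflicting overlapping placements are rejected,
compatible ones (e.g. UAAUAAU) allowed. Expected background occurrences
are (L−3)/4⁴ per L-mer, ≈0.38 for a 100-nt UTR.

*What the generator does not emulate:* fragment-level coverage biases,
gene length and GC effects, correlated gene modules, mapping artifacts,
gene-specific batch interactions, and plate-position or evaporation
effects in growth curves. Passing recovery tests therefore demonstrate
the estimators' correctness under the stated noise model, not robustness
to every artifact of real sequencing or plate data.

## Problem sizes used in the checked results

The null calibration runs the caller on 5,034-gene Gaussian nulls,
averaged over 200 seeded repetitions. Planted-effect recovery uses
2,000-gene designs with 3 replicate batches over 20 seeds: 25 genes
planted up and 25 down at 4× the residual SD realized on a matched null
simulation, recovered through per-replicate calls plus 2-of-3 consensus
(the pipeline's operating mode). Growth-rate recovery uses noiseless and
CV = 0.02 curves with capacity 100 so the window stays exponential.

## Known limitations

- The 2-SD rule's false-positive rate is a fixed ~2.3% per tail per
  replicate; single-replicate call lists are correspondingly noisy and
  should always be consolidated across replicates.
- The trend fit is plain OLS: both axes carry sampling noise, so the
  slope is attenuated toward zero when the shared signal is weak. The
  calls are residual-based and remain calibrated, but the slope itself
  should not be interpreted as a regulatory coefficient.
- Size factors require at least one gene with nonzero counts in every
  sample; extremely sparse matrices need a different estimator.
- The dual-motif definition (consecutive occurrences, 1–8 nt linker) is
  one defensible reading of "two UAAU separated by a short linker"; both
  bounds should be varied when scanning real UTRs.
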