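# Methods

`prsport` implements a complete analysis of cross-population polygenic
score (PRS) transferability: score construction, accuracy evaluation, a
continuous genetic-distance metric, a model-based decomposition of the
accuracy loss, and recombination-rate stratification.  Because the
cohort data such analyses run on are controlled-access, the package
ships a synthetic generator that reproduces the statistical structure
the analysis depends on; every claim the test suite makes is therefore a
statement about recovery of known generative truth, not about any real
cohort.

## Polygenic scores

Scores are built by clumping + thresholding (C+T).  Given marginal GWAS
summary statistics harmonized to an LD reference panel, the greedy rule
repeatedly takes the smallest-p remaining variant with `p <= p_threshold`
as an index SNP and removes every remaining variant on the same
chromosome within `window_kb` whose dosage r² with it exceeds
`r2_threshold`.  LD is the squared Pearson correlation of dosages in the
reference panel (composite LD; no phasing).  The default tuning grid is
`p ∈ {5e-5, 0.01, 0.5} × r² ∈ {0.1, 0.5} × window ∈ {100, 250} kb`,
i.e. 12 scores per discovery population and phenotype; the score used
downstream is the grid argmax of incremental R² in the tuning
population, ties broken toward the smaller p threshold then smaller r².
Equal p-values clump in (chrom, pos) order so the output is invariant to
input row order.  The score itself is `PRS_i = Σ_j β̂_j G_ij` over the
selected variants; missing dosages are mean-imputed at `2p` from the
scoring panel.

## Accuracy

Accuracy is the incremental R²: the R² of phenotype on covariates plus
PRS minus the R² of covariates alone (OLS for quantitative traits).  For
binary traits both models are logistic regressions and the observed-scale
R² is the squared Pearson correlation between outcome and fitted
probabilities; the increment is converted to the liability scale with the
Lee et al. (2012) transformation, `R²_l = R²_o · K²(1-K)² / (z² P(1-P))`,
where `K` is population prevalence, `P` the sample case proportion
(`P = K` for a population cohort, the default when `K` is not supplied)
and `z` the standard-normal density at the threshold `Φ⁻¹(1-K)`.
Negative increments are reported as computed, never truncated, so
bootstrap intervals remain valid.  Uncertainty is the percentile
bootstrap over individuals (default 1000 replicates, 95% interval);
replicates on which a statistic is undefined (e.g. a case-free resample)
are redrawn with a logged count.

The observed relative accuracy between a target and the discovery
population is `RA_obs = R²_target / R²_discovery` on a common scale.

## Genetic distance

Group labels hide within-group heterogeneity, so transferability is also
profiled against a continuous distance:

1. **Reference PCA + projection.** PCs come from the SVD of the
   standardized reference genotypes (centered at `2p`, scaled by
   `√(2p(1-p))`).  Study individuals are projected with an online
   augmentation–decomposition–Procrustes (OADP) scheme: per study
   sample the reference Gram matrix is augmented with that sample,
   re-decomposed, and the augmented reference scores are similarity-
   aligned back onto the original reference scores, carrying the study
   sample along.  This corrects the toward-zero shrinkage of naive
   projection when variants far outnumber reference samples.  The
   residual self-projection error of the adjustment is O(1/n_ref)
   (about 1% of the coordinate norm at n_ref ≈ 400); naive projection
   (`projection="naive"`) remains available.
2. **Allele-frequency MDS.** Populations for which only summary allele
   frequencies exist (the discovery GWAS samples) are embedded by
   classical (Torgerson) MDS of the pairwise Euclidean distance matrix
   between population frequency vectors; signs are fixed by making each
   axis's largest-magnitude loading positive.  At least `k+1`
   populations are required for a `k`-dimensional embedding, which is
   why simulated studies include extra reference populations beyond the
   two under comparison.
3. **Procrustes mapping.** The MDS rows of the reference populations
   are least-squares aligned to their PC centroids by the closed-form
   similarity transform (scale, orthogonal matrix, translation);
   reflections are allowed by default because they can only reduce the
   alignment error (`allow_reflection=False` restores proper
   rotations).  The fitted transform maps every MDS row — including the
   GWAS populations — into PC space.

Genetic distance is the Euclidean distance between an individual's PC
point and the mapped GWAS point over the first five dimensions (five
throughout, configurable).  Profiles bin individuals into equal-sized
distance bins (20 by default; deciles for within-group profiles),
evaluate per-bin incremental R², and report the Pearson correlation
between bin-mean distance and accuracy with its bin-level p-value, which
is how such profiles are summarized graphically.  The PC coordinates are
included among the evaluation covariates; besides matching the standard
covariate set, this absorbs a small positive artifact whereby bins of
extreme PC coordinates carry more genetic variance (and hence higher
marginal in-bin R²) even in a homogeneous population.

## Relative-accuracy decomposition

The expected relative accuracy of a score trained in population 1 and
deployed in population 2 is modeled as

    RA = (ρ_b² h²₂ / h²₁)
       × ( Σ_k  mean_j[r_{kj,1} r_{kj,2}] √(p₂q₂/p₁q₁)_k  /  Σ_k mean_j[r²_{kj,1}] )²
       × Σ_k p₁q₁ β̂²_k / Σ_k p₂q₂ β̂²_k

with `k` over the M PRS SNPs, `j` over SNP k's *candidate causal*
variants — any variant within 100 kb whose r² with it exceeds 0.45 —
`p` the effect-allele frequencies, `q = 1-p`, `r` signed dosage
correlations under a common allele orientation, `h²` the SNP
heritabilities and `ρ_b` the cross-population correlation of causal
effects (taken as 1 when the true causal variants are unknown).  A SNP
is always its own candidate.  Constrained variants: `RA_LD+MAF` sets
`h²₁ = h²₂` and `ρ_b = 1`; `RA_LD` keeps only the tagging ratio (all
frequency terms at 1); `RA_MAF` treats every PRS SNP as causal
(candidate sets collapse to the SNP itself).  The share of the observed
loss a model explains is `LOA = (1 − RA_model)/(1 − RA_obs) × 100%`,
defined only when `RA_obs < 1`.

Choices where the design was open:

* the candidate screen's r² > 0.45 is evaluated in the population-1
  reference panel (candidates proxy what the discovery GWAS could tag);
  both the window and threshold are arguments;
* the frequency-ratio factor `√(p₂q₂/p₁q₁)` is indexed by the PRS SNP
  `k`, so it is constant across a SNP's candidates and averaging order
  does not arise;
* PRS SNPs monomorphic in either reference panel are excluded from all
  sums with a logged count (the ratio terms are undefined at
  `p(1-p) = 0`);
* standard errors come from a SNP-level bootstrap (resampling the M
  SNPs with replacement, default 1000 replicates) rather than analytic
  derivations, with normal-approximation CIs `± 1.96·SE`.  This is a
  deliberate, self-contained substitute for delta-method expressions
  and is labelled as such in the results object.

All four predicted terms equal 1 exactly when the two populations are
identical, `RA_full = (ρ_b² h²₂/h²₁)·RA_LD+MAF` exactly, and
`RA_LD+MAF = RA_MAF` exactly when every candidate set is the SNP itself;
these identities are enforced to 1e-12 in the tests.

The model is an approximation even under its own assumptions: it
replaces ratios of β̂-weighted sums by products of unweighted means, so
it is accurate when the frequency-variance ratio varies moderately
across SNPs (as for GWAS-ascertained common variants) and when the
causal variant is exchangeable within each candidate set.  In the
generative recovery experiments the LD+MAF model captures roughly 80%
of the loss induced by divergent LD while the MAF-only model predicts
essentially no loss; the residual gap is the heuristic's own
approximation error, not an implementation artifact.

## Recombination stratification

Each PRS SNP's local recombination rate is the mean rate over a 20 kb
window centered on it, computed exactly from the piecewise-linear
cumulative genetic map: `(map(pos+10kb) − map(pos−10kb)) / 0.02 Mb`,
with the cumulative map linearly interpolated (windows truncated at map
ends are renormalized by the covered length).  Integrating the map,
rather than averaging sampled rate values, makes the estimate invariant
to densifying the map with collinear points.  SNPs are split into four
equal-sized rate quartiles (ties broken by chrom, pos), each quartile's
sub-score is evaluated separately with percentile-bootstrap CIs, and
because the quartiles partition the SNPs the four sub-scores sum to the
full score.

## Synthetic data

Haplotypes are drawn from a Gaussian copula: within an LD block a
latent AR(1) Gaussian vector with parameter `ld_rho ∈ [0, 1)` is
thresholded at `Φ⁻¹(p_j)`; a genotype is the sum of two independent
haplotypes.  The implied genotype correlation for any pair is the
thresholded-bivariate-normal value, which the tests evaluate by
numerical integration as an oracle.  MAF (thresholds) and LD (latent
correlation) are therefore controlled independently — exactly the two
factors the decomposition isolates.  Blocks are independent, so no
long-range LD exists.

Causal effects are drawn standard normal for the first population and
correlated `ρ_b` for the others, either per allele (identical across
populations at `ρ_b = 1`) or per standardized genotype.  Environmental
noise is scaled per population so the realized genetic-variance fraction
equals that population's `h²` in sample; effects themselves are never
rescaled, preserving cross-population effect equality.  Binary traits
threshold the standardized liability at `Φ⁻¹(1-K)` — the regime in
which the Lee transformation is exact.  Summary statistics are actual
per-variant marginal regressions on a simulated discovery cohort (the
default), so β̂ carries the LD-induced tagging the decomposition's `r`
terms require; a fast analytic mode adds asymptotic noise to supplied
true effects and is blind to LD.  The admixture gradient draws each
individual's ancestry fraction `α ~ U(0,1)` and each LD block of each
haplotype from population A's copula with probability `α` (else B's), a
coarse model of ancestry segments under which per-variant expected
frequency is `α p_A + (1-α) p_B` and LD interpolates along the
gradient.  Recombination maps are piecewise-constant rates (background
plus rectangular hotspots, optional lognormal jitter) integrated into an
exactly piecewise-linear cumulative map.

What the generator does **not** emulate: coalescent genealogies,
selection, long-range LD, genotyping error, phasing ambiguity,
population-specific imputation quality, or environmental confounding
correlated with ancestry.  Passing recovery tests therefore show that
the estimators are correct under the stated model, not that real-data
transferability estimates are unbiased in the presence of those forces.

## Validation designs and problem sizes

The recovery experiments fix their own generative conditions:

* **MAF-only recovery** — 500 causal PRS SNPs with discovery
  frequencies `U(0.2, 0.5)` (mirroring GWAS ascertainment toward
  variants common in the discovery sample) and Balding–Nichols
  divergence at Fst = 0.1 (continental scale); equal `h² = 0.5`,
  `ρ_b = 1`, cohorts of 50,000, 20 replicate seeds.  Observed RA must
  sit inside the Monte-Carlo band of the MAF-only prediction.
* **LD+MAF recovery** — the same, but two-variant (tag, causal) blocks
  with latent copula correlation 0.95 in the discovery population and
  0.3 in the target, the causal member of each block chosen uniformly
  (so the candidate-causal heuristic's exchangeability premise holds);
  only tags are scored.  The MAF-only model must over-predict accuracy
  and the LD+MAF model must capture most of the additional loss.
* **Genetic-distance direction** — a 2000-individual admixture gradient
  against a 10,000-sample discovery GWAS with tagged architecture and
  Fst = 0.2 divergence (negative bin-level correlation), plus a
  homogeneous-population null (correlation indistinguishable from 0).
* **Recombination gradient** — four chromosome bands with rates 0.5,
  1.5, 3 and 6 cM/Mb and target-population latent LD falling from 0.9
  to 0.1 across bands, cohorts of 20,000: accuracy must decline
  monotonically across rate quartiles.
* **Liability recovery** — planted liability-scale R² of 0.08 at
  prevalence 0.25, n = 30,000, recovered within 0.015.
* **Bootstrap calibration** — 95% percentile intervals for a normal
  mean (n = 500, 1000 replicates) cover the truth at the nominal rate
  over 200 repetitions.

`scripts/acceptance.py` re-runs the same designs at somewhat smaller
cohort sizes (noted in its output's `n` fields) so the whole script
completes quickly on one CPU.

## Numerical notes and limitations

* Seeds: a single global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence.spawn` with a fixed stage order; identical
  seeds give bit-identical outputs.
* OLS R² uses `lstsq`; rank-deficient designs fall back to the
  minimum-norm solution with a warning (R² is unaffected).  Logistic
  models are unpenalized.
* The liability conversion assumes the liability-threshold model; for
  very rare traits (`K < 0.01`) the observed-scale correlation R² is
  noisy and the conversion factor large, so estimates are unstable.
* Strand-ambiguous (A/T, C/G) variants are dropped during
  harmonization rather than frequency-inferred: deterministic, at the
  cost of losing some variants.
* `RA_obs ≥ 1` makes LOA undefined and is reported as an error, not
  clamped.
* The pairwise relatedness pruner consumes an externally supplied
  kinship table; kinship estimation itself is out of scope.
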