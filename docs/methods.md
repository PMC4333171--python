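# Methods

This note documents the models implemented in `gpimpute`, the defaults and
the numerical choices behind them, and what the synthetic data can and
cannot establish.

## Study design

The pipeline studies how genotype imputation affects genome-enabled
phenotype prediction. Individuals with phenotype and genotype are split
2/3 : 1/3 into training (reference) and testing (target) sets under two
family layouts: **across families** (whole full-sib families assigned to
one side, minimising train–test relatedness) and **within families**
(members of each family randomised to both sides, maximising it). Testing
genotypes are reduced to an evenly spaced low-density panel (masking rates
50/75/90%), imputed back to the full panel from training-set haplotypes,
and each prediction model is evaluated on three genotype conditions: the
full panel, the imputed-to-full panel, and the reduced panel alone. The
reduced-panel condition retrains the model on the training set restricted
to the same panel, which is the only leakage-free way to align train and
test features. Metrics are the Pearson correlation between predicted and
observed (pre-corrected) phenotypes and the prediction mean squared error
(PMSE). One split per scenario is used by default, shared by all models so
model comparisons are paired.

## Synthetic populations

`simulate_population` gene-drops a heterogeneous-stock-style population:

* **Founders.** `n_strains` (default 8) fully inbred strains, one
  homozygous haplotype each, founder allele frequency 0.5 per locus.
* **Mixing.** `n_generations − 1` rounds (default 2) of random mating in an
  intermediate population sized `max(2·n_families, 4·n_strains, 48)`, so
  the final generation's parent pairs can be distinct.
* **Families.** The last generation consists of `n_families` (default 60)
  full-sib litters of `litter_size` (default 10). Parent pairs are disjoint
  when the parent pool allows and never identical, so families are genuine
  full-sib groups. Cage = family, except a configurable 10% of litters are
  split over two cages; this reproduces the cage–family confounding typical
  of heterogeneous-stock husbandry.
* **Meiosis.** Haldane model: recombination events in disjoint intervals
  are independent with r = ½(1 − e^(−2d)) for d Morgans. No interference,
  no mutation, no sex chromosomes, autosomal maps only.
* **Default dimensions.** 600 study individuals × 300 loci (5 chromosomes
  × 60 loci at 1.5 cM). These are deliberately desk-scale; real studies of
  this design run ~1,900 individuals × ~1,800 SNPs, and all dimensions are
  plain configuration.

`simulate_phenotypes` builds a trait as fixed covariate effects (age,
gender, month, cage density — simple categorical/uniform draws with
configurable coefficients) plus additive, dominance and pairwise
additive×additive epistatic values at `n_qtl` random QTL, a cage effect
and a Gaussian residual. Each genetic and cage component is rescaled to
its exact target variance, so the realised narrow-sense heritability
matches the architecture up to residual sampling noise. Two reference
architectures are provided: `BW_LIKE` (total variance ≈ 8.8, h² ≈ 0.45,
mostly additive) and `BMI_LIKE` (h² = 0.15 with substantial non-additive
variance). True breeding values and QTL effects are retained for
validation.

What the simulator does **not** emulate: a realistic allele-frequency
spectrum (founder frequencies are symmetric), genotyping-platform error
modes, selection, or the long-range LD structure of a real mosaic
population. Passing tests therefore demonstrate internal correctness and
the direction of design effects (relatedness, masking rate, architecture),
not real-data effect sizes.

## Phenotype pre-correction

Traits are pre-corrected with the animal model
y = Xθ + Wc + Zu + e, u ~ N(0, Aσᵤ²), c ~ N(0, Iσ꜀²), e ~ N(0, Iσₑ²),
where A is the pedigree numerator relationship matrix from the tabular
recursion (a_jj = 1 + ½a_{sire,dam}; a_ij = ½(a_{i,sire} + a_{i,dam})).
Variance components are estimated by REML: the restricted likelihood is
maximised directly over the log variance ratios (γᵤ, γ꜀) =
(σᵤ², σ꜀²)/σₑ² with σₑ² profiled out, using Nelder–Mead within bounds
log γ ∈ [−12, 8] and Cholesky factorisations of
H = I + γᵤ ZAZ′ + γ꜀ WW′. Direct maximisation was chosen over EM-style
iterations because the profiled two-parameter surface is cheap at this
scale and the optimiser is indifferent to poor starting values. Ratios
ending below 10⁻⁵ are snapped to exactly zero so degenerate models
collapse cleanly (both zero ⇒ y* = OLS residuals). Fixed effects use
treatment coding with an intercept; exactly collinear columns are dropped
by QR. The corrected response y* = y − Xθ̂ − Wĉ removes fixed and cage
effects only — the additive prediction u is *not* subtracted, so y*
retains all genetic signal for the downstream models.

## Imputation

A diploid **Li–Stephens** haplotype-copying HMM: the target's two gametes
are modelled as mosaics of K reference haplotypes. Between adjacent loci
each copied-from index switches with probability 1 − e^(−λd), d the map
distance in cM and λ = 0.1/cM by default (expected mosaic blocks ≈ 10 cM,
a few generations of recombination); the index is redrawn uniformly at
chromosome boundaries. Observed panel genotypes are emitted through a
per-allele error rate ε = 0.01, giving the 3×3 dosage-emission matrix by
convolving two Bernoulli flips; ε also guards zero-probability paths.
Posterior genotype probabilities at every locus come from forward–backward
over the K² haplotype-pair states (transitions applied via their separable
rank-one structure, O(K²) per locus), and the imputed code is the
posterior mode. Reference haplotypes are capped (default 200) by seeded
subsampling for runtime; the imputer never sees the pedigree, only
haplotypes. Imputation accuracy is the fraction of masked entries imputed
correctly; erroneous entries are decomposed into 0↔1, 1↔2 and 0↔2 code
switches, the three shares summing to one.

## Bayesian LASSO

y = μ + Xβ + e with the double-exponential prior on each marker effect in
its scale-mixture form: β_j | τ_j², σₑ² ~ N(0, τ_j²σₑ²), τ_j² ~
Exp(λ²/2), σₑ² ~ scaled-inv-χ²(df, S), λ² ~ Gamma(shape α₁, rate α₂).
Defaults S = df = 1, α₁ = 1.2, α₂ = 10⁻⁵ (a flat Gamma with prior mass
over a wide λ range). Gibbs updates: Gaussian conditionals for μ and each
β_j (residual maintained incrementally), inverse-Gaussian for 1/τ_j²,
scaled-inv-χ² for σₑ², Gamma(p + α₁, Στ_j²/2 + α₂) for λ². Markers are
centered, not standardised; an intercept is always included. The full
study-scale chain is 70,000 iterations after 5,000 burn-in; the package's
test-scale default is 6,000/1,000 with thinning 5, which the chain-
stability and Geweke checks show is ample at n ≤ 600, p ≤ 300. Freezing
τ² (`fixed_tau2`) converts the prior to a fixed Gaussian, giving the
closed-form ridge posterior used as an independent cross-check. The prior
hierarchy contains no pedigree random effect; on pre-corrected phenotypes
the markers are the only genetic term.

## RKHS with kernel averaging

Genotypic values are a sum of three Gaussian-process components, g = f₁ +
f₂ + f₃, fₘ ~ N(0, Kₘσ²ₐₘ), with Gaussian kernels Kₘ(xᵢ, xᵢ′) =
exp(−hₘ dᵢᵢ′) on squared Euclidean marker distances (centered codes).
Bandwidths follow the kernel-averaging recipe hₘ = |aₘ|/q₀.₅ with
multipliers {−5, −1, −1/5} and q₀.₅ the median off-diagonal distance —
the magnitude convention, since a literally negative h would make the
kernel explode. Variance components (three σ²ₐₘ and σₑ²) carry identical
scaled-inv-χ² priors with df = 5, S = var(y)/2·(df − 2). Sampling is done
in the eigenbasis of each kernel (eigenvalues below 10⁻⁸ dropped), where
the Gaussian conditional is diagonal; study-scale chain 50,000/5,000,
test-scale default 6,000/1,000. Prediction uses the implied kernel-space
coefficients α̂ₘ = Kₘ⁺f̂ₘ, so predicting the training set reproduces the
in-sample posterior means identically.

## Bayesian-regularised neural network

A feed-forward net with 5 tanh hidden neurons and a linear output
(s(R+1) + s + 1 parameters for R inputs) minimises F = γE_D + αE_w, E_D
the squared-error loss and E_w the squared-weight decay. Each of the 30
epochs takes one accepted Levenberg–Marquardt step (damping ×10 on
reject, ÷10 on accept) followed by evidence-framework updates with the
Gauss–Newton Hessian: n_eff = Σ γλᵢ/(γλᵢ + α) over the eigenvalues of
J′J, then α ← n_eff/(2E_w), γ ← (n − n_eff)/(2E_D). Numerical choices
that matter:

* LM solves use a Woodbury identity on the n×n matrix JJ′ whenever the
  parameter count exceeds n, so wide genotype inputs stay cheap.
* The coupled (α, γ) updates have a degenerate attractor when parameters
  outnumber observations (n_eff → n, γ → 0, α → ∞, the network collapses
  to a constant). Training therefore starts at α = 0.01, runs 3 LM-only
  warm-up epochs, floors (n − n_eff) at 0.02n and caps α at 10⁶. These
  guards leave the update equations intact away from the degenerate
  region.
* Inputs are min–max scaled to [−1, 1] per column with training statistics;
  the target is standardised and back-transformed.

Results are the average over an ensemble of restarts (20 at study scale)
differing only in seeded initial weights; a restart ending in a non-finite
state is excluded with a warning. Early stopping is intentionally not
offered — regularisation is the evidence framework's job. The ensemble
average of predictions is used; averaging correlations instead is a
one-line variant the evaluation layer could apply but does not.

## Scale choices in the test suite and acceptance script

Tests and `scripts/acceptance.py` run the study at 600 individuals × 300
loci with 50/75/90% masking, chains of 3,000–6,000 iterations (burn-in
1,000), BRANN ensembles of 3–5 restarts and a reference-haplotype cap of
100–120; imputation accuracy in the pattern tests is scored on a seeded
subsample of ~60 targets per scenario (≈ 10⁴ masked entries, ample for
ordering comparisons). The factorial runner trains each full-panel model
once per layout and reuses it for the full and imputed test conditions —
they are the same trained model by design — and retrains only the
reduced-panel models per masking rate.

## Known limitations

* The imputer is a clean Li–Stephens model, not a localized
  haplotype-cluster model; absolute accuracies are not comparable to
  specialised software, only the orderings studied here.
* REML assumes the phenotype's non-additive genetic variance can be
  absorbed by the residual during pre-correction; y* keeps that signal by
  construction, but σᵤ² estimates under cage–family confounding are
  biased upward, as expected for this design.
* With unphased real input the simulator-truth haplotype path is
  unavailable; the pipeline expects phased reference haplotypes (VCF with
  `|` genotypes) and does not implement statistical phasing.
* The exact HWE test is available (`hwe_exact_test`) but the χ² test is
  the default everywhere.
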