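# Methods

This note documents the models, the simulator design, the numerical choices
and the known limitations of `addomgs`.

## Population simulator

**Composite population.** Two founder populations in linkage equilibrium
are crossed: each generation-0 individual receives one gamete drawn
locus-by-locus from the frequency vector `p¹` and one from `p²`. The default
divergence scheme draws `p¹_i ~ U(0.05, 0.95)` and sets `p²_i = 1 − p¹_i`
(maximal divergence); a `mild` scheme draws both vectors independently. With
the maximal scheme the composite allele frequency is 0.5 at every locus and
the expected LD between loci a and b is
`Δ_ab = ((1 − 2θ_ab)/4)(p¹_a − p²_a)(p¹_b − p²_b)` — strong and long-range,
the regime where marker-based prediction is informative.

**Small breeding population.** The cross is large (default 5,000) but the
subsequent random-mating generations are kept at a census of 40
(`breeding_size`), matching the design's stated effective size Ne ≈ 39.22.
This matters beyond realism: the drift LD accumulated by the small
population is *shared* by every cohort sampled from it, and it is this
shared LD (together with the founder-divergence LD) that lets marker effects
estimated in one replicate predict individuals of another. With a large
random-mating phase, cross-replicate accuracy collapses to ~0.2–0.4 because
each family sample then carries mostly private bottleneck LD.

**Replicates.** Replicates of "the same conceptual population" share the
founder frequencies, the advanced composite and the calibrated trait; they
differ in the family sampling (which parents are drawn and how they are
paired into full-sib families) and in the phenotype noise. Validation and
training individuals therefore belong to the same population but to
different families. The genotyped cohort defaults to 20 full-sib families
of 50 from a pool of 40 parents (monogamous pairing when the pool is exactly
twice the family count); the reported effective size is `4·Nm·Nf/(Nm+Nf)`
over the sires and dams actually used — reported, not enforced.

**Meiosis.** Recombination uses the Haldane map function (no interference):
along each chromosome the transmitted strand switches between adjacent loci
with probability `c = (1 − e^(−2d))/2` for map distance `d`, with an
independent random start per chromosome. This is the two-state Markov
formulation of independent crossovers; a Monte-Carlo test checks the
realized recombination fraction at 0.1 cM against the map function.

**Traits.** Per-QTL genotype values are `m + a` (MM), `m + d` (Mm),
`m − a` (mm). Additive and dominance effects are i.i.d. standard-normal
draws (so the mean degree of dominance |d|/|a| is ≈ 1, complete dominance on
average); dominance direction defaults to mixed with 70% positive.
Calibration is performed on the realized cohort: the dominance effects are
rescaled (iteratively, since α = a + (q − p)d depends on d) until the
realized `Vd/Va` equals `(h²_broad − h²_narrow)/h²_narrow`, five designated
QTL are rescaled to carry 50% of the genetic variance under the major-genes
architecture, and `σ²_e` is set so the realized broad-sense heritability on
that cohort equals the target exactly. Scenario mapping: 1 = infinitesimal
h² 0.30/0.20, 2 = major genes 0.30/0.20, 3 = infinitesimal 0.50/0.35,
4 = major genes 0.50/0.35. Markers failing the cohort MAF > 0.05 filter have
their founder frequencies redrawn and the pipeline re-run, so the full
marker panel (default 2,000 SNPs at 0.1 cM over 10 × 20 cM; 100 of them
QTL) is always emitted; under the default divergence scheme this loop
essentially never triggers.

## Estimation

**REML / BLUP.** `fit_reml` maximizes the restricted likelihood of
`V = σ²_a K_a + σ²_d K_d + σ²_e I` by EM warm-up followed by
average-information (AI) steps, falling back to a (monotone) EM step when
the AI step leaves the parameter space, lowers the likelihood, or the AI
matrix has condition number above 1e8. The condition guard exists because a
cohort consisting only of full-sib families makes pedigree A and D within-
family blocks span the same two-matrix space — the three variances are then
not jointly identified and unguarded AI steps wander along an
equal-likelihood ridge. Variances are floored at `1e-8·var(y)`; convergence
is a relative parameter change below 1e-8 or a restricted-likelihood change
below 1e-10 (which also terminates cleanly on flat ridges); 500 iterations
maximum, non-convergence flagged rather than raised. BLUPs solve
Henderson's equations with a 1e-8 diagonal ridge on `G_a`/`G_d` before
inversion; a variance at its floor returns a zero effect vector (complete
shrinkage). The marker-level equivalent model (`solve_marker_mme`) accepts
scalar or per-locus variances and is checked to reproduce G-BLUP
predictions exactly.

**Gibbs sampler.** One kernel (numba-compiled) serves all eight MCMC
methods; they differ only in the prior block. Updates per iteration, in
order: intercept (flat prior); each additive then each dominance marker
effect from its normal full conditional, site by site in fixed locus order
with residual updating; marker-variance block; residual variance. The prior
blocks:

- *BRR*: one common variance per effect block, scaled-inv-χ²(df2 + n, ·)
  conditional; df2 = −2 is the flat limit.
- *BayesA\*B\* (t prior)*: per-locus variances,
  τ²_i | · ~ scaled-inv-χ²(df2 + 1, df2·S² + m²_i) — marginally a Student-t
  prior with df2 degrees of freedom on the effects.
- *IBLASSO (Laplace)*: exponential-mixture latents,
  1/τ²_i | · ~ InvGaussian(√(λ²/m²_i), λ²), and
  λ² | · ~ Gamma(n + df2/2, Στ²/2 + df2·S²/4); the Gamma prior on λ² is the
  transform of a scaled-inv-χ²(df2, S²) placed on the implied prior effect
  variance 2/λ² (flat limit at df2 = −2 gives shape n − 1).
- *BLASSO*: as IBLASSO but with the effect variances scaled by σ²_e
  (single-variance-component parameterization); the effect quadratic forms
  then enter the σ²_e conditional, whose degrees of freedom grow by the
  marker count.
- *RR-HET*: per-locus variances fixed at the posterior means of an
  IBLASSO(4,−2) run on the same data (a two-stage pipeline).

σ²_e uses scaled-inv-χ²(df1 + N, ·); df1 = −2 flat. Prior scales default to
method-of-moments values: (σ̃²_a, σ̃²_d, σ̃²_e) solve the 3×3 cross-trace
system of a Haseman–Elston-type regression of `y_c y_c'` on
`{G_a, G_d, I}` (clipped below at 2% of var(y)), and
`S²_ma = σ̃²_a/Σ2pq`, `S²_md = σ̃²_d/Σ(2pq)²`. Chains derive per sample
`σ²_a = Σ2p_iq_i m²_ai` and `σ²_d = Σ(2p_iq_i)² m²_di`. Protocol defaults:
120,000 iterations, 20,000 burn-in, thinning 10 (10,000 retained). Chains
are reproducible from the seed. Convergence is monitored with a Geweke
diagnostic (means of the first 10% vs last 50% with Bartlett-window
spectral-density variances); arviz no longer ships one, so it is
implemented here and calibrated under the null in the tests.

**Validation protocol.** One replicate is held out; each training replicate
yields marker effects (the REML methods through the equivalent marker
model), which are applied to the validation replicate's own W/S coding and
correlated with its true breeding values and dominance deviations; metrics
are plain means across training replicates with SDs alongside. Bias is the
OLS slope of true on predicted (1 = unbiased). Pedigree-BLUP carries no
marker effects and pedigree relationships across replicates vanish, so its
accuracy is computed within the training replicate — the only reading under
which a pedigree method scores a nonzero validation accuracy. The
"number of criteria best" score marks a method for h2a, h2d and Vd/Va when
within 0.02 of the method value closest to the parametric one, for the two
accuracies when within 0.02 of the highest, and for the two bias slopes
when inside [0.5, 1.5].

**Deterministic accuracies.** `r_aâ = sqrt(r²_mq (N r²_mq h²_a/n_QTL) /
(1 + N r²_mq h²_g/n_QTL))`, analogously with `h²_d`, combined in quadrature
for the genotypic accuracy. At the full design the capture proportion
entering these formulas is `r²_mq = n/(n + 2NeL) = 0.93`, the value that
reproduces the design's printed accuracies 0.68 and 0.73; the alternatives
`n/(n + n_QTL) = 0.95` and `1/(1 + 4NeS) = 0.86` are exposed. For the
scaled-down test design (genome shrunk to 10 × 5 cM at unchanged 0.1 cM
spacing, 500 markers, 25 QTL, N = 500) the spacing-based rule is used for
the prediction, since S and Ne are exactly the full design's values while L
is not.

## Information decomposition

The same cohort is analysed three ways — raw phenotypes (co-segregation +
LD + family IBD relationships), within-family deviations with all families
together (co-segregation + LD), and one family at a time on family-corrected
phenotypes with unweighted averaging over families (LD only) — plus
pedigree-BLUP on the raw data (co-segregation + individual IBD).
Heritability components are simple differences (CS = AWF − DMS,
F-IBD-R = raw − AWF, I-IBD-R = pedigree − CS; they sum back to the raw h²
by construction) while accuracy components are quadrature differences
`sqrt(x² − y²)` — the asymmetry is kept deliberately, mirroring how such
partitions are tabulated. Negative derived components are floored at zero
with a warning. The composed related-individuals accuracy
`r_related = r_ped + (1 − r_ped)·r_LD` and the marker-captured fraction of
pedigree information `h²(I-IBD-R)/h²(LD)` are reported as table attributes.
Decomposition accuracies are within-cohort correlations with the true
breeding values (the family structure must stay intact, so no held-out
replicate is available).

## What the simulator does and does not emulate

It emulates: biallelic SNP dosages with controlled composite LD, small-Ne
breeding structure, full-sib family cohorts, additive-dominance traits with
calibrated heritabilities and degree of dominance ≈ 1, two architectures,
MAF-filtered dense panels. It does not emulate: mutation, selection or
migration (deliberately excluded), multi-allelic markers, genotyping error
or missingness, sequence-level variation, linkage maps with interference,
or environment/GxE structure. Passing tests therefore demonstrate the
estimators' behaviour under a clean additive-dominance generative model
with strong LD — not robustness to real-data artefacts such as genotyping
error, population admixture beyond the two-founder cross, or model
misspecification.

## Numerical choices and degenerate inputs

- Relationship matrices get a `1e-8 · mean(diag)` ridge before inversion.
- Allele frequencies are estimated from the genotyped cohort; coding is
  undefined at p ∈ {0, 1}, so monomorphic loci must be filtered (the
  simulator's MAF step guarantees this); in per-family re-analysis,
  frequencies are clipped to [1e-6, 1 − 1e-6] so loci monomorphic within a
  family produce near-zero incidence columns instead of errors.
- A constant phenotype yields zero BLUPs and the mean as intercept; a
  zero-variance input to accuracy/bias computation raises.
- Inverse-Gaussian sampling clips its mean parameter at 1e8 (effects
  numerically at zero); variance draws are bounded away from zero.
- Marker effects are updated in fixed locus order; chains are bit-identical
  across runs with the same seed.

## Problem sizes in the test suite

The default suite exercises the full pipeline at reduced sizes chosen to
keep the statistical content intact: unit fixtures use 40–250 markers and
100–500 individuals; the stochastic recovery tests use the scaled design
(500 markers, 25 QTL, N = 500, 10,000 Gibbs iterations) averaged over eight
seeds, where measured G-BLUP and BayesA\*B\*(−2,8) validation accuracies
(0.68–0.69) sit within 0.01–0.04 of the deterministic predictions. The
full design (2,000 markers, N = 1,000, 120,000 iterations, ten replicates)
runs through `addomgs scenario`; spot checks at that scale give G-BLUP
cross-replicate accuracies of 0.64–0.67 against the deterministic 0.68.

## Known limitations

- The pedigree additive-dominance model is not identified on a cohort of
  full-sib families only (no half-sib or multi-generation ties); REML
  returns one point on the equal-likelihood ridge, deterministically.
- Cross-replicate validation of pedigree-BLUP is undefined (zero
  relationships); the within-replicate accuracy reported instead measures
  fit, not transfer.
- The method-of-moments prior scales can be poor for very small N; they are
  config-overridable.
- `Vd/Va` recovery at small problem sizes is noisy for all methods; the
  ranking patterns among the eight MCMC methods stabilise only at the full
  design size.
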