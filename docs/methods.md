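# Methods

This note documents the models, estimators and design choices behind
`straintrack`, and what the synthetic-data tests do and do not show
about real data.

## Species coverage and abundance

Species depth in a sample is the trimmed mean of SNP-site coverages
(major + minor counts): the `floor(0.05·L)` largest and smallest
values are dropped per side, with ties broken by position order.  The
count-based trim (rather than percentile thresholds) makes the
estimator exactly permutation-invariant and linear under count
scaling; for L < 20 nothing is trimmed and the estimate is the plain
mean.  Relative abundance divides by the sample's summed coverage;
samples with zero total coverage are reported as missing rather than
as an arbitrary point of the simplex.

## Strain deconvolution

Each species is a mixture of K binary haplotypes over its biallelic
sites.  With per-sample frequencies `f[:, s]` on the simplex,
genotypes `g[k, l] ∈ {0, 1}` (1 = minor allele) and symmetric
sequencing error ε, minor counts are binomial with success rate
`q = ε + (1 − 2ε)·Σ_k f_k g_kl`.  Fitting alternates:

1. **Frequency step.** For fixed genotypes, each read is a latent
   draw from one strain, giving a standard EM update of every
   sample's frequency vector (iterated to a 1e-10 relative tolerance,
   at most 60 inner iterations).
2. **Genotype step.** For fixed frequencies, sites are independent,
   so each site's K-vector of alleles is maximised *exactly* by
   scoring all 2^K assignments (two matrix products); above K = 10 a
   per-(strain, site) coordinate sweep is used instead.  The exact
   step matters: the coordinate sweep alone stalls in local optima
   where two strains should swap alleles at a site.

Both steps are monotone in the log-likelihood (asserted in tests to
1e-8 per step).  The outer loop stops at a 1e-6 relative
log-likelihood change or 500 iterations; the best of `n_restarts`
(default 2 in the pipeline, 3 in recovery studies) seeded
initialisations is kept.  Initial frequencies are symmetric
Dirichlet(1); initial genotypes are coin flips weighted by the pooled
per-site minor fraction.

K is fixed per run (pipeline default 4, hard cap 20), not selected by
any information criterion: with the detection filter downstream,
overfitting K splits a true strain into near-duplicates that share
its provenance, which perturbs counts far less than it perturbs
per-strain identities.  ε defaults to 0.01 and is not estimated.
Inferred strains are identifiable only up to permutation; evaluation
against a truth uses Hungarian assignment on genotype Hamming
distance.  At 200× species coverage, 100 sites and K ∈ {2, 3, 4} the
model is essentially fully identifiable (genotype accuracy ≈ 1.0,
mean absolute frequency error < 0.01); accuracy degrades gracefully
with coverage, and samples with zero species coverage are excluded
(frequencies reported missing) rather than imputed.

Deconvolution uses 100 uniformly subsampled sites per species (of 200
simulated), matching the protocol of consuming only a random site
subset for tractability.

## Detection, origin classification and transferability

A strain is *detected* in a sample when its study-wide relative
abundance strictly exceeds a threshold.  The default threshold is
1e-3.  This value is deliberately above the EM noise floor: at ~200×
species coverage the fitted frequency of a strain that is truly
absent from a sample lands at up to ~1e-3 within its species
(relative abundance ~1e-4 for a 1%-abundance species), so a 1e-4
threshold reads mixture-model leakage as presence.  Detection
semantics are shared by the strain filter (detected in ≥ 2 samples),
origin classification and transfer counting, so "present" means one
thing throughout.

Origin labels per (patient, strain) use the patient's baseline sample
and the donor profile (coverage summed over the donor's samples, then
normalised): detected in baseline only → baseline-specific; donor
only → donor-specific; both → shared; neither → neither.  Strains in
neither reference (possible inference artifacts) form an explicit
class so that community fractions stay conservative and sum to one.

The per-phylum transferability index divides transfer successes
(donor-specific strains detected in the patient at F1) by
opportunities (donor-specific strains pooled over donor–patient
pairs).  The pipeline's default opportunity definition applies a
detectability guard band (`margin = 2`): a pair counts only when the
strain is clearly present in the donor (relative abundance >
margin × threshold — otherwise a genuine transfer would be
unobservable at F1, biasing the rate down) and clearly absent from
the baseline (< threshold / margin — otherwise a retained baseline
strain hovering at the threshold can jitter above it at F1 and count
as a false transfer, biasing the rate up).  `margin = 1` recovers the
plain count over donor-specific labels.  Both biases are real at a
single threshold: in recovery studies with a true rate of 0.03 the
unguarded estimator exceeded its 99% binomial interval on a
substantial fraction of seeds, while the guarded estimator is
approximately unbiased.

## Community statistics

Bray–Curtis dissimilarity (`1 − 2Σmin/(Σx+Σy)`) serves compositional
taxonomic profiles; cosine dissimilarity serves functional-gene and
bile-acid profiles, which are not compositional.  Taxonomic
aggregation sums strain abundances within GTDB lineage assignments;
phylum subsetting renormalises within the phylum and masks samples
with no abundance there.

ANOSIM uses average ranks with `R = (r̄_between − r̄_within)/(M/2)`,
`M = n(n−1)/2`, and a one-sided permutation p with the add-one
estimator `(1 + #{R_perm ≥ R_obs})/(n_perm + 1)`; 9999 permutations
by default.  NMDS delegates to scikit-learn's non-metric MDS
(normalised stress, seeded starts); its internals are not part of
this package's contracts beyond stress reporting and determinism.

Mantel machinery operates on masked dissimilarity matrices: for the
longitudinal design, only within-patient pairs are defined
("block-diagonal"; inter-patient entries masked), built over
baseline, maintenance and follow-up samples with any post-antibiotic
samples excluded by configuration.  The permutation null permutes
sample identities independently within each patient block (blocks are
recovered as connected components of the mask), preserving the
repeated-measures structure; p-values are two-sided on |r|.  Partial
Mantel residualises both matrices on a control by simple linear
regression and correlates the residuals; the time control is
√(|days_i − days_j|) — the square root of the interval between
collections, not the difference of square roots, a reading documented
here because both exist.  When the control explains a matrix to
round-off (residual spread ≤ 1e-10 of the data spread) the partial
correlation is defined as exactly 0.

## Clinical statistics

Remission is total Mayo ≤ 2 at first follow-up with endoscopic
improvement ≥ 1; response is a drop of ≥ 3 total points.  Both are
pure predicates of two visit records.  Patients who withdrew before
follow-up can be excluded or coded non-remission via an explicit
flag, since both analyses are standard.  The two-sided Fisher exact
p-value is the point-probability method (summing hypergeometric
probabilities no larger than the observed table's), which reproduces
0.065 for [[6,3],[2,9]] and 0.18 for [[6,5],[2,9]]; the log odds
ratio is the sample value ln(ad/bc) with a 1.96·SE Wald interval,
reported as undefined for zero cells.  Rank tests delegate to SciPy
(exact small-sample distributions without ties).  The GEE contrast
fits a Gaussian marginal model with an AR(1) working correlation
ordered by time within subject and robust (sandwich) covariance, and
tests the covariate's coefficients with a Wald chi-square; GEE has no
likelihood, so this working contrast stands in where a
likelihood-ratio test would otherwise be quoted, and a covariate with
no variation returns statistic 0, p 1 rather than an error.

## Synthetic study generator

The generator produces truth and observations for a configurable
study.  Defaults emulate the trial's design: 3 donors with uneven
sampling (10/31/1 metagenomes in the trial; 10/31/1 is the default
replication pattern), 22 patients randomized round-robin over the
2×2 arms and assigned donors round-robin, and the calendar B (−7 d),
D1–D6 (weekly doses, days 7–42), F1–F3 (days 56, 84, 140 — about 2,
6 and 14 weeks after the last dose).  Six phyla carry baseline
weights 54.0 / 18.3 / 10.4 / 8.1 / 3.6 / 2.8% (Firmicutes A,
Bacteroidota, Actinobacteriota, Firmicutes, Proteobacteria,
Firmicutes C); species draw their phylum from these weights, and
communities are log-normal (σ = 1) weights over a random half of the
strain pool, so heavy-tailed abundances and phylum composition follow
the weights through species counts.

FMT is modelled as independent Bernoulli events: each baseline strain
is retained with probability 1 − displacement (defaults 0.7/0.3 for
ABX+/ABX−, reflecting antibiotic knock-down) and each donor strain
transfers with an (arm, phylum)-dependent engraftment probability
(defaults ordered like the observed per-phylum transfer rates, ±25%
by pretreatment arm).  Retained and transferred weights combine and
renormalise into a post-FMT composition held across D1–F3 with
multiplicative log-normal jitter (σ = 0.2) — a stand-in for
within-patient dynamics, which the generator does not attempt to
model mechanistically.  Sequencing draws Poisson site totals
(mean coverage × species abundance × log-normal depth factor,
σ = 0.3) and binomial minor counts through the same error model the
EM inverts.  Bile acids and gene families are
`exp(subject intercept + coupling · loadings · composition + noise)`
— patient-stable, weakly composition-coupled, strictly positive;
at couplings ≲ 1 the exp link is near-linear, which is where the
deterministic no-noise limit reproduces composition distances almost
exactly.  Remission is Bernoulli with per-arm log-odds (defaults
logit(6/11) and logit(2/11)), and Mayo tables are constructed to be
consistent with the drawn outcome and trial eligibility (baseline
total 4–9, endoscopy 1–2).

A single root seed drives everything through per-operation child
streams (`numpy` `SeedSequence.spawn`), so a study is bit-reproducible
and stages can be re-run independently.

**What passing tests show — and don't.**  The generator shares its
likelihood with the EM and its event model with the transfer
estimator, so recovery tests certify internal consistency,
identifiability at the stated coverages, and calibration of the
permutation machinery.  They do not certify robustness to real-data
features the generator omits: linked strains within a species
(haplotypes here are independent coin flips), reference bias and
mapping artifacts in metagenotypes, strain-level selection dynamics
after FMT, compositional depth artifacts, or batch structure in
metabolomics.

## Problem sizes and defaults

The default end-to-end study is 3 donors, 22 patients, 50 species at
mean coverage 1000 (a desk-scale stand-in for the trial's 371
species); it runs in about two minutes on one CPU.  Recovery studies
use per-species coverage near 200× — the regime where strain
inference is reliable — with 160 species, baseline + F1 time points
and displacement off, so the baseline community is a fixed provenance
reference and ≥ 300 transfer opportunities accrue per phylum.
Permutation tests default to 9999 permutations in the pipeline;
calibration studies use 199 per replicate across 200 replicates.
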