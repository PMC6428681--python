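# Methods

## Statistical model

### Burden regression

For an individual *i* with case indicator *y_i*, the burden model is a
logistic regression of case status on the count of qualifying variant
alleles,

    logit Pr(y_i = 1) = β0 + β1·N_i + β2·S_i + γ'·PC_i + δ·sex_i + waves,

where *N_i* is the number of qualifying alleles (a mutation class × allele
frequency regime × gene subset selection), *S_i* is the individual's
synonymous allele count over the whole panel at the same frequency regime
(a per-sample sequencing-quality covariate: technical artefacts inflate
all classes, true risk inflates only the functional ones), *PC* the first
ten ancestry principal components, and sequencing-wave indicators
(contrasts against the first wave) included only for targeted-sequencing
designs where batch and phenotype can be confounded. β1 is reported as a
log odds ratio per additional allele.

Estimation is by Firth's penalized likelihood: maximize
ℓ(β) + ½·log det I(β), the Jeffreys-prior penalty on the Fisher
information. This removes the O(1/n) bias of the MLE and guarantees a
finite interior optimum under complete or quasi-complete separation — the
generic situation for rare variants, where all carriers in a small gene
set may be cases. The solver uses the modified-score Newton iteration with
leverage-corrected residuals, step-halving whenever a step would decrease
the penalized likelihood, convergence at max|Δβ| < 1e-8, and a 100
iteration cap (non-convergence is flagged on the result, never silent).
Rank-deficient designs raise an error naming the collinear columns
(pivoted QR); covariates constant in the data are dropped with a logged
warning, but a constant burden column is an error with explicit status —
reporting p = 1 for an untestable gene would silently distort corrected
scans.

Inference defaults to Wald: p = 2·Φ(−|β/se|), CI = exp(β ± 1.96·se), with
se from the inverse Fisher information at the penalized optimum. Wald was
chosen as default because published odds ratios, intervals and p-values in
this literature cohere under Wald reconstruction (e.g. an OR of 1.36 with
CI 1.13–1.64 reproduces the printed p = .0012 exactly). A penalized
likelihood-ratio p is available (`p_method="plr"`); it fixes the burden
coefficient at zero *within the full design* and re-maximizes, so the
log-det penalty compares like with like — refitting a smaller design would
shift the penalty by the dimension change and corrupt the statistic.

### Mutation classes and frequency regimes

Atomic classes are LoF, damaging missense (NSD), other missense, and
synonymous. Analysis composites are nested by default: the NSD analysis
class is LoF ∪ NSD and the nonsynonymous class is all three, because
published count tables in this field are consistent with cumulative
classes; an `exclusive` switch is provided since the convention is not
always recoverable. The paralog-conserved composite is LoF ∪ (missense
flagged as falling at a position conserved across the paralogous gene
family); its negative-control counterpart is flag-false missense only
(flag-missing sites belong to neither). A sensitivity flag drops LoF sites
from the composite. Genes without paralog conservation scores (in the
default synthetic panel: two of the four sodium-channel beta subunits, and
all genes outside the two channel families) contribute only LoF sites to
the composite — `restrict_paralog_flags` masks their missense flags.

Frequency is computed on the combined case+control sample within each
dataset (allele count / 2N), with the rare regime keeping frequency
strictly < 0.1% and the singleton regime keeping allele count exactly 1;
singleton status is dataset-local in meta-analyses. An external reference
panel filter is not implemented; the within-sample filter is the
configurable default.

### Empirical nulls

Label permutation shuffles case-control labels uniformly (covariates stay
attached to individuals) and recomputes the covariate-adjusted burden |z|
per shuffle; the empirical p uses the add-one rule (r+1)/(n+1), bounded
below by 1/(n+1). Plain unstratified permutation is the default; a
within-stratum option (e.g. within sequencing wave) is provided because
wave can be confounded with phenotype in targeted designs. The random
gene-set null compares a focal set's statistic with sets of equal gene
count sampled from the panel, with the focal genes either excluded from
the pool (does the set beat the rest of the panel?) or included (does it
beat comparable sets drawn from all paralogous genes?). The default
set-level statistic is the burden log odds ratio, under which set size
cancels; matching on summed coding length instead of gene count would be a
natural extension but is not implemented.

### De novo enrichment

Given per-gene per-class mutation probabilities μ (per chromosome per
generation), the expected count over a gene set in n trios is
λ = 2·n·Σμ, and the observed count is tested with the exact Poisson upper
tail P(X ≥ k) evaluated through the survival function (regularized
incomplete gamma). λ in candidate-set analyses is well below 10, so no
normal approximation is used; P = 1 at k = 0 by construction. The class
tested per set is configurable, following whichever class was previously
reported as most enriched (all-nonsynonymous for one synaptic complex, LoF
for the other, in the default pipeline wiring).

### Meta-analysis and combination

Default case-control combination is a pooled ("mega") Firth regression on
concatenated individual-level tables with cohort indicator covariates;
fixed-effects inverse-variance weighting of per-cohort log odds ratios is
the alternative and supplies Cochran's Q (Q = Σw_i(β_i − β̄)², df = k−1,
χ² upper tail). Whether published meta-analyses pooled individuals or
summaries is usually not recoverable from main texts; both modes are
first-class and agree closely for balanced cohorts with a common effect.
`se_from_ci` inverts a printed OR (95% CI) to its log-scale standard error
so summary tables can enter the meta without raw data.

Case-control evidence is made one-sided in the direction of the point
estimate (p/2 if enriched, 1 − p/2 otherwise) and combined with the
already-one-sided de novo p by Fisher's method, −2Σln p ~ χ²(2k); the two
samples are disjoint, so independence holds. The halving convention is
anchored by reproducing a published combined p (4.0 × 10⁻⁴) from its
printed inputs. Effect-size differences between partitions (e.g.
LoF-intolerant vs tolerant genes) use z = (β1−β2)/√(se1²+se2²) with
configurable sidedness — the published value this reproduces is one-sided,
which is documented rather than silently assumed.

Bonferroni denominators for the named test families are fixed constants:
6 (panel burden: 3 classes × 2 regimes), 4 (primary gene sets), 8
(paralog-conserved secondary), 12 (subunit dissection), 20,000
(single-gene, exome-wide). The pLi partition assigns the boundary value
pLi = 0.9 to the tolerant side. Overlapping sets can be re-tested after
set-difference removal of shared genes.

## Synthetic data generator

The generator emulates the *data structure and first two moments* of a
targeted case-control panel, not sequence-level realism. Per mutation
class c and gene g, each individual carries a qualifying allele with
probability expit(logit(rate_c/G) + 1{case}·lnOR + covariate terms), so
the case carrier odds equal the control odds inflated by the configured
odds ratio and the closed-form expected case count is Σ_g expit(·).
Carrier counts are drawn per individual per gene per class; rare-variant
linkage and haplotypes are ignored because the analysis consumes only
counts. Carried alleles are grouped into sites by a sequential process
(new site with probability 0.6, else join an existing site of that
gene × class), giving the singleton-heavy allele-count spectrum that makes
the two frequency regimes meaningfully different; allele counts assume one
variant allele per carrier. Only SNV classes are modelled — indels are
excluded by construction.

Defaults are the study conditions the package targets: 5207 cases, 4991
controls, 1136 trios, a 187-gene panel (28 + 61 + 14 + 26 + 58, the
sodium-channel set split 10 alpha / 4 beta), 106 LoF-intolerant genes, and
exclusive-class control carrier rates derived from published per-person
rates under the nested hierarchy: LoF 0.039, damaging-missense-only 1.051
(= 1.09 − 0.039), other-missense 0.639 (= 1.73 − 1.09). The synonymous
rate is not printed in the sources this models; 1.0 per person was chosen
once as comparable to the damaging-missense burden, which is the right
order for a ~0.5 Mb coding target. Covariate effects default to zero
(sex, PCs, wave); a `confound_wave` switch gives cases and controls
distinct wave mixes to exercise the adjustment. Missense sites in the two
channel families are flagged paralog-conserved with probability 0.3 (a
typical conserved fraction for ion-channel paralog alignments),
configurable elsewhere via a second fraction. De novo rate tables give
each gene a total point-mutation probability of `rate_scale` (default
1e-5 per chromosome per generation, the right magnitude for an average
gene) with lognormal gene-to-gene variation (σ = 0.5) split 10/65/25%
across LoF/missense/synonymous; trio counts are Poisson(2·n_trios·μ·
enrichment). Everything is deterministic under the config seed.

What passing tests on these cohorts do **not** show: robustness to
genotype error and coverage heterogeneity, linkage between rare variants,
realistic site-frequency spectra, population substructure beyond Gaussian
PCs, or annotation error in class labels. The generator validates
configuration (non-negative rates, positive odds ratios, non-empty sets,
per-gene carrier probabilities in [0,1]); note that per-person class
rates are means of counts and legitimately exceed 1 for missense classes.

## Numerical choices and degenerate inputs

- Firth solver: tolerance 1e-8 on max|Δβ|, ≤ 100 iterations, ≤ 25
  step-halvings, penalized log-likelihood via slogdet (−∞ on non-PD
  information, which step-halving then avoids).
- Poisson tails, χ² tails and normal quantiles via scipy's survival
  functions; complementarity P(X≥k) + P(X≤k−1) = 1 holds to 1e-12.
- Degenerate CI (low = high) in `se_from_ci` returns 0 with a warning;
  `wald_ci` at se = 0 collapses to the point estimate.
- Empirical p-values can never be 0 (add-one rule); permutation
  statistics are recomputed with the identical covariate-adjusted fit on
  observed and permuted labels.
- Multi-allelic sites are assumed decomposed upstream (one ALT per
  record); VCF input uses 1-based coordinates per the standard and is a
  sites-only convenience reader (INFO keys GENE, CLASS, PCONS, AC).

## Problem sizes used in the test suite

Calibration suites run at sizes chosen to make their Monte-Carlo error
small relative to the asserted bands: CI coverage of injected odds ratios
{1, 1.5, 2} uses 200 replicates of 5000/5000 individuals at carrier rate
0.04; the type-I-error check uses 1000 replicates of 1000/1000 (≈ 80
carriers per replicate, comfortably in the Wald test's calibrated
regime); the random-gene-set power check uses 10 replicates of 2000
sampled sets over a 60-gene panel; permutation accuracy is checked
against exhaustive enumeration of all 20 label arrangements of a
6-individual fixture. The full-scale synthetic run (5207/4991, 187 genes)
is exercised once in the acceptance script.

## Known limitations

- No SKAT-type dispersion tests, mixed models, random-effects meta, or
  Bayesian case-control/de novo integration — burden regression plus the
  combinations above only.
- No variant-effect prediction, transcript annotation, or derivation of
  mutation rates from sequence context: classes, flags and μ are inputs.
- The "damaging" missense label is treated as given; no predictor is
  modelled.
- Gene panels and set memberships are configuration inputs, never
  hard-coded; the bundled 187-gene layout is synthetic.
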