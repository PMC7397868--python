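# Methods

## The estimand

A protein's intensity in an oligo(dT) pull-down is, up to a shared capture
constant, A·φ·κ·C: abundance A, in vivo poly(A)+ RNA-bound fraction φ,
UV-crosslink efficiency κ, capture efficiency C. Its whole-cell-extract
(WCE) intensity is A. The paired log2 ratio RIC − WCE therefore estimates
log2(φκC); after per-column median centering the shared constants drop out
and the ratio ranks proteins by their binding activity φκ. The package
never attempts to separate φ from κ — no desk analysis can — and all
downstream statements ("high activity", "substoichiometric") refer to the
product.

## Enrichment statistics

Order of operations: impute, center, merge, score.

1. **Imputation.** Label-free non-detections are left-censored; every
   missing cell is set to the fixed background value 18 (log2) within its
   triplicate batch, before batches are merged. Detection flags
   (both / RIC-only / WCE-only) are always taken from pre-imputation
   missingness, with "detected" meaning observed in at least one replicate
   of the fraction (configurable).
2. **Median centering** (WCE-normalized mode only) subtracts each sample
   column's median, imputed cells included; the noCL-normalized contrast
   uses raw imputed intensities. With heavily censored pull-down columns
   the column median can pin at the imputation floor; this is expected and
   harmless, since only ratio differences matter downstream.
3. **Ratios.** WCE mode uses paired per-replicate differences
   d_i = RIC_i − WCE_i matched by batch and replicate (the extract is the
   input of that same pull-down), giving the mean ratio and its replicate
   SD in one pass — the SD-vs-ratio table is emitted for SD plots. The
   noCL mode is an unpaired contrast of crosslinked (n=6) against
   non-crosslinked (n=3) captures with pooled variance on n₁+n₂−2 df.
4. **Moderated test.** Per-protein variances are shrunk toward a scaled
   inverse-χ² prior fitted by moment matching on e_g = ln s²_g − ψ(d/2) +
   ln(d/2): the excess of Var(e) over ψ′(d/2) is inverted through the
   trigamma function (Newton iteration) to give d₀, and s₀² follows from
   mean(e). Zero variances (fully imputed groups) are excluded from the
   fit but still moderated, receiving s̃² = d₀s₀²/(d₀+d). If the observed
   dispersion does not exceed the sampling term the prior degenerates to a
   point (d₀ = ∞, s₀² = exp(mean e), the bias-corrected geometric mean)
   and the test becomes a z-test. P-values are two-sided on d₀+d df; BH
   ("fdr") and Bonferroni adjustments are both reported. With d₀ = 0 the
   machinery reduces exactly to the ordinary one-sample t-test, which the
   test suite exploits as an oracle, alongside a cross-check against the
   reference R implementation on a small fixture.

## Comparative shifts

For each genotype the ratio is summarized by RatioMoments (means, squared
SEs and covariance of the mean RIC and mean WCE signals). Propagation is
second-order Taylor: exact for the default log2-difference scale (the
Hessian vanishes), genuinely second-order for the optional linear-ratio
scale f = x/y, where E ≈ f(μ) + ½tr(HΣ) and Var ≈ gᵀΣg + ½tr((HΣ)²).
The truncation error of the linear-ratio *variance* grows like 4·CV_y²
(≈4% at CV 0.1), which is why log2-difference is the default; the
linear-ratio engine matches its own frozen second-order values to
machine precision. Note Var(x/y) for Gaussian y is not even finite, so
Monte-Carlo "truth" for it is itself an effective, truncation-dependent
quantity.

Design choices that were genuinely open:

- **Covariance.** RIC and WCE replicates come from the same culture, so
  their means are positively correlated; the default estimates the paired
  covariance (equivalently, uses the variance of the paired differences).
  `covariance: independent` restores the two-independent-errors behavior,
  which overstates the SE when replicate abundance noise is shared.
- **Pseudo-replicates.** The corrected shift and its SE are converted to
  n = 3 draws with *exact* sample moments (center, rescale, shift), so
  t, P and Q are identical across seeds. The pseudo-replicate SD defaults
  to SE·√n, making the ordinary t of the draws equal shift/SE — the
  calibrated choice (the literal SD = SE option inflates null statistics
  by √n and is provided as `pseudo_sd_scale: literal`).
- **Prior df.** Because the pseudo-replicates carry the propagated SE
  verbatim, the across-protein scatter of their variances is that of the
  underlying replicate-based estimate; the prior is therefore fitted, and
  the moderated t formed, with the effective df (n_wt−1)+(n_mut−1) rather
  than the nominal pseudo-replicate df. Using the nominal df would
  attribute all scatter to sampling noise and collapse the prior to total
  pooling, penalizing well-quantified proteins.
- **Rescaling.** "Crosslinked proteins" for the global constant are those
  detected in RIC of both genotypes pre-imputation; the constant is the
  negative mean of their raw shifts (a single multiplicative factor in
  linear space, idempotent by construction). Mean-centering implies that
  with many truly shifted proteins, unaffected proteins acquire a small
  opposite offset — visible as a mildly elevated false-positive rate when
  a large fraction of the proteome moves.
- Proteins detected in RIC of at least one genotype are tested; the
  detected-in-mutant flag distinguishes full from empty circles.

## Domain classification

Per nonclassical Pfam domain, over RIC-detected member proteins that
neither carry a classical RBD nor the cytosolic-ribosome GO term:
unclassified if fewer than 4 members; classical-like if the median ratio
≥ +2 (the 4-fold enrichment cutoff); substoichiometric if ≤ −2; adaptive
if the members span both thresholds; otherwise adaptive when the IQR
exceeds half the threshold span, else the nearest-median class. The ±2
boundaries are anchored to the high-activity (>4) and underrepresented
(<0.25) ratio cutoffs and are configurable; the class rule is a declared
quantitative convention for what is, in the source material, a visual
call. GO-term statistics are descriptive fractions only — enrichment
testing is deliberately out of scope.

## Binding curves

Anisotropy r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥); titrations default to the
13-point two-fold dilution series from 1240 nM (≈0.30 nM floor; the exact
dilution factor of the published series is a declared convention). The
4PL y = y_min + (y_max−y_min)/(1+(x/K_d)^(−n)) is fitted by unweighted
Levenberg–Marquardt least squares with K_d and n log-parameterized
(positivity), initialized at y_min = min y, y_max = max y, K_d at the
log-interpolated midpoint, n = 1, with up to three jittered restarts.
Standard errors come from the Jacobian at the optimum via the chain rule
back from log scale. Degenerate inputs (fewer than 5 points, <10× span,
flat curves) are rejected with diagnostics.

## Synthetic experiments

Per protein g, replicate i (log2 scale):

    WCE  = log2 A_g              + b_s + u^WCE_{c(g),i} + ε_{g,i}
    RIC  = log2(A_g φ_g κ_g C)   + b_s + u^RIC_{c(g),i} + ε_{g,i}
    noCL = log2(A_g β C)         + b_s + ε'_{g,i}

with left-censoring of anything below the detection limit L. ε is
culture-level replicate noise *shared* by the RIC and WCE of the same
replicate — they derive from one extract — so it cancels in paired
ratios; noCL controls are separate cultures with independent ε′. The
complex-shared term u is drawn per fraction, replicate and complex
(proteins outside complexes are size-1 complexes), so complex members
co-vary in their ratios — the generative basis of the concordant
"noisiness" of complex subunits — and σ_cplx is the effective ratio
noise. b_s is a per-sample offset removed by median centering except
where a column median pins at the imputation floor.

Defaults (chosen once as a realistic, well-powered testbed; the noise and
abundance scales are free parameters of the emulation, not fitted to any
deposited dataset): 2000 proteins, 100 complexes of mean size 4,
abundance log2 ~ N(25, 3²), φ mixture with 30% high binders
(LogUniform(0.25, 1)) over a substoichiometric bulk
(LogUniform(0.005, 0.05)), κ ~ LogUniform(0.05, 0.3), C = 0.5, noCL
background β = 0.01, L = 18, σ_rep = 0.3, σ_cplx = 0.1,
batch-offset SD 0.05, two batches of triplicates with noCL only in the
first. With these settings ~39% of all cells are censored, pull-down
columns majority-censored — deliberately harsh for the imputation path.

The mutant generator shares A, κ and complex structure between genotypes
and multiplies φ by 2^Δ (clipped at 1) for the affected proteins, using
the single-batch triplicate comparative design. The annotation fixture
plants nonclassical domains on well-separated φ strata, restricting
members to a central κ band (domain families with coherent crosslink
chemistry) and to the most capturable proteins of each stratum, since
classes are only assessable on detected proteins; classical-RBD and
ribosome-GO distractors are placed outside the planted pools.

What the generator does *not* emulate: peptide-level quantification and
protein inference, intensity-dependent (non-left-censored) missingness,
per-protein nonspecific stickiness in the noCL channel (background is one
global β), isotope labeling, and real Pfam/GO annotation structure.
Passing tests therefore demonstrate the statistics and the pipeline
plumbing under a faithful abstraction of the design — not robustness to
every pathology of real MS data.

## Problem sizes and numerics

Simulation-based checks run at 2000 proteins (the default design), 20,000
null proteins for calibration, 10⁷ Monte-Carlo draws for propagation, 50
generator seeds × 199 label permutations for the complex-noise structure,
and 100 titration seeds for K_d recovery; together they complete in well
under a minute on one CPU. Trigamma inversion iterates Newton to 1e-10
relative; BH/Bonferroni go through statsmodels; median centering is exact
to 1e-12; P-values are floored at 1e-300 to stay in (0, 1]. Ties in the
4PL midpoint initialization fall back to the geometric mean of the
concentration range.

## Known limitations

- RIC/WCE ratios conflate φ and κ; crosslink-efficiency differences can
  masquerade as binding-activity differences between proteins (not within
  a protein across genotypes, where κ cancels).
- Imputation at a fixed floor biases ratios of partially censored
  proteins toward the floor; the monotonicity and identity guarantees in
  the test suite hold for fully quantified proteins.
- The mean-centering rescale assumes most crosslinked proteins do not
  shift; global redistribution of RNA between fractions would be absorbed
  into the constant.
- The moderated test assumes a single variance population; strongly
  bimodal variance structure (clean vs censoring-dominated proteins) is
  only partly captured by the prior.
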