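# ric-activity

Estimating in vivo poly(A)+ RNA-binding activity from RNA interactome
capture (RIC) proteomics, for groups who quantify oligo(dT) pull-downs
against their whole-cell extracts (WCE) and want statistics rather than
presence/absence lists.

In RIC, living cells are UV-crosslinked, poly(A)+ RNA is captured on
oligo(dT) beads, and co-purifying proteins are quantified by label-free
mass spectrometry. A protein's enrichment in the pull-down relative to its
cellular abundance — the **RIC/WCE ratio** — estimates the product of two
quantities: the fraction φ of the protein bound to poly(A)+ RNA in vivo
and its UV-crosslink efficiency κ. Normalizing capture intensities to the
WCE therefore turns a qualitative interactome into a quantitative map of
binding activity: it separates proteins that live on mRNA (high ratios)
from *substoichiometric* binders that crosslink reproducibly but bind with
only a small fraction of their pool (low ratios).

The package implements the full statistical workflow around that idea:

- **Enrichment statistics** (`ric_activity.enrichment`): left-censored
  intensities imputed at a fixed background floor (18, log2), per-sample
  median centering, paired per-replicate log2 RIC/WCE ratios (or unpaired
  crosslinked-vs-noCL contrasts), and an empirical-Bayes moderated t-test.
  The per-protein variance s²_g is shrunk toward a scaled inverse-χ² prior
  whose hyperparameters (d₀, s₀²) are fitted by moment matching on log
  variances; the statistic t = x̄ / (s̃/√n) with
  s̃² = (d₀s₀² + d·s²_g)/(d₀ + d) is referred to a t distribution on
  d₀ + d degrees of freedom. BH and Bonferroni adjustments, and the
  detected-in-RIC/WCE population flags, complete the volcano tables.
- **Comparative RIC** (`ric_activity.comparative`): mutant-minus-WT
  **shift coefficients** of RIC/WCE ratios with second-order Taylor
  uncertainty propagation, a global rescaling constant (mean-centering of
  shifts over crosslinked proteins), exact-moment pseudo-replicates
  (sample mean and SD reproduced exactly, so inference is independent of
  the simulation seed), and the same moderated test.
- **Domain classes** (`ric_activity.domains`): nonclassical RNA-binding
  domains classified as *classical-like*, *substoichiometric*, or
  *adaptive* from the distribution of their member proteins' ratios
  (domains on fewer than four detected proteins stay unclassified), plus
  high-activity / underrepresented protein sets (ratio > 4 or < 0.25 at
  P < 0.01) and annotation-fraction comparisons.
- **Binding assay** (`ric_activity.binding`): fluorescence anisotropy
  r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥) and four-parameter logistic fits
  y = y_min + (y_max − y_min)/(1 + (x/K_d)^(−n)) for K_d estimation.
- **Synthetic experiments** (`ric_activity.simulate`): a generative model
  of the whole design — log-normal abundances, a two-component φ mixture,
  crosslink efficiencies, complex-shared noise, left-censoring at the
  detection limit, the two-batch triplicate layout with noCL controls in
  the first batch, and mutant effects — with full ground truth, so every
  stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write plot-ready tables under `results/`:

```bash
python analysis/01_simulate_experiment.py
python analysis/02_enrichment_analysis.py
python analysis/03_comparative_shifts.py
python analysis/04_domain_classification.py
python analysis/05_binding_curve.py
```

Output of steps 02–05 (seed 1):

```
[wce] 1983 proteins scored; populations: {'wce_only': 1208, 'both': 775}
[wce] variance prior: d0 = 4.71, s0^2 = 0.04556
[wce] Spearman(true log2 phi*kappa, estimated ratio) = 0.9985 over 775 both-detected proteins
710 proteins tested; rescale constant c = -0.03364 log2
affected complex: 4/5 detected proteins reach q < 0.05; 0 other proteins do
24 domains classified: {'classical_like': 8, 'substoichiometric': 8, 'adaptive': 8}
planted-class recovery: 100.0% of 24 domains
Kd = 48.7 +/- 3.4 nM (truth 47 nM), Hill n = 0.94, ymin/ymax = 0.049/0.255
```

Reading this: of 2000 simulated proteins, 775 are detected in both the
pull-down and the extract, and their estimated RIC/WCE ratios rank them by
true binding activity φκ almost perfectly (Spearman 0.998). In the mutant
comparison, the complex whose RNA binding was halved is recovered at
q < 0.05 with no false positives among the other ~700 tested proteins.
All 24 planted nonclassical domains receive their constructed class, and
the binding fit recovers the 47 nM dissociation constant within its
standard error.

The same stages are available as a CLI for external TSV data:
`ric-activity simulate|enrich|compare|classify|fitbind --help`.

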