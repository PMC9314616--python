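# Methods

`tigermoth` implements the analysis chain used to connect the wood
tiger moth (*Arctia plantaginis*) hindwing-colour genotype to its
phenotype: Mendelian inheritance inference from rearing pedigrees,
multispectral colour/pattern feature extraction, discriminant
classification of genotypes, and receptor-noise-limited (RNL)
discriminability modelling for ecologically relevant receivers.  A
seeded synthetic-data generator reproduces the statistical structure of
the rearing and photography data so the whole pipeline is testable
end to end without any external data.

## 1. Genetic model

A single autosomal locus with two alleles controls male hindwing
colour: `W` (white) is dominant over `y` (yellow), so `WW` and `Wy`
males are white and `yy` males yellow.  Offspring distributions for the
six unordered parent-genotype pairs are exact Punnett-square
enumerations (`genetics.offspring_genotype_distribution`), and male
phenotype distributions are their pushforward through the dominance
map — the classic 3:1 white:yellow ratio for `Wy x Wy`.

Female hindwing colour is scored on a 1–6 yellow–orange–red scale and
treated as uninformative for the locus: all inference conditions on
male phenotypes only.

## 2. Synthetic data generator

### Pedigrees

Founders are drawn at Hardy–Weinberg proportions for a configurable W
allele frequency (default 0.5); pairs mate with one uniform gamete per
parent per offspring; offspring sex is Bernoulli(1/2).  Families with
fewer than 10 male or 10 female offspring are *flagged* excluded, never
dropped, so the reliability filter's effect is itself testable.  In
multi-generation mode each later generation mates offspring of the
previous one (avoiding full-sib pairs when possible), which produces
the linked pedigrees the back-trace operates on.

The female score is a standard-normal latent value binned at fixed cut
points.  Cut points are placed once by quantile matching so that the
category marginals equal the configured probabilities — default 3%
yellow (scores 1–2), 68% orange (3–4), 29% red (5–6), each category
split evenly between its two scores.  A genotype shift parameter moves
the latent mean by `-s, 0, +s` for `WW, Wy, yy`; its default is 0
because the female phenotype shows no usable coupling with the male
locus, but the hook exists for sensitivity analyses.

### Specimen images

Specimens are four co-registered reflectance rasters (`uv`, `sw`, `mw`,
`lw`) of default size 96 x 96 px with a fixed rectangular ROI layout
(forewing FW, hindwing HW, thorax TH, abdomen AB; disjoint by
construction, 0-based row-major pixel coordinates).  Per
(genotype, sex, ROI, channel) the generator draws

    reflectance = mean + specimen offset + pixel noise,  clipped to [0, 1]

* `mean` — the configured genotype/sex-specific reflectance.  The
  defaults encode the study system's structure: `yy` hindwings with
  high long-wave and low short-wave reflectance (yellow), a hindwing UV
  difference between the two white genotypes, and lower thorax/abdomen
  UV in `WW` than `Wy`.  Female hindwings are orange for every
  genotype.
* `specimen offset` — one Gaussian draw per specimen, ROI and channel
  (sd 0.04 by default).  This is the biological between-individual
  scatter; without it ROI means over thousands of pixels would have
  essentially zero within-class variance and every classification
  problem would be degenerate.  0.04 against UV effect sizes of ~0.1
  yields per-feature standardised effects near 2.5, which puts the
  three-genotype LOO accuracy in the mid-to-high 90s — the regime the
  real photographs occupy.
* `pixel noise` — independent per-pixel Gaussian noise (sd 0.02).

Pattern texture is square markings (configurable scale, count,
reflectance) stamped into the forewing; `yy` males get larger and more
numerous markings.  Per-specimen randomness is hashed from
`(cohort seed, index)` via `numpy.random.SeedSequence` spawn keys, so
specimen *i* is unchanged when the cohort grows.

What the generator does **not** emulate: real wing shapes, specular
effects, illumination spectra, camera spectral sensitivities,
registration error, or any correlation structure between ROIs beyond
the shared genotype means.  Tests passing on this generator show the
*pipeline* recovers known structure; they do not certify accuracy
numbers on real photographs.

## 3. Mendelian inference

* **Goodness of fit.**  Observed male phenotype counts are compared to
  model expectations with Pearson's chi-square without continuity
  correction, `df = (#cells with positive expectation) - 1`.  A
  positive count in a zero-expectation cell raises an
  "impossible observation" error rather than producing a NaN: it is a
  model violation signal.  A chi-square test of independence on a
  contingency table is also provided, but the goodness-of-fit form is
  the default.  The pooled segregation test treats every offspring as
  an independent observation, pools counts within cross strata and
  sums the per-stratum statistics and degrees of freedom.
* **Back-trace.**  The parental cross is inferred from F1 male counts
  by binomial maximum likelihood over the six crosses (yellow
  probabilities 0, 0, 0, 1/4, 1/2, 1).  Exact ties are reported as
  sets: all-white broods always give the three-way tie
  {WW x WW, WW x Wy, WW x yy}, an irreducible identifiability class.
  The ML rule is Bayes-optimal under a flat prior, so its error is the
  information limit: at 40 male offspring, the binomial overlap between
  yellow fractions 1/4 and 1/2 alone gives ~5.4% misclassification for
  `Wy x Wy` and ~4.0% for `Wy x yy` (~1.6% pooled over the six cross
  types), and no decision rule can do better from male counts alone.
  An optional Hardy–Weinberg founder prior adds a posterior and its
  mode.
* **Pedigree propagation.**  Exact genotype posteriors are computed by
  enumerating all `3^n` joint configurations of each connected pedigree
  component (Hardy–Weinberg founder priors, Punnett transmission,
  dominance evidence from observed male phenotypes, direct
  conditioning on recorded genotypes).  The component cap is 12
  individuals: dense enumeration stays well under a second there,
  while the spec'd alternative of exact peeling is out of scope for
  this version; larger components raise an explicit error asking the
  user to partition.  Zero-probability evidence marks the component
  inconsistent (NaN marginals) rather than raising, except for direct
  record-level genotype/phenotype contradictions, which are data
  errors.

## 4. Feature extraction

* **Calibration.**  Raw responses are mapped affinely so the 7% and
  93% grey standards land at 0.07 and 0.93, then clipped to [0, 1].
* **Granularity.**  The luminance channel (long-wave) of each ROI is
  cropped to its bounding box, non-ROI pixels replaced by the ROI mean
  (a stated approximation that keeps mask edges from injecting
  energy), and band-pass filtered in the Fourier domain at scales
  `2 x 1.414^k <= 100` px (12 bands).  A band at scale *s* passes
  wavelength *s* px at unit gain and crossfades to zero at the
  adjacent band centres with a raised-cosine profile in log-frequency;
  adjacent bands therefore partition energy smoothly and DC is always
  excluded (band energies are mean-invariant and scale linearly with
  contrast).  Band energy is the standard deviation of the filtered
  pixels inside the ROI.  Summaries: dominance (maxPower) = peak
  energy; diversity (propPower) = peak / summed energy; marking size
  (maxFreq) = scale of the peak band, ties broken toward the smallest
  scale and flagged.  "Pattern contrast" is not given a formula in the
  source analysis chain; it is implemented as the root of summed
  squared band energies, flagged as a convention and swappable.
* **Luminance histogram.**  20 equal bands over [0, 65535] (the
  long-wave channel rescaled to the 16-bit dynamic-range anchor),
  right edge inclusive in the last band.  Computed on request but
  excluded from the default discriminant feature set, since its role
  in the original discriminant analysis is unclear.
* **Allometry.**  Area ratios FW/AB, FW/TH, FW/HW, TH/AB.  (The
  published variable list abbreviates the third ratio inconsistently;
  forewing-to-hindwing is the intended quantity and is what is
  implemented.)
* **Correlation filter.**  Greedy elimination: drop zero-variance
  columns, then repeatedly drop the member of the worst `|r| >= 0.9`
  pair with the larger mean absolute correlation to the remaining
  columns (ties toward the later column), until no pair exceeds the
  threshold.  Deterministic; every drop is reported with a reason.

## 5. Genotype classification

Fisher/Gaussian LDA as a 3-group problem.  Features are standardised;
the pooled within-class covariance uses the `n - k` denominator and is
ridge-regularised by `1e-6 x trace/d` on the diagonal when singular
(recorded on the model).  Discriminant axes solve the generalised
eigenproblem of between- versus within-class scatter and are
Sw-orthonormal (whitened), at most `k - 1` of them.  Class priors are
uniform by default — with groups as unbalanced as 37/88/42, empirical
priors would bias assignment toward the heterozygote — and
configurable.  Evaluation is leave-one-out with a full refit per fold:
deterministic, and honest for cohort sizes in the low hundreds.
Predictions are invariant under any invertible affine transform of the
feature space (Mahalanobis property, verified in tests).

The shadow-feature screen appends an independently permuted copy of
every feature each iteration, fits a seeded random forest (default 500
trees, sqrt-features per split, impurity importance; swappable), and
counts wins of each real feature over the maximum shadow importance.
A two-sided binomial test against 0.5 at level 0.01 splits features
into confirmed / tentative / rejected.

## 6. Vision models

Receiver noise follows the Weber-fraction convention anchored to the
most abundant cone class: `e_i = w sqrt(eta_max / eta_i)` with
`w = 0.05` for all receivers, so the most abundant channel has noise
exactly 0.05 and rarer channels are noisier.  Built-in receivers:
trichromatic human (sw:mw:lw = 0.057:0.314:0.629 — noise
0.1661:0.0708:0.0500), tetrachromatic blue tit (uv:sw:mw:lw =
1:1.92:2.68:2.7) and trichromatic moth (uv:sw:mw = 1:1:1, the true
ratio being unknown).

Quantum catches default to identity selection of the receiver's
channels from the like-named camera channels — the original camera-to-
cone transform is not published, so this is a stated approximation,
and a linear mapping matrix hook accepts a proper transform when one
is available.  Catches are floored at 1e-6 (flagged) to keep logs
finite.

Receptor signals are `delta f_i = ln(qA_i / qB_i)` (the standard
high-signal log form) and chromatic contrast is the general n-channel
RNL quadratic form

    dS^2 = df' (V^-1 - V^-1 1 1' V^-1 / (1' V^-1 1)) df,   V = diag(e_i^2),

the noise-weighted distance after projecting out the achromatic
direction.  This reduces exactly to the published dichromat /
trichromat / tetrachromat closed forms, which are kept as a reference
implementation and cross-checked to 1e-9.  dS is symmetric,
zero on identical stimuli, invariant to scaling one stimulus uniformly
(intensity) or one channel of both stimuli (von Kries).  Note that dS
is *not* monotone in a single `delta f_i` when other channels are
non-zero (the quadratic's minimum sits off the origin); monotonicity
holds along rays from the achromatic origin, which is what is tested.
Achromatic contrast dL is deliberately not implemented.  A contrast
below 1 JND is reported as indistinguishable.

## 7. Numerical and design choices

* Seeds: every generator is a pure function of (config, seed); cohort
  and pipeline stages derive child seeds by hashing, all below 2^31.
* Distribution sums, symmetry and marginal identities are tested at
  1e-12; granularity against its spatial-domain convolution oracle at
  1e-8; RNL closed forms at 1e-9.
* Degenerate inputs raise typed errors (empty ROIs, zero-expectation
  observations, single-member classes, cyclic pedigrees) rather than
  returning NaN.
* Problem sizes in the test suite and acceptance script (cohorts of
  100 specimens x 10 seeds at 96 x 96 px, 2000 replicate family sets,
  1000 back-trace families per cross, 50 shadow-screen runs at 25
  iterations x 100 trees) are chosen so a complete run finishes in a
  few minutes on one CPU while keeping Monte-Carlo error well inside
  the asserted margins; the shadow screen's library defaults remain
  100 iterations x 500 trees.

## 8. Known limitations

* The pedigree enumerator is exact but exponential; components above
  12 individuals need manual partitioning (no peeling in this
  version).
* The granularity mean-fill treats non-ROI pixels as featureless; ROIs
  much smaller than twice the largest band scale trigger a warning and
  their large-scale energies are unreliable.
* Classifier accuracies measured on synthetic cohorts characterise the
  pipeline, not the real photographic data: the generator's
  between-specimen scatter is Gaussian and ROI-independent, which real
  specimens are not.
* The camera-to-receptor identity mapping ignores true spectral
  sensitivities; absolute dS values should be read as model contrasts,
  and only their orderings (e.g. UV-sensitive receivers vs human) as
  findings.
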