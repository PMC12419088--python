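# Methods

`cortexlayers` re-implements, as a tested library, the statistical pipeline
of a depth-resolved proteome study of the developing mouse cerebral cortex.
Four genotypes are compared — control (CTRL), LIN28A overexpression (GL),
stabilized CTNNB1 / WNT activation (GB), and both combined (GBL) — using
consecutive ~40 µm tissue layers ablated from the skin surface into the
cortex (nine layers at E14.5, eighteen at E18.5), with hemisphere
replicates and two technical batch factors (laser-ablation batch `LA1..LA4`
and mass-spectrometry measurement batch `M1..M8`). Because the animal data
are not recomputable, a synthetic generator with complete ground truth
drives every stage; this note records the model behind the generator, the
statistical procedures, the numerical choices, and what the passing tests
do and do not demonstrate about real data.

## Study design and manifest

`build_manifest` enumerates one sample per (genotype, timepoint,
hemisphere, layer): CTRL contributes five hemispheres (the fourth
biological replicate supplies both hemispheres as technical replicates,
ablated in the separate batch `LA4`), the other genotypes three each.
Three exclusions reproduce the study's quality control: one E14.5 GBL
sample and nine deep E18.5 CTRL samples (region-of-interest shift), and one
E14.5 CTRL sample (human keratin contamination). The resulting accounting —
124 E14.5 samples, 243 E18.5, 367 total — is exact integer arithmetic and
is asserted in the tests.

## The abundance generator

Log2 abundance of protein *i* in a sample at layer *l* is

    x = base_i + delta_i * [compartment(l) in affinity(class_i)]
        + slope_i * l + perturbations + batch offsets + N(0, sigma)

* **Compartments.** Each layer belongs to an anatomical compartment:
  at E14.5 a non-neural block (layers 1–4) and cortex (5–9); at E18.5 an
  outer skin/bone block (1–2), a meningeal block (3–9) and cortex (10–18).
  These blocks are the planted counterparts of the consensus clusters
  C1/C2 and C3–C5 — a modelling choice that makes cluster recovery
  well-posed, not a claim about the data.
* **Tissue classes.** 8% of proteins are surface-specific (elevated
  7.0 log2 units in skin/bone-containing compartments), 8%
  meninges-specific and 15% cortex-specific (2.5 log2 each); per-protein
  effect sizes are jittered (SD 0.4) but shared across genotypes, so
  abundance rankings — and hence layer signatures — agree between
  genotypes wherever no perturbation is planted. The large surface effect
  reflects that the keratin-rich skin/bone proteome is drastically unlike
  CNS tissue; it also matters numerically (see *Consensus clustering*).
* **Depth gradients.** 30% of the unreserved proteins carry a linear
  depth slope, sign random, magnitude uniform on [0.05, 0.2] log2/layer.
  Cortex markers (TBR1, MAP2, BCL11B) rise with depth at 0.12 log2/layer.
* **Genotype perturbations** (the planted ground truth):
  1. *GBL layer-identity shift*: at E18.5 the structural profiles of
     layers 1–4 are replaced by those of layers 15–18 — the overmigration
     phenotype in which superficial tissue carries deep-cortex identity.
  2. *Meningeal ECM drop*: LAMB1 falls by 2.5 log2 in the
     meninges-affine layers of GBL.
  3. *Model-specific intercept shifts*: three disjoint 20-protein sets
     gain +1 log2 in the cortical layers of GL, GB and GBL respectively
     (the Venn-partition ground truth for the ANCOVA screen).
  4. *Receptor-module slope inversion*: RPSA, ITGB1 and 18 partners have
     baseline slope −0.2 log2/layer; in GBL an extra +0.4 log2/layer over
     the cortex inverts the gradient.
  Perturbation targets are drawn from the well-quantified abundance range
  (base ≈ N(22.5, 0.5)); with realistic left-censoring, low-abundance
  targets would be removed by the validity filter and recovery tests would
  measure censoring instead of the planted effect.
* **Batch effects.** Additive per-(batch, protein) offsets: a batch-level
  shift (SD 0.5 for ablation batches, 0.3 for measurement batches) plus
  per-protein jitter (SD 0.15). A multiplicative component exists but is
  off by default — with 9–18 samples per batch, per-protein scale
  estimates are too unstable to plant or remove meaningfully.
* **Missingness (MNAR).** P(missing) = logistic((18.5 − x)/1.0): label-free
  MS missingness is left-censored, so the probability rises as abundance
  falls (~13% missing overall at the defaults). The noise model of the
  ablation/LC-MS chain is not published; Gaussian noise (SD 0.25) plus
  logistic censoring is this package's choice.

All randomness flows from one integer seed through a single
`numpy.random.Generator`.

## Preprocessing

* **Median normalization** subtracts each sample's median over observed
  values (idempotent; missingness untouched).
* **Batch correction** is a reference-class location adjustment, not a
  re-implementation of the hierarchical framework used in the study; the
  contract is planted-effect removal. Per protein and batch, the effect is
  the mean class-mean-centred residual over the batch's reference samples;
  estimation and subtraction are iterated to a fixed point so that
  re-estimated effects on the corrected matrix vanish even for unbalanced
  designs (a single pass leaves O(imbalance) residuals). Reference classes
  are genotype × layer-block (L1–4/L5–9 at E14.5, L1–9/L10–18 at E18.5);
  classes observed in a single batch are skipped for estimation, and a
  (protein, batch) cell with no usable values keeps effect 0. The pipeline
  corrects the ablation batch with references first, then the measurement
  batch with all samples participating. Scale adjustment is available but
  off by default (same instability argument as above). Whether the original
  study adjusted scale is not stated; location-only is this package's
  default.
* **Validity filtering** keeps proteins observed in ≥ `min_fraction` of
  the in-scope samples (count ≥ ceil(f·n), i.e. 7/10 passes 70% and 6/10
  does not). `min_fraction=1.0` reproduces the complete-case subset used
  for ordination and enrichment.

## Consensus clustering

Monti-style consensus over 250 resamples: 80% of the control samples drawn
without replacement, pairwise-complete Euclidean distances (features with
≥ 50% validity; the distance under missingness is not defined by the study
— pairwise-complete is this package's choice), Ward linkage, cut at k. The
consensus entry of a sample pair is co-clusterings over co-selections. k is
selected from the relative change of the area under the consensus CDF, with
the smallest k within 5% of the maximal relative gain winning; cluster
labels are ordered by ascending mean layer index and each layer joins the
cluster holding the majority of its replicates.

One geometric subtlety: Ward's merge cost scales with n1·n2/(n1+n2), so at
k = 2 the small outer block (10 samples at E18.5) only splits off — making
the k = 3 delta-area dominate — if its centroid distance to the meningeal
block exceeds the meninges–cortex distance by more than that size factor.
The 7.0 vs 2.5 log2 compartment effects satisfy this with ~3× margin; at
5.0 the elbow collapses onto k = 2. This is why the surface effect is the
one deliberately large constant in the generator.

## Layer signatures

Per layer L_n of one genotype/timepoint, the replicates of L_n are
contrasted against all other layers with a moderated t-test on proteins
passing 70% validity: per-protein pooled variances are shrunk toward a
common prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) obtained by
inverse-gamma moment matching of the observed variance distribution
(marginally s² ~ s₀²·F(d, d₀); the squared coefficient of variation
identifies d₀). The moderated t uses d + d₀ degrees of freedom; d₀ = 0
recovers the ordinary pooled t-test and under-dispersed variances give
d₀ = ∞ (complete shrinkage). BH-adjusted p-values are reported; raw
p < 0.05 with positive logFC gates signature candidacy, matching the
study's screening threshold.

Unique signatures apply the first-come-first-serve rule: layers are
processed superficial to deep; candidates are ordered by descending logFC
(ties: smaller p, then protein id) and the first ten not claimed by an
earlier layer are taken, so signatures are disjoint by construction and an
earlier layer keeps a shared protein. Cross-genotype layer mapping
correlates (Pearson, pairwise-complete, ≥ 3 pairs) the concatenated
signature-protein vector of each query layer — per-layer replicate means,
not replicate-level vectors, which the study leaves unstated — against
every control layer; the argmax is the assigned identity, ties resolving to
the most superficial control layer.

## Gene-set depth scores and term deconvolution

Combined-z scoring: per gene, layer means (complete-case proteins) are
z-scored across the layers of one genotype/timepoint (scores are compared
per genotype, so pooling across genotypes would leak their differences into
the reference distribution); a set of m quantified members scores
Σzᵢ/√m per layer. Zero-variance genes contribute 0 but count toward m.
Scores are screened for linear depth trends over the cortex layers
(E14.5: 5–9, E18.5: 10–18) by OLS on the layer index, kept at p < 0.05 and
R² > 0.1, and classified across timepoints by slope-sign agreement.

The GO enrichment and term condensation behind the parent-term tables
require live external databases and are consumed as precomputed input (the
generator fabricates such tables). Best Match takes the mean adjusted p
within each (genotype, layer), then the argmax of −log10 across all sites
— meaning within a site, then argmax across sites, since Best Match names a
single genotype and layer; ties resolve by genotype order CTRL < GL < GB <
GBL, then lower layer. DiffScore sums represented layer indices per
genotype, substitutes Sₙ = −n(n+1)/2 for absent genotypes (S₉ = −45,
S₁₈ = −171) and reports the range across genotypes; it is bounded by
[0, n(n+1)].

## ANCOVA screen

Per layer cluster and per contrast (CTRL vs GL/GB/GBL), each protein with
70% valid values over the contrast samples is fit casewise-complete with
the layer index as the depth covariate (the only ordered axis available).
The slope difference and its p come from the interaction term of
`abundance ~ layer × group`; the intercept difference and its p from the
group term of the additive model — the standard two-model ANCOVA scheme;
the original description names the tested quantities (slope, intercept)
but no model formula. R² is taken from the full (interaction) model,
another unstated detail resolved here.
Significance: min(p_slope, p_intercept) < 0.05 and R² > 0.1. Proteins
significant in exactly one contrast form the model-specific sets (three-way
Venn partition); annotation attaches interaction-partner and
literature-category labels from optional tables, flagging panels whose
partner fraction exceeds 40%. The export rule for downstream enrichment
(descending logFC, at most 50 proteins) is implemented; the query itself is
out of scope.

Calibration: under the screen's null model (Gaussian errors, no censoring)
the type-I rate of both tests is ~5%, verified by a 1000-protein
simulation. Under the full default conditions the intercept test runs at
~7–9%: left-censoring skews the observed error distribution, and the
two-pass batch correction leaves small within-batch shared residuals. Both
numbers are computed by the test suite; real label-free data share both
features, so nominal p-values there should be read with the same caution.

## Histomorphometry

Distances are binned into ten half-open 50 µm bins, [0,50) … [450,500],
with the last bin closed at 500 µm and larger distances kept as an explicit
overflow category (a stated 0–500 µm range leaves >500 unaddressed; in the
original data no mutant cell migrated beyond 400 µm). ROI means are compared by one-way ANOVA
with Tukey's HSD (exact studentized-range p-values, degrees of freedom from
the pooled residual); per-bin counts — counts, not proportions, another
unstated choice — by a two-factor genotype × bin ANOVA with Tukey across
genotypes within bins. Proliferation is positives per 100 µm of ventricular
margin. Re-entry fractions use a 2×2 chi-square on replicate-summed counts
with Yates' continuity correction (the default of the statistical
environment the study names), toggleable.

The cell generator draws distances from a normal truncated to [0, ROI
thickness], with genotype means set to the printed values (CTRL 171.94,
GL 182.90, GB 107.15, GBL 112.85 µm; thickness 456.83/447.38/240.92/225.12
µm) plus a per-ROI mean shift (SD 15 µm) for between-animal variability —
without it, three-replicate Tukey tests on hundreds of cells per ROI would
flag even the 11 µm CTRL–GL difference. Monte-Carlo checks compare
empirical means against the truncated distribution's analytic mean, which
differs from the configured normal mean by a few µm for the thin-cortex
genotypes.

## Problem sizes and determinism

Default problem sizes — 1000 proteins × 367 samples, 250 consensus
resamples, 1000-protein calibration simulations, ~5700 simulated cells —
were chosen so the full pipeline runs in seconds per stage on one CPU while
keeping every Monte-Carlo band narrow. All stochastic tests fix their seeds;
`scripts/acceptance.py` threads its `--seed` through every simulation it
runs.

## What passing tests do not show

The generator is additive, Gaussian and log-linear: it contains no
peptide-level structure, no correlated protein modules beyond the planted
classes, no retention-time or m/z artefacts, no inter-animal biological
variance in the proteome (only in the cell tables), and its batch effects
are purely additive. Recovery results therefore demonstrate that the
implementations are correct under the stated model, not that the pipeline's
thresholds (70% validity, p < 0.05, R² > 0.1) are optimal for real
label-free data.
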