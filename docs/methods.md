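# Methods

This note documents the statistical procedures the package implements, the
modelling choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Analysis geneset

The packaged fixture (`src/coexprofiler/data/geneset.tsv`) holds 137 unique
gene symbols in five functional categories: nuclear receptors (41), histone
demethylases (18), methyltransferases (45), coregulators (7) and
endocrine-disruptor phenotype genes (28). Category slots sum to 139: two
genes carry dual membership. We chose **Nr5a1** (SF-1; nuclear receptor and
the canonical steroidogenesis regulator) and **Nr0b1** (DAX-1; nuclear
receptor whose loss causes sex-reversal phenotypes) as the dual members —
the natural candidates for receptors that are themselves phenotype
endpoints. The `source` column distinguishes members named directly in the analyses
this package implements (`core`) from members curated from the functional
review literature (`review`). The coregulator category is
Ncoa6 (the receptor–ASCOM linker), the ASCOM structural core (Wdr5, Ash2l,
Rbbp5, Dpy30) and the corepressors Hdac2 and Ncor2. DNA methyltransferases
(Dnmt1, Dnmt3a, Dnmt3b) sit in the methyltransferase category, matching how
the source tables report them among methylation modifiers.

Symbol canonicalization is a static alias table (no live nomenclature
queries): legacy demethylase names (Utx, Jmjd3, Aof2, the Jarid/Jmjd
families) resolve case-insensitively to current Kdm symbols. Unknown
symbols pass through unchanged with a warning, so platform rows outside the
geneset are not silently altered. Resolution is idempotent.

## Expression input and probe collapse

Input matrices are assumed already RMA-normalized on the log2 scale
(normalization is upstream; no CEL parsing). The parser enforces
rectangular, numeric, duplicate-free tables and reports the exact cell of
any violation; values outside [0, 20] trigger a plausibility warning only.

Probe collapse keeps, per gene, the probe with the highest mean over the
*normal* samples — operationalized as `condition == control` within the
setting being processed, falling back (with a warning) to all samples for
settings without controls, e.g. pooled normal-only designs. Ties break on
lexicographic probe id, making the collapse deterministic and invariant to
column order. The collapse is recomputed per setting, following the
per-setting phrasing of the rule rather than a once-per-platform reading.

## Coexpression networks

For each unordered gene pair within one biological setting the sample
Pearson correlation r is tested with t = r·√(df)/√(1−r²), two-sided, df =
n−2. Edges classify as

- **strong**: |r| ≥ 0.75 and p < 0.05 (both bounds exactly as stated; the
  p bound is strict — a pair at p = 0.05 is only approaching);
- **approaching**: |r| ≥ 0.75 and 0.05 ≤ p < 0.10;
- **absent** otherwise.

|r| = 1 (within 1e−12, snapped) returns p = 0 exactly. Pairs with zero
variance are dropped and logged rather than imputed at r = 0, because
silent zeros would corrupt downstream conservation counts.

Settings whose samples are grouped (pooled cell types, generations, time
points) use partial correlation: the categorical grouping is removed as
fixed group means from both genes, and the residuals are correlated with
df = n − 2 − (k−1) for k group levels. This equals partialling out k−1
indicator covariates with an intercept; for a single categorical covariate
it also coincides with the precision-matrix formulation, so nothing hinges
on that choice. With one group level the procedure reduces exactly to plain
Pearson (verified to 1e−12 in tests).

The analytic null rate used for calibration: under ρ = 0 the strong call
requires |r| above max(0.75, r_α), where r_α is the |r| at which the
two-sided p equals α; at n = 12 the 0.75 bound binds and
P(strong | null) ≈ 0.0050.

## Conservation across settings

A relationship is conserved when the same pair is strong *with the same
sign* in at least `min_settings` settings — the minimal faithful reading of
"similar strength and direction", since no numeric similarity band on r is
defined beyond the threshold. Approaching edges never count toward
conservation. Pairs strong with opposite signs in different settings are
excluded and reported separately as sign-discordant. Occurrence counts (the
hub measure) sum a gene's strong edges over settings, so the column total
equals twice the strong-edge count. Cross-species comparison relies on
shared canonical symbols; no ortholog mapping is attempted.

## Gatekeeper concordance

The gatekeeper set is {Esr2, Ehmt2, Ehmt1, Kdm1, Prdm2, Setdb1}. A
phenotype gene's profile records its correlation and significance class
against every gatekeeper member present, plus a receptor link — the best
class over {Esr1, Esr2, Ar} (restricted to platform availability). The
concordance classes are mutually exclusive and exhaustive:

- **full** — receptor link strong and every gatekeeper *modifier* (the
  non-receptor members) strong;
- **approaching** — receptor link at least approaching and every modifier
  at least approaching;
- **none** — otherwise.

Pattern agreement is judged on significance class, not sign: the observed
consistent patterns mix correlation and anti-correlation. The signed
pattern vector is reported so users can impose a stricter sign criterion;
the class rule here is a minimal operationalization of a concept that has
no numeric definition in the source analysis.

## Moderated-t differential expression

Implemented from the formulas (no external DE package). Per gene, the
two-group model gives log2fc (exposed − control mean), pooled residual
variance s²_g and df d_g = n−2. Gene variances are modelled as scaled
inverse-χ² draws with hyperparameters (d₀, s₀²); equivalently
d_g·s²_g/(d₀·s₀²) is F(d_g, d₀). The hyperparameters are estimated by
matching the first two moments of e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the excess of var(e) over the sampling term ψ′(d_g/2) determines d₀ through
a Newton inversion of the trigamma function, and the mean determines s₀².
When the observed spread is no larger than the sampling term — including
exactly equal variances — d₀ = +∞ and s₀² is the common variance
(total shrinkage). Zero-variance genes are excluded from the fit; with
fewer than two usable genes the fit falls back to d₀ = +∞ so degenerate
inputs cannot crash the pipeline.

The moderated statistic uses s²_post = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g) in
place of s²_g, with df d_g + d₀ and the design factor √(1/n₁ + 1/n₂) in the
standard error. d₀ = 0 reproduces the ordinary two-sample t exactly
(machine precision in tests); d₀ = ∞ tests every gene against s₀² with a
normal reference. The whole pipeline (hyperparameters, t, p, BH) matches
Bioconductor limma to ~1e−8 on a fixture, with limma used only as the
independent oracle.

Benjamini–Hochberg is the step-up rule adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j capped
at 1, returned in input order; it is permutation-invariant and matches
statsmodels in tests. The reporting filter keeps fold change ≥ 1.5 (fold
change is 2^|log2fc| with an up/down flag, since the source tables print
positive fold changes for down-regulated genes) and adjusted p < 0.05;
statistically significant genes with fold change in [0.93·1.5, 1.5) are
listed as near misses — the band is set to capture a 1.4-fold significant
gene sitting just under the cut-off. Multi-factor designs are out of scope:
a generation-stratified analysis is run as separate two-group contrasts per
generation, and the grouped analysis as one 6v6 contrast without a
generation covariate; both routes are available and the per-generation
route is the stratified alternative.

## Synthetic data

The generator emulates RMA-scale log2 matrices at the study's sample sizes
(4–12 samples per condition):

    x_gs = μ_g + β_g·exposed_s + γ_{g,subgroup(s)} + λ_g·f_{m(g),s} + ε_gs

with per-module standard-normal factors f, gene loadings
|λ| = σ·√(ρ/(1−ρ)) (sign per gene, so a pair's expected correlation sign is
the product of its loading signs), residual ε ~ N(0, σ²) and baselines
μ_g ~ Uniform(6, 12). The latent-factor construction was chosen over
sampling a full covariance matrix because module membership, signs and
exposure-dependent rewiring stay specifiable gene-by-gene and the implied
covariance is positive-definite by construction. Defaults: σ = 0.5 log2
units (typical RMA residual spread), ρ = 0.9 for planted modules, subgroup
offsets γ ~ N(0, 1) when generation/cell-pool structure is enabled.
Everything is deterministic given the seed.

Three shipped scenarios mirror the study designs: `experiment1` (three
normal-only species settings of 8/12/12 samples sharing modules),
`experiment2` (three generations × (2 control + 2 exposed), rewired modules
under exposure, planted down-regulation) and `experiment6` (4 controls plus
six exposure groups of 4, with the planted module surviving only in one
high-dose group).

What passing tests show: the thresholded-correlation rule recovers planted
modules at the stated operating point (mean sensitivity ≈ 0.95 at ρ = 0.9,
n = 12), its null calibration matches the analytic tail, partial
correlation removes subgroup-driven spurious edges that inflate plain
Pearson, and the DE stack is correctly calibrated and recovers planted
effects. What they do not show: robustness to real-data features the
generator omits — probe-level effects, heavy-tailed or outlying intensities,
correlated noise across genes outside modules, batch effects beyond a
single categorical subgroup, or annotation/probe-mapping error. Conclusions
about real arrays therefore rest on the correctness of the procedures, not
on these recovery rates.

## Numerical choices

- Correlations are clipped to [−1, 1]; values within 1e−12 of ±1 snap to ±1
  with p = 0.
- Probe-collapse and edge ordering ties break lexicographically; all
  outputs are deterministically ordered, so identical inputs and config
  give byte-identical tables (the run log additionally records paths).
- The trigamma inversion runs Newton from the asymptotic start 0.5 + 1/x to
  relative tolerance 1e−10, with closed-form limits for extreme arguments.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; scenario builders derive per-setting seeds by
  small offsets.

## Problem sizes in the checks

The calibration and recovery checks run at sizes chosen to keep the whole
suite fast while leaving Monte-Carlo error well below the tested margins:
200 settings × 50 genes for null calibration, 100 seeds for module
recovery, 20 × 2000 genes for hyperparameter recovery, 50 × 1000 genes for
the global-null error rate, and 25 replicate experiments for fold-change
recovery in the acceptance script.

## Known limitations

- Conservation requires exact symbol identity across settings; platform
  coverage differences show up as absent genes, not as partial evidence.
- The "approaching" band (0.05 ≤ p < 0.10) is reported but never feeds
  conservation counts; users wanting a softer meta-analysis need to relax
  `Thresholds` explicitly.
- The concordance classes condense a pattern into three tiers; borderline
  profiles (e.g. one modifier at p = 0.051) fall to the lower tier by
  design.
- The moderated-t implementation covers two-group contrasts only.
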