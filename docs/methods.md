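# Methods

`photoadapt` chains three layers of analysis that are usually scattered
across separate tools: leaf-level photosynthesis model fitting,
quantitative-genetic mixed modelling on replicated field designs, and
population-genetic inference of local adaptation in a structured,
selfing diversity panel. A synthetic-data generator with full ground
truth stands in for the field and glasshouse experiments, so every
stage is testable end to end without any external download.

## Photosynthesis models

### FvCB A–Ci fitting (`photofit`)

Net assimilation follows the Farquhar–von Caemmerer–Berry model at
saturating light (J = Jmax, matching a 1800 µmol m⁻² s⁻¹ PAR
protocol):

    Ac = Vcmax (Ci − Γ*) / (Ci + Kc(1 + O/Ko))
    Aj = Jmax  (Ci − Γ*) / (4Ci + 8Γ*)
    Ap = 3·TPU
    A  = min(Ac, Aj, Ap) − Rd

One numerical subtlety: the limiting branch is selected on the
*carboxylation* rates Wc = Vcmax·Ci/(Ci+Km) and Wj = J·Ci/(4Ci+8Γ*),
with gross assimilation (1 − Γ*/Ci)·min(Wc, Wj). Above the
compensation point Γ* this is identical to min(Ac, Aj); below Γ* the
naive minimum of the *net* expressions would flip to the
RuBP-regeneration branch merely because it is more negative there,
which breaks the contiguity in Ci that the bilinear fit (and the
physics) assumes. The protocol's lowest setpoint (50 µmol mol⁻¹
reference CO₂, Ci ≈ 35 at the default Ci/Ca of 0.7) sits below
Γ* = 42.75, so this case occurs on every curve.

The inverse problem uses the bilinear method: every admissible
assignment of the sorted observations to an Ac segment (≥3 points) and
an Aj segment (≥2 points) is scored by a joint bounded linear least
squares on the two linearising transforms with a shared Rd (all
parameters constrained non-negative), and the assignment with minimum
SSE wins. Repeated setpoints (the protocol logs 400 µmol mol⁻¹ three
times as a stability check) are retained as observations but never
split across segments. A TPU segment is considered only when the
two-segment fit systematically overshoots the top of the curve — both
highest-Ci residuals negative with a mean shortfall above one noise SD,
or a single undershoot beyond one noise SD — and a three-segment
assignment (≥2 TPU points) is accepted only if it improves the SSE by
more than the noise variance. This guard holds the spurious-TPU rate
near 3% at the default noise level while recovering a genuine plateau
exactly on clean data. When the plateau caps most of the high-CO₂
points, Jmax rests on few observations and is correspondingly less
certain — the same identifiability limit any A–Ci tool faces.

Kinetic constants default to the Bernacchi 25 °C values on a Ci basis
(Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, Γ* = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹); no temperature scaling and no mesophyll
conductance. Rd is fitted jointly (lower-bounded at zero) because the
instrument protocol gives no independent respiration measurement.

Stomatal limitation compares the operating assimilation with the
fitted model's prediction at Ci = Ca (infinite conductance):
SL = (A(Ca) − A_op)/A(Ca).

### Light response and NPQ kinetics (`photofit`, `npqkinetics`)

A–Q curves use the non-rectangular hyperbola
A(Q) = [φQ + As − √((φQ+As)² − 4θφQAs)]/(2θ) − R_L, fitted by
multi-start nonlinear least squares over θ ∈ {0.3, 0.6, 0.9} with φ
bounded by its theoretical maximum of 0.125 mol CO₂ mol⁻¹ photons
(fits pinned at the bound are flagged rather than silently accepted).

Fluorescence traces (actinic light on for 600 s, off for 800 s) are
converted to NPQ(t) = Fm/Fm′ − 1 and ΦPSII(t) = (Fm′ − Fs)/Fm′. The
light phase is summarised by the least-squares slope over the first
60 s (the protocol does not fix this window; it is a configurable
default) plus a no-offset saturating exponential
NPQ = A·(1 − e^(−kt)); the dark phase by NPQ = A·e^(−kt′) + c and
ΦPSII = c + A·(1 − e^(−kt′)) with t′ re-zeroed at light-off. Rates are
multi-started over {0.001, 0.01, 0.1} s⁻¹. "Final" NPQ and ΦPSII are
read at the last pulse of the light phase. Degenerate inputs (flat
traces) flag the exponential parameters as missing while the linear
slope remains defined.

## Mixed models and heritability (`quantgen`, `mixedmodel`)

Plot values from the two-year alpha-lattice trials are modelled as

    y = genotype + replicate + block(replicate) + column + β·DPH + ε

with design terms random, days-post-heading (DPH) a fixed covariate,
and genotype either random (BLUPs, genotypic variance σg²,
prediction error variance) or fixed (BLUEs by GLS, reported as
deviations from the estimated population mean at the average DPH).
Joint-year models add a fixed year effect and year interactions with
genotype and every design term (year fixed, interactions random — the
convention here; configurable). Genotype random → BLUP and genotype
fixed → BLUE is the standard convention and the one implemented.

REML is computed by profiling out the residual variance and optimising
the variance *ratios* γᵢ = σᵢ²/σε² with bounded quasi-Newton; negative
components are handled by the γ ≥ 0 boundary. Each objective
evaluation works in the q-dimensional random-effect space via the
Woodbury identity (q = total random levels, typically half the plot
count), so a 600-plot, four-component fit takes well under a second.
BLUPs, the full PEV matrix and GLS fixed effects come from the fitted
ratios by direct dense algebra.

Heritability uses the two printed mean-PEV formulas

    H²_PM     = 1 − PEV̄ / σg²
    H²_Cullis = 1 − PEV̄ / (2σg²)

where PEV̄ is the mean prediction-error variance of a *difference*
between two genotypes' BLUPs (the quantity the reference mixed-model
packages report as the mean variance of a BLUP contrast). With that
reading, the Cullis formula equals the line-mean heritability in a
balanced design — the property the recovery tests assert — while
per-genotype PEVs remain available separately. σg² = 0 renders both
undefined (reported missing); values below zero are reported unclamped
with a flag.

Phenotypic plasticity per accession is exactly
(PopMean₂₀₂₁ + BLUE₂₀₂₁) − (PopMean₂₀₂₂ + BLUE₂₀₂₂), where the
population mean is the year model's estimated grand mean — the model
intercept plus the mean fixed-covariate contribution, since the
formula's source leaves "population mean" undefined.

Comparisons: Pearson correlations on pairwise-complete observations
with p from the exact t transform; one-way ANOVA with Tukey HSD
p-values from the studentized-range distribution and an
insert-and-absorb compact letter display; and for the two-treatment
watering experiment, a nested two-way ANOVA
(treatment × subpopulation + genotype within subpopulation and its
treatment interaction) with configured traits log-transformed first,
percent change (mean₈₀ − mean₄₀)/mean₈₀ × 100 computed on the original
scale, and Shapiro/median-Levene screens that are reported but never
acted on automatically.

## Population genetics (`popgen`)

The panel is fully selfing, so genotypes are single 0/1 codes; an
accession's codes double as degenerate allele frequencies.

* **Distances and trees.** Nei's standard distance
  D = −ln(Jxy/√(JxJy)) with J terms averaged over biallelic loci;
  identical-by-state zero overlap (Jxy = 0) is capped at a
  configurable 10. Neighbour joining is the Saitou–Nei agglomeration
  with the standard Q criterion and a lowest-index tie-break, so the
  topology is deterministic; bootstrap support is the fraction of
  locus-resampled replicate trees containing each internal
  bipartition (100 replicates by default — the replicate count is not
  fixed by any protocol).
* **Admixture.** A deliberately simple latent-factor estimator:
  mean-impute, seed Q from k-means on the top-K principal components,
  then alternate constrained least squares (cluster frequencies
  clipped to [0,1], Q rows projected to the simplex) to convergence.
  K is chosen by the largest relative eigenvalue gap among the top 15
  eigenvalues of the genotype covariance (K − 1 structure axes →
  gap index + 1). This is a documented simplification of the full
  constrained factor-analysis estimators; on Balding–Nichols panels at
  the study's FST it recovers labels essentially perfectly, which is
  all the downstream stages require. An accession is assigned to a
  cluster only when its proportion strictly exceeds 0.5, else labelled
  admixed.
* **Coancestry and the S statistic.** Subpopulation coancestry is the
  moment estimator θ_AB = mean over polymorphic loci of
  (p_A − p̄)(p_B − p̄)/(p̄(1 − p̄)), eigenvalue-clipped to the nearest
  PSD matrix. Because deviations from the across-subpop mean sum to
  zero, **1** is exactly in the null space of θ; the selection test
  therefore measures divergence in the contrast space, where the
  centering choice is immaterial (the weighted grand mean is used when
  defined, the plain mean otherwise). The drift null takes
  subpopulation mean additive values m ~ MVN(µ1, 2σ_A²θ); the observed
  pseudoinverse Mahalanobis divergence is compared with Monte-Carlo
  null draws and S is the fraction of draws with smaller divergence —
  S ≈ 0.5 under drift, → 1 under divergent and → 0 under stabilising
  selection. The null sample size defaults to the retained-draw count
  of the reference MCMC protocol, (15000 − 5000)/2 = 5000, computed by
  the `mcmc_retention` helper for protocol parity. Genotype BLUPs act
  directly as additive values with σ_A² = σg², reflecting the
  assumption of unrelated, fully inbred lines. S is a plug-in
  Monte-Carlo statistic, not a posterior integral: its calibration
  properties (neutral mean ≈ 0.5, power against ±5σ_A perturbations)
  are what the tests assert, not numerical identity with any published
  S value.

## GWAS and follow-up (`gwas`)

A single-marker mixed linear model stands in for multi-locus scans
(explicitly out of scope): y = PCs·β + u + ε with var(u) = σu²K, three
principal components of the scaled genotype matrix and a VanRaden
kinship built on 0/2 dosages (diagonal ≈ 1 + F ≈ 2 for selfing lines).
The null variance ratio is estimated once by exact 1-parameter REML on
the kinship eigenbasis and reused for every SNP (the standard
population-parameters-previously-determined shortcut); per-SNP Wald
tests then reduce to weighted least squares on the rotated data,
vectorised across all SNPs. Missing genotypes are mean-imputed — for
the tested dosage this is equivalent to zero-weighting the missing
entries under the centered coding. Significance is Bonferroni
α/n_snps; high-confidence QTL are the intersection of the BLUE-based
and BLUP-based significant sets; follow-up joins per-subpopulation
allele frequencies with the trait's subpopulation ANOVA/Tukey
groupings; and the gene screen reports any gene overlapping
±100 kb of a QTL (1-based inclusive coordinates, strand ignored,
any-overlap rule), with distance 0 inside a gene and the gap to the
nearest edge otherwise.

Because the scan is single-marker, discovered QTL counts are not
comparable to multi-locus results; the calibration claims are the
family-wise error under a structured null and the power for a
25%-variance marker.

## Synthetic data (`synthdata`)

The generator's defaults mirror the study conditions: 8 subpopulations
under a Balding–Nichols F-model (ancestral frequencies
Uniform(0.05, 0.95), subpop frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at
F = 0.15), fully homozygous 0/1 lines, admixed accessions drawing each
locus from a flat-Dirichlet ancestry row; 320 accessions in year 1
(8 blocks × 40 plots × 2 replicates) and 270 carried into year 2
(6 blocks × 45 plots × 2 replicates). The published region counts
(71+37+41+8+29+48+19+33) exceed the panel size once the 69 admixed
accessions are added, so the default subpopulation sizes scale those
counts proportionally to 251 assigned + 69 admixed = 320, which fills
the year-1 lattice exactly.

Plot values are built from genotype effects (causal SNPs plus a
polygenic term, rescaled so the genetic SD is exact), year shift,
optional G×E, random replicate/block/column effects and a linear DPH
term. The configured heritability is the **line-mean (entry-mean over
the two replicates)** heritability σg²/(σg² + σε²/2); the residual SD
is solved from it. This is the definition under which the one-way
ANOVA estimator and the Cullis recovery tests are mutually consistent.

Gas-exchange curves evaluate the forward models at the protocol's 11
CO₂ setpoints (Ci = 0.7 × setpoint — a typical C₃ operating ratio,
used because the protocol fixes reference CO₂, not Ci) and 6 light
steps, plus Gaussian noise (default SD 0.5 µmol m⁻² s⁻¹).
Fluorescence traces emit pulses every 20 s (the imaging protocol's
pulse interval is not documented; 20 s is a free parameter) over
0–1400 s with the phase boundary at 600 s; noise is applied on the
NPQ/ΦPSII scale and converted back to Fm′/Fs, so derived series
round-trip exactly. Per-accession physiological parameters vary
lognormally (CV 0.12) around field-plausible centres (Vcmax 60,
Jmax 120, TPU 10, Rd 1.5 µmol m⁻² s⁻¹; φ 0.06, As 28, θ 0.7, R_L 1.0;
NPQ amplitude 2, induction rate 0.01 s⁻¹, relaxation rate 0.005 s⁻¹).

What the generator does **not** emulate: linkage disequilibrium,
geographic coordinates or climate covariates, spatial field trends
beyond the block/column structure, instrument drift, or correlated
trait architectures. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated generative
model — not that field data meet those assumptions.

## Problem sizes and numerical choices

Default test/acceptance problem sizes are chosen so the whole suite
runs on a single CPU in a few minutes while keeping every estimator in
its asymptotically informative regime: 2 000–5 000 SNPs, panels of
100–355 accessions, 300-accession × 2-replicate trials for
heritability recovery (20 seeds per level), 500 Monte-Carlo replicates
for the selection-test calibration, 50 traits/seeds for the GWAS
error-rate and power checks. REML convergence is declared at a 1e-8
relative objective tolerance; variance ratios below 1e-8 collapse to
the boundary; the admixture ALS stops at a 1e-6 relative change in
reconstruction error; pseudoinverse cutoffs are 1e-10 relative.

## Known limitations

* No temperature response of the FvCB constants; all fits assume 25 °C.
* The bilinear fit assumes saturating light (J = Jmax) on A–Ci curves.
* The joint-year REML treats year as fixed; crossed spatial
  (row × column autoregressive) structure is not modelled.
* The S statistic is a plug-in calibration of the drift null, not a
  Bayesian posterior probability.
* The single-marker GWAS deliberately omits multi-locus conditioning
  and LD clumping, so hit lists are conservative under polygenic
  architectures.
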