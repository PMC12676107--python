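# photoadapt

Photophysiology phenomics and local-adaptation genetics for
structured, selfing diversity panels — built for studies like a wild
barley (*Hordeum spontaneum*) common-garden experiment, where hundreds
of accessions from geographically distinct subpopulations are
phenotyped for photosynthesis across years and then screened for
signatures of selection and marker–trait associations.

The package chains, as tested and reusable Python:

1. **Leaf-level model fitting** — FvCB A–Ci curves (Vcmax, Jmax, TPU,
   Rd via the bilinear transition-point method), non-rectangular
   hyperbola light-response curves (ΦCO₂max, Asat, θ, R_L), stomatal
   limitation, and NPQ/ΦPSII induction–relaxation kinetics from
   pulse-amplitude fluorescence traces.
2. **Quantitative genetics** — REML mixed models on two-year
   alpha-lattice designs (genotype random → BLUPs, fixed → BLUEs),
   PEV-based broad-sense heritability (Cullis and Piepho–Möhring),
   between-year plasticity, correlations, ANOVA + Tukey letter
   displays, and the nested two-way ANOVA of a targeted watering
   experiment with percent-change summaries.
3. **Population genetics** — Nei-distance neighbour-joining trees with
   bootstrap support, a latent-factor admixture estimator with the
   >50% assignment rule, moment-based subpopulation coancestry, a
   Monte-Carlo drift-null selection test (the S statistic: ≈0.5 drift,
   ≈1 divergent, ≈0 stabilising selection), and a kinship-corrected
   single-marker GWAS with Bonferroni thresholds, BLUE∧BLUP
   high-confidence QTL, allele-frequency follow-up and ±100 kb
   gene-window queries.
4. **Synthetic data** — a Balding–Nichols genotype and alpha-lattice
   trial generator with full ground truth (ancestry, causal SNPs,
   curve parameters), so every downstream stage is testable without
   any external data.

The core quantities, in the field's notation: for C₃ photosynthesis
A = min(Ac, Aj, Ap) − Rd with Ac = Vcmax(Ci−Γ*)/(Ci+Kc(1+O/Ko)) and
Aj = J(Ci−Γ*)/(4Ci+8Γ*); NPQ = Fm/Fm′ − 1 and ΦPSII = (Fm′−Fs)/Fm′;
heritability H²_PM = 1 − PEV̄/σg² and H²_Cullis = 1 − PEV̄/(2σg²);
plasticity = (PopMean₂₀₂₁ + BLUE₂₀₂₁) − (PopMean₂₀₂₂ + BLUE₂₀₂₂).
See `docs/methods.md` for the full model descriptions, defaults and
design choices.

## Worked example

Simulate a structured panel, fit a curve, estimate heritability and
test for selection:

```python
from photoadapt.synthdata import SimConfig, DesignSpec, \
    simulate_genotypes, simulate_trial, simulate_aci_curve
from photoadapt.photofit import fit_aci
from photoadapt.quantgen import fit_mixed, heritability
from photoadapt.popgen import estimate_admixture, assign_subpops, \
    coancestry, selection_S

cfg = SimConfig(seed=42, n_subpops=3, accessions_per_subpop=(40, 40, 40),
                n_admixed=20, n_snps=2000, fst=0.15,
                trait_heritabilities={"Asat": 0.6},
                trait_means={"Asat": 21.0}, trait_genetic_sd={"Asat": 2.5},
                design_year1=DesignSpec(7, 20, 2),
                design_year2=DesignSpec(7, 20, 2))
gm, truth = simulate_genotypes(cfg)
plots = simulate_trial(gm, truth, cfg)

acc = gm.accessions[0]
fit = fit_aci(simulate_aci_curve(truth.true_curve_params[acc]["aci"], cfg))
print(f"{acc}: Vcmax={fit.estimates.vcmax:.1f}, "
      f"Jmax={fit.estimates.jmax:.1f}, Rd={fit.estimates.rd:.2f}")

mm = fit_mixed(plots[plots.year == 2021], "Asat", model="year2021")
h2 = heritability(mm)
print(f"sigma2_g={mm.sigma2_g:.2f}, Cullis H2={h2.h2_cullis:.2f}, "
      f"Piepho-Mohring H2={h2.h2_pm:.2f}")

q = estimate_admixture(gm, 3, seed=0)
labels = assign_subpops(q)
theta = coancestry(gm, labels)
means = [mm.blups[labels == sp].mean() for sp in theta.subpops]
s = selection_S(means, mm.sigma2_g, theta, n_draws=5000, seed=1)
print(f"S(Asat) = {s.s:.2f} with {s.n_draws} null draws")
```

prints

```
B1K-0001: Vcmax=64.3, Jmax=112.1, Rd=1.18
sigma2_g=4.86, Cullis H2=0.55, Piepho-Mohring H2=0.10
S(Asat) = 0.10 with 5000 null draws
```

Reading the output: the fitted Vcmax of 64.3 µmol m⁻² s⁻¹ sits within
a few percent of this accession's true value (66.5) from one noisy
11-point curve. The single-year Cullis heritability (0.55) tracks the
configured line-mean value of 0.6; the Piepho–Möhring number is always
lower by construction. The selection statistic near 0.1 says the BLUP
divergence between the three ancestry clusters is *smaller* than
typical drift at this coancestry — shrinkage toward the mean makes
BLUP-based subpop contrasts conservative, exactly the behaviour the
calibration tests quantify.

The same pipeline runs from the shell, driven by a YAML config:

```bash
photoadapt run --config config.yaml     # simulate → … → gwas
photoadapt structure --outdir myrun     # rerun one stage from disk
photoadapt retention                    # MCMC retained-draw helper
```

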