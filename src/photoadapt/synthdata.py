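"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study system: a structured selfing wild-barley panel of
8 geographic subpopulations (Balding–Nichols allele-frequency model
with admixed individuals), two-year alpha-lattice field trials
(8 blocks × 40 plots in year 1, 6 blocks × 45 plots in year 2, two
replicates), A–Ci curves at the 11 reference-CO2 setpoints of the
measurement protocol, mini light-response curves at its 6 light steps,
and NPQ/ΦPSII fluorescence traces for a 600 s actinic-on / 800 s
actinic-off schedule.

One global seed fans out to per-component child seeds via
``numpy.random.SeedSequence``, so a configuration is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photofit import FvCBParams, fvcb_forward, nrh_forward
from .popgen import CHROMOSOMES, MISSING, ADMIXED_LABEL, GenotypeMatrix

__all__ = [
    "SimConfig",
    "DesignSpec",
    "SyntheticTruth",
    "AqParams",
    "NpqTraceParams",
    "CO2_SETPOINTS",
    "LIGHT_STEPS",
    "simulate_genotypes",
    "simulate_trial",
    "simulate_aci_curve",
    "simulate_aq_curve",
    "simulate_npq_trace",
]

#: Reference-CO2 setpoints of the A–Ci protocol, in measurement order
#: (µmol mol⁻¹); the 400 level is revisited twice for stability checks.
CO2_SETPOINTS = (400, 300, 200, 100, 50, 400, 400, 700, 1000, 1300, 1800)

#: PAR steps of the mini light-response protocol (µmol m⁻² s⁻¹).
LIGHT_STEPS = (1800, 1100, 500, 300, 150, 50)

#: Actinic schedule of the fluorescence protocol (s).
ACTINIC_ON_S = 600.0
DARK_PHASE_S = 800.0

#: Default subpopulation sizes: the study's eight region counts scaled
#: proportionally so that assigned (251) + admixed (69) fills the
#: 320-plot year-1 lattice exactly.
DEFAULT_SUBPOP_SIZES = (62, 33, 36, 7, 26, 42, 17, 28)


@dataclass(frozen=True)
class DesignSpec:
    """One year's alpha-lattice dimensions (per replicate)."""

    n_blocks: int
    plots_per_block: int
    n_reps: int = 2

    @property
    def n_plots(self) -> int:
        return self.n_blocks * self.plots_per_block


@dataclass
class SimConfig:
    seed: int = 0
    n_subpops: int = 8
    accessions_per_subpop: tuple = DEFAULT_SUBPOP_SIZES
    n_admixed: int = 69
    n_snps: int = 5000
    fst: float = 0.15
    missing_rate: float = 0.0
    n_causal: int = 5
    trait_heritabilities: dict = field(default_factory=lambda: {
        "Asat": 0.34, "gs": 0.29, "SLA": 0.44, "DTH": 0.28,
    })
    trait_means: dict = field(default_factory=lambda: {
        "Asat": 21.0, "gs": 0.35, "SLA": 300.0, "DTH": 60.0,
    })
    trait_genetic_sd: dict = field(default_factory=lambda: {
        "Asat": 2.5, "gs": 0.08, "SLA": 40.0, "DTH": 5.0,
    })
    gxe_sd: float = 0.0  # trait units, on the genetic-SD scale fraction
    year2_shift_frac: float = -0.15  # year-2 mean shift in genetic SDs
    design_year1: DesignSpec = field(default_factory=lambda: DesignSpec(8, 40, 2))
    design_year2: DesignSpec = field(default_factory=lambda: DesignSpec(6, 45, 2))
    rep_sd_frac: float = 0.1  # design-effect SDs as fractions of genetic SD
    block_sd_frac: float = 0.2
    column_sd_frac: float = 0.1
    dph_beta_frac: float = 0.02  # per day, in genetic SDs
    admix_concentration: float = 1.0  # Dirichlet concentration for true Q
    # gas exchange / fluorescence
    ci_over_ca: float = 0.7
    ci_noise_sd: float = 0.0  # µmol mol⁻¹
    noise_sd_gasex: float = 0.5  # µmol m⁻² s⁻¹
    noise_sd_npq: float = 0.05  # NPQ units
    pulse_interval_s: float = 20.0
    curve_param_cv: float = 0.12  # between-accession lognormal CV

    def __post_init__(self) -> None:
        if self.n_subpops < 2:
            raise ValueError("need at least K = 2 subpopulations")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if self.n_subpops > len(self.accessions_per_subpop):
            raise ValueError("K exceeds the number of subpop sizes given")
        for tr, h2 in self.trait_heritabilities.items():
            if not (0.0 <= h2 <= 1.0):
                raise ValueError(f"heritability for {tr} outside [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_accessions(self) -> int:
        return int(sum(self.accessions_per_subpop[: self.n_subpops])) + self.n_admixed

    def child_rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component generator fanned out from ``seed``."""
        name_entropy = int.from_bytes(component.encode(), "little") % (2 ** 32)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(name_entropy,)))


@dataclass
class AqParams:
    phi: float = 0.06
    asat_gross: float = 28.0
    theta: float = 0.7
    r_l: float = 1.0


@dataclass
class NpqTraceParams:
    fm_dark: float = 3000.0
    f0_dark: float = 600.0
    ind_amp: float = 2.0
    ind_rate: float = 0.01
    rel_rate: float = 0.005
    rel_res_frac: float = 0.3  # residual NPQ as a fraction of end-of-light NPQ
    phi_end: float = 0.25  # end-of-light ΦPSII
    phi_rate: float = 0.02  # light-phase ΦPSII decay rate, s⁻¹
    rec_amp: float = 0.45
    rec_rate: float = 0.003

    @property
    def fv_fm(self) -> float:
        return (self.fm_dark - self.f0_dark) / self.fm_dark


@dataclass
class SyntheticTruth:
    true_q: np.ndarray  # accessions × K, simplex rows
    true_subpop: pd.Series  # label per accession ("subpop1"… / "admixed")
    causal_snps: list  # (snp index, trait, effect size)
    true_genotype_values: pd.DataFrame  # accession × trait
    true_curve_params: dict  # accession → {"aci": FvCBParams, "aq": …, "npq": …}
    ancestral_freq: np.ndarray = None
    subpop_freq: np.ndarray = None  # K × n_snps

    def __post_init__(self) -> None:
        if np.any(np.abs(self.true_q.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("true Q rows must sum to 1")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Balding–Nichols genotypes for a selfing panel, plus ground truth.

    Ancestral frequencies are Uniform(0.05, 0.95); subpopulation
    frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F = ``cfg.fst``.
    Non-admixed accessions draw homozygous 0/1 alleles from their
    subpopulation's frequencies; admixed accessions draw each locus
    from a subpopulation sampled from a flat-Dirichlet Q row.  Ground
    truth (Q, labels, causal effects, genotype trait values, per-leaf
    curve parameters) is returned alongside.
    """
    k = cfg.n_subpops
    sizes = list(cfg.accessions_per_subpop[:k])
    rng = cfg.child_rng("genotypes")

    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    f = cfg.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    p_sub = rng.beta(a, b, size=(k, cfg.n_snps))

    n_assigned = sum(sizes)
    n = n_assigned + cfg.n_admixed
    q = np.zeros((n, k))
    subpop_idx = np.repeat(np.arange(k), sizes)
    q[np.arange(n_assigned), subpop_idx] = 1.0
    labels = [f"subpop{i + 1}" for i in subpop_idx] + [ADMIXED_LABEL] * cfg.n_admixed
    if cfg.n_admixed:
        q[n_assigned:] = rng.dirichlet(
            np.full(k, cfg.admix_concentration), size=cfg.n_admixed)

    codes = np.empty((n, cfg.n_snps), dtype=np.int8)
    for i in range(n_assigned):
        codes[i] = rng.random(cfg.n_snps) < p_sub[subpop_idx[i]]
    for i in range(n_assigned, n):
        origin = np.array([rng.choice(k, size=cfg.n_snps, p=q[i])]).ravel()
        codes[i] = rng.random(cfg.n_snps) < p_sub[origin, np.arange(cfg.n_snps)]

    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING

    # map: SNPs spread over 7 chromosomes, sorted 1-based positions
    chrom_of = np.sort(rng.integers(0, len(CHROMOSOMES), size=cfg.n_snps))
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    for c in range(len(CHROMOSOMES)):
        sel = chrom_of == c
        k_c = int(sel.sum())
        draws = rng.integers(1, 600_000_001, size=k_c)
        while len(np.unique(draws)) < k_c:  # collisions are vanishingly rare
            draws = np.unique(draws)
            draws = np.concatenate(
                [draws, rng.integers(1, 600_000_001, size=k_c - len(draws))])
        pos[sel] = np.sort(draws)
    chrom = np.array([CHROMOSOMES[c] for c in chrom_of])

    accessions = [f"B1K-{i + 1:04d}" for i in range(n)]
    snp_ids = [f"{chrom[j]}_{pos[j]}" for j in range(cfg.n_snps)]
    gm = GenotypeMatrix(codes=codes, accessions=accessions, snp_ids=snp_ids,
                        chrom=chrom, pos=pos)

    truth = SyntheticTruth(
        true_q=q,
        true_subpop=pd.Series(labels, index=accessions, name="subpop"),
        causal_snps=[],
        true_genotype_values=_genotype_values(gm, cfg),
        true_curve_params=_curve_params(accessions, cfg),
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
    )
    truth.causal_snps = truth.true_genotype_values.attrs.get("causal_snps", [])
    return gm, truth


def _genotype_values(gm: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """True genotypic trait values: causal-SNP effects plus a polygenic
    term, rescaled to the configured genetic SD exactly."""
    rng = cfg.child_rng("genetics")
    g = gm.imputed()
    gc = g - g.mean(axis=0)
    values = {}
    causal_all = []
    for trait in cfg.trait_heritabilities:
        sd_target = cfg.trait_genetic_sd.get(trait, 1.0)
        if cfg.trait_heritabilities[trait] == 0.0 or sd_target == 0.0:
            values[trait] = np.zeros(gm.n_accessions)
            continue
        idx = rng.choice(gm.n_snps, size=min(cfg.n_causal, gm.n_snps),
                         replace=False)
        beta = rng.standard_normal(len(idx))
        raw = gc[:, idx] @ beta + 0.5 * rng.standard_normal(gm.n_accessions)
        sd = raw.std(ddof=0)
        scale = sd_target / sd if sd > 0 else 0.0
        values[trait] = raw * scale
        causal_all.extend((int(j), trait, float(b * scale))
                          for j, b in zip(idx, beta))
    df = pd.DataFrame(values, index=gm.accessions)
    df.attrs["causal_snps"] = causal_all
    return df


def _curve_params(accessions: list[str], cfg: SimConfig) -> dict:
    """Per-accession true physiological parameters, lognormal around the
    defaults with CV ``cfg.curve_param_cv``."""
    rng = cfg.child_rng("curves")
    cv = cfg.curve_param_cv
    sig = np.sqrt(np.log1p(cv ** 2))

    def ln(mean):
        return float(mean * np.exp(rng.normal(-0.5 * sig ** 2, sig)))

    out = {}
    for acc in accessions:
        out[acc] = {
            "aci": FvCBParams(vcmax=ln(60.0), jmax=ln(120.0), rd=ln(1.5),
                              tpu=ln(10.0)),
            "aq": AqParams(phi=min(ln(0.06), 0.12), asat_gross=ln(28.0),
                           theta=min(ln(0.7), 0.99), r_l=ln(1.0)),
            "npq": NpqTraceParams(ind_amp=ln(2.0), ind_rate=ln(0.01),
                                  rel_rate=ln(0.005)),
        }
    return out


# ---------------------------------------------------------------------------
# field trial
# ---------------------------------------------------------------------------

def _year_layout(design: DesignSpec, accessions: list[str],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Randomised alpha-lattice layout: per replicate, accessions are
    shuffled into blocks; column = plot position within the block."""
    if len(accessions) != design.n_plots:
        raise ValueError(
            f"{len(accessions)} accessions incompatible with a "
            f"{design.n_blocks}×{design.plots_per_block} lattice")
    rows = []
    for rep in range(1, design.n_reps + 1):
        order = rng.permutation(len(accessions))
        for slot, a_idx in enumerate(order):
            rows.append({
                "accession": accessions[a_idx],
                "replicate": rep,
                "block": slot // design.plots_per_block + 1,
                "column": slot % design.plots_per_block + 1,
            })
    return pd.DataFrame(rows)


def simulate_trial(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    cfg: SimConfig,
    year2_accessions: list[str] | None = None,
) -> pd.DataFrame:
    """Two-year alpha-lattice plot table with configured heritability.

    Plot value = µ + g_i + year_t + (g×year)_it + rep + block(rep, year)
    + column + β·DPH + ε.  The residual SD is set per trait so that the
    single-year line-mean heritability σg²/(σg² + σε²/r) equals the
    configured value.  Year 2 keeps ``year2_accessions`` (default: the
    first 270 of the panel, mirroring the study's 270-of-320 carryover).
    """
    rng = cfg.child_rng("trial")
    accs = list(genotypes.accessions)
    d1, d2 = cfg.design_year1, cfg.design_year2
    if year2_accessions is None:
        year2_accessions = accs[: d2.n_plots]
    layouts = {
        2021: _year_layout(d1, accs, rng),
        2022: _year_layout(d2, list(year2_accessions), rng),
    }

    gvals = truth.true_genotype_values
    frames = []
    for year, lay in layouts.items():
        lay = lay.copy()
        lay["year"] = year
        lay["dph"] = rng.integers(0, 11, size=len(lay))
        frames.append(lay)
    plots = pd.concat(frames, ignore_index=True)

    for trait, h2 in cfg.trait_heritabilities.items():
        sg = cfg.trait_genetic_sd.get(trait, 1.0)
        mu = cfg.trait_means.get(trait, 0.0)
        r = d1.n_reps
        if h2 <= 0 or sg == 0:
            g_eff = pd.Series(0.0, index=gvals.index)
            se = sg if sg > 0 else 1.0
        elif h2 >= 1.0:
            g_eff = gvals[trait]
            se = 0.0
        else:
            g_eff = gvals[trait]
            se = float(sg * np.sqrt(r * (1.0 - h2) / h2))

        unit = sg if sg > 0 else 1.0
        gxe = {}
        for year in (2021, 2022):
            gxe[year] = pd.Series(
                rng.normal(0.0, cfg.gxe_sd * unit, size=len(gvals)),
                index=gvals.index) if cfg.gxe_sd > 0 else pd.Series(0.0, index=gvals.index)
        year_shift = {2021: 0.0, 2022: cfg.year2_shift_frac * unit}

        rep_eff = {(y, rp): rng.normal(0, cfg.rep_sd_frac * unit)
                   for y in (2021, 2022) for rp in (1, 2)}
        blk_eff = {}
        col_eff = {}
        vals = np.empty(len(plots))
        for i, row in enumerate(plots.itertuples(index=False)):
            key_b = (row.year, row.replicate, row.block)
            if key_b not in blk_eff:
                blk_eff[key_b] = rng.normal(0, cfg.block_sd_frac * unit)
            key_c = (row.year, row.column)
            if key_c not in col_eff:
                col_eff[key_c] = rng.normal(0, cfg.column_sd_frac * unit)
            vals[i] = (
                mu
                + g_eff[row.accession]
                + year_shift[row.year]
                + gxe[row.year][row.accession]
                + rep_eff[(row.year, row.replicate)]
                + blk_eff[key_b]
                + col_eff[key_c]
                + cfg.dph_beta_frac * unit * row.dph
                + (rng.normal(0.0, se) if se > 0 else 0.0)
            )
        plots[trait] = vals
    return plots


# ---------------------------------------------------------------------------
# gas exchange and fluorescence
# ---------------------------------------------------------------------------

def simulate_aci_curve(params: FvCBParams, cfg: SimConfig,
                       rng: np.random.Generator | None = None):
    """A–Ci observations at the protocol's 11 setpoints, in order.

    Ci = ``cfg.ci_over_ca`` × setpoint (+ optional Gaussian jitter,
    resampled up to 10 times if non-positive); A = FvCB forward model
    + Gaussian noise of SD ``cfg.noise_sd_gasex``.
    """
    from .photofit import AciCurve

    if rng is None:
        rng = cfg.child_rng("aci")
    ca = np.array(CO2_SETPOINTS, dtype=float)
    ci = cfg.ci_over_ca * ca
    if cfg.ci_noise_sd > 0:
        for j in range(len(ci)):
            for _ in range(10):
                trial = ci[j] + rng.normal(0.0, cfg.ci_noise_sd)
                if trial > 0:
                    ci[j] = trial
                    break
            else:
                raise ValueError("could not draw a positive Ci after 10 tries")
    a = np.asarray(fvcb_forward(ci, params), dtype=float)
    if cfg.noise_sd_gasex > 0:
        a = a + rng.normal(0.0, cfg.noise_sd_gasex, size=a.shape)
    return AciCurve(ci=ci, a_net=a, ca_ref=ca)


def simulate_aq_curve(params: AqParams, cfg: SimConfig,
                      rng: np.random.Generator | None = None):
    """A–Q observations at the protocol's 6 light steps."""
    from .photofit import AqCurve

    if rng is None:
        rng = cfg.child_rng("aq")
    q = np.array(LIGHT_STEPS, dtype=float)
    a = nrh_forward(q, params.phi, params.asat_gross, params.theta, params.r_l)
    if cfg.noise_sd_gasex > 0:
        a = a + rng.normal(0.0, cfg.noise_sd_gasex, size=a.shape)
    return AqCurve(q=q, a_net=a)


def npq_truth_curves(p: NpqTraceParams, t: np.ndarray):
    """Noise-free NPQ(t) and ΦPSII(t) for the two-phase schedule."""
    t = np.asarray(t, dtype=float)
    light = t <= ACTINIC_ON_S
    npq = np.empty_like(t)
    phi = np.empty_like(t)
    npq[light] = p.ind_amp * (1.0 - np.exp(-p.ind_rate * t[light]))
    phi[light] = p.phi_end + (p.fv_fm - p.phi_end) * np.exp(-p.phi_rate * t[light])
    td = t[~light] - ACTINIC_ON_S
    npq600 = p.ind_amp * (1.0 - np.exp(-p.ind_rate * ACTINIC_ON_S))
    rel_res = p.rel_res_frac * npq600
    npq[~light] = (npq600 - rel_res) * np.exp(-p.rel_rate * td) + rel_res
    phi[~light] = p.phi_end + p.rec_amp * (1.0 - np.exp(-p.rec_rate * td))
    return npq, phi


def simulate_npq_trace(params: NpqTraceParams, cfg: SimConfig,
                       rng: np.random.Generator | None = None):
    """Fluorescence trace on a fixed pulse grid over 0–1400 s.

    NPQ/ΦPSII noise (SD ``cfg.noise_sd_npq`` on the NPQ scale, scaled
    to ΦPSII) is applied on the derived-quantity scale, then converted
    back to Fm′/Fs so derived series round-trip exactly.
    """
    from .npqkinetics import FluorTrace

    if rng is None:
        rng = cfg.child_rng("npq")
    dt = cfg.pulse_interval_s
    end = ACTINIC_ON_S + DARK_PHASE_S
    t = np.arange(dt, end + 0.5 * dt, dt)
    if not (np.any(t <= ACTINIC_ON_S) and np.any(t > ACTINIC_ON_S)):
        raise ValueError("pulse grid must cover both actinic phases")
    npq, phi = npq_truth_curves(params, t)
    if cfg.noise_sd_npq > 0:
        npq = npq + rng.normal(0.0, cfg.noise_sd_npq, size=t.shape)
        phi = phi + rng.normal(0.0, cfg.noise_sd_npq * 0.2, size=t.shape)
    npq = np.maximum(npq, 0.0)
    phi = np.clip(phi, 1e-3, 0.999)
    fm_prime = params.fm_dark / (1.0 + npq)
    fs = fm_prime * (1.0 - phi)
    return FluorTrace(time=t, fs=fs, fm_prime=fm_prime,
                      fm_dark=params.fm_dark, f0_dark=params.f0_dark,
                      actinic_on=0.0, actinic_off=ACTINIC_ON_S, end=end)
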