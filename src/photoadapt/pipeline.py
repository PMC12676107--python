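"""End-to-end orchestration: simulate → fit curves → trait table →
mixed models/heritability → plasticity → structure/selection → GWAS.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can restart from prior on-disk artifacts.  A
:class:`StageReport` (hashes, row counts, wall time, warnings) is
recorded per executed stage and the full run report is written as
JSON.  All randomness derives from the single seed in the simulation
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import gwas as pgwas
from . import popgen, quantgen
from .photofit import fit_aci, fit_aq, FitError
from .npqkinetics import fit_trace
from .synthdata import (SimConfig, simulate_aci_curve, simulate_aq_curve,
                        simulate_genotypes, simulate_npq_trace, simulate_trial)

__all__ = ["RunConfig", "StageReport", "run", "mcmc_retention", "STAGES"]

STAGES = ("simulate", "fit_curves", "traits", "quantgen", "plasticity",
          "structure", "seltest", "gwas")


def mcmc_retention(iterations: int, burn_in: int, thin: int) -> int:
    """Retained posterior draws after burn-in and thinning:
    (iterations − burn_in) // thin.  Used to size the selection-test
    null sample for protocol parity with the MCMC convention
    (15000, 5000, 2) → 5000."""
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1:
        raise ValueError("thin must be ≥ 1")
    return (iterations - burn_in) // thin


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "photoadapt_run"
    stages: tuple = STAGES
    alpha: float = 0.05
    traits: tuple | None = None  # default: all simulated traits
    curve_subset: int = 20  # accessions with gas-exchange/fluorescence curves
    n_bootstrap: int = 100
    k_clusters: int | None = None  # None → choose_k
    tree_level: str = "subpop"  # "subpop" | "accession"
    mcmc_iterations: int = 15_000
    mcmc_burn_in: int = 5_000
    mcmc_thin: int = 2
    annotation: str | None = None  # optional GFF3 for gene windows

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .synthdata import DesignSpec

        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            for key in ("design_year1", "design_year2"):
                if key in sim and isinstance(sim[key], (list, tuple)):
                    sim[key] = DesignSpec(*sim[key])
            sim = SimConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StageReport:
    stage: str
    outputs: dict  # path → sha256
    rows: dict  # artifact → row count
    warnings: list
    wall_time_s: float


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report(stage: str, outdir: Path, files: list[str], rows: dict,
            warns: list, t0: float) -> StageReport:
    return StageReport(
        stage=stage,
        outputs={f: _sha256(outdir / f) for f in files if (outdir / f).exists()},
        rows=rows,
        warnings=[str(w.message) for w in warns],
        wall_time_s=round(time.perf_counter() - t0, 3),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    gm, truth = simulate_genotypes(cfg.sim)
    plots = simulate_trial(gm, truth, cfg.sim)
    pio.write_genotype_csv(gm, out / "genotypes.csv")
    pio.write_vcf(gm, out / "genotypes.vcf")
    pio.write_truth_json(truth, out / "truth.json")
    plots.to_csv(out / "plots.csv", index=False)

    rng = cfg.sim.child_rng("pipeline-curves")
    subset = gm.accessions[: cfg.curve_subset]
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    manifest = []
    for acc in subset:
        params = truth.true_curve_params[acc]
        aci = simulate_aci_curve(params["aci"], cfg.sim, rng=rng)
        aq = simulate_aq_curve(params["aq"], cfg.sim, rng=rng)
        trace = simulate_npq_trace(params["npq"], cfg.sim, rng=rng)
        pio.write_aci_csv(aci, curves_dir / f"{acc}_aci.csv")
        aqf = curves_dir / f"{acc}_aq.csv"
        pd.DataFrame({"Qin": aq.q, "A": aq.a_net}).to_csv(aqf, index=False)
        pio.write_trace_csv(trace, curves_dir / f"{acc}_trace.csv")
        manifest.append({"accession": acc,
                         "aci": f"curves/{acc}_aci.csv",
                         "aq": f"curves/{acc}_aq.csv",
                         "trace": f"curves/{acc}_trace.csv"})
    pd.DataFrame(manifest).to_csv(out / "curve_manifest.csv", index=False)
    files = ["genotypes.csv", "genotypes.vcf", "truth.json", "plots.csv",
             "curve_manifest.csv"]
    return files, {"plots.csv": len(plots), "curve_manifest.csv": len(manifest)}


def _stage_fit_curves(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    manifest = pd.read_csv(out / "curve_manifest.csv")
    rows = []
    for rec in manifest.itertuples(index=False):
        row = {"accession": rec.accession}
        try:
            fit = fit_aci(pio.read_aci_csv(out / rec.aci),
                          tpu_noise_sd=max(cfg.sim.noise_sd_gasex, 1e-3))
            row.update(Vcmax=fit.estimates.vcmax, Jmax=fit.estimates.jmax,
                       TPU=fit.estimates.tpu, Rd=fit.estimates.rd,
                       aci_rmse=fit.rmse)
        except FitError as exc:
            row["aci_error"] = str(exc)
        aq_df = pd.read_csv(out / rec.aq)
        from .photofit import AqCurve

        try:
            aqfit = fit_aq(AqCurve(q=aq_df["Qin"].to_numpy(float),
                                   a_net=aq_df["A"].to_numpy(float)))
            row.update(PhiCO2max=aqfit.phi, Asat_gross=aqfit.asat_gross,
                       theta=aqfit.theta, R_L=aqfit.r_l)
        except FitError as exc:
            row["aq_error"] = str(exc)
        try:
            k = fit_trace(pio.read_trace_csv(out / rec.trace))
            row.update(NPQ_linear=k.npq_linear, NPQ_ind_amp=k.ind_amp,
                       NPQ_ind_rate=k.ind_rate, NPQ_rel_amp=k.rel_amp,
                       NPQ_rel_rate=k.rel_rate, NPQ_rel_res=k.rel_res,
                       PhiPSII_rec_amp=k.rec_amp, PhiPSII_rec_rate=k.rec_rate,
                       PhiPSII_rec_res=k.rec_res, max_NPQ=k.max_npq,
                       final_NPQ=k.final_npq, final_PhiPSII=k.final_phipsii,
                       FvFm=k.fv_fm)
        except (ValueError, FitError) as exc:
            row["trace_error"] = str(exc)
        rows.append(row)
    fitted = pd.DataFrame(rows)
    fitted.to_csv(out / "fitted_curves.csv", index=False)
    return ["fitted_curves.csv"], {"fitted_curves.csv": len(fitted)}


def _stage_traits(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    plots = pd.read_csv(out / "plots.csv")
    fitted_path = out / "fitted_curves.csv"
    if fitted_path.exists():
        fitted = pd.read_csv(fitted_path)
        plots = plots.merge(fitted, on="accession", how="left")
    table = quantgen.derive_traits(plots)
    table.to_csv(out / "trait_table.csv", index=False)
    return ["trait_table.csv"], {"trait_table.csv": len(table)}


def _traits_of(cfg: RunConfig, table: pd.DataFrame) -> list[str]:
    if cfg.traits is not None:
        return list(cfg.traits)
    return [t for t in cfg.sim.trait_heritabilities if t in table.columns]


def _stage_quantgen(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    table = pd.read_csv(out / "trait_table.csv")
    blups, blues, herit = [], [], []
    for trait in _traits_of(cfg, table):
        for model in ("year2021", "year2022", "joint"):
            fr = quantgen.fit_mixed(table, trait, model=model,
                                    genotype_as="random")
            fb = quantgen.fit_mixed(table, trait, model=model,
                                    genotype_as="fixed")
            h2 = quantgen.heritability(fr)
            for acc, v in fr.blups.items():
                blups.append({"trait": trait, "model": model, "accession": acc,
                              "blup": v, "pev": fr.pev[acc]})
            for acc, v in fb.blues.items():
                blues.append({"trait": trait, "model": model, "accession": acc,
                              "blue": v,
                              "population_mean": fb.population_mean})
            herit.append({"trait": trait, "model": model,
                          "sigma2_g": fr.sigma2_g, "mean_pev": fr.mean_pev,
                          "h2_cullis": h2.h2_cullis, "h2_pm": h2.h2_pm,
                          **{f"var_{k}": v
                             for k, v in fr.variance_components.items()}})
    pd.DataFrame(blups).to_csv(out / "blups.csv", index=False)
    pd.DataFrame(blues).to_csv(out / "blues.csv", index=False)
    pd.DataFrame(herit).to_csv(out / "heritability.csv", index=False)
    return (["blups.csv", "blues.csv", "heritability.csv"],
            {"heritability.csv": len(herit)})


def _stage_plasticity(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    blues = pd.read_csv(out / "blues.csv")
    rows = []
    for trait, sub in blues.groupby("trait"):
        y1 = sub[sub["model"] == "year2021"].set_index("accession")
        y2 = sub[sub["model"] == "year2022"].set_index("accession")
        if y1.empty or y2.empty:
            continue
        res = quantgen.plasticity(
            y1["blue"], y2["blue"],
            {2021: float(y1["population_mean"].iloc[0]),
             2022: float(y2["population_mean"].iloc[0])})
        for acc, v in res.values.items():
            rows.append({"trait": trait, "accession": acc, "plasticity": v})
    df = pd.DataFrame(rows)
    df.to_csv(out / "plasticity.csv", index=False)
    return ["plasticity.csv"], {"plasticity.csv": len(df)}


def _stage_structure(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    gm = pio.read_genotype_csv(out / "genotypes.csv")
    k = cfg.k_clusters or popgen.choose_k(gm)
    q = popgen.estimate_admixture(gm, k, seed=cfg.sim.seed)
    labels = popgen.assign_subpops(q)
    pd.DataFrame(q.q, index=q.accessions,
                 columns=[f"Q{i + 1}" for i in range(k)]).to_csv(out / "qmatrix.csv")
    labels.to_csv(out / "subpops.csv")
    freqs = popgen.allele_freq_by_subpop(gm, labels)
    freqs.to_csv(out / "allele_freqs.csv")
    theta = popgen.coancestry(gm, labels)
    pd.DataFrame(theta.theta, index=theta.subpops,
                 columns=theta.subpops).to_csv(out / "coancestry.csv")
    if cfg.tree_level == "accession":
        tree_freqs = gm.imputed()
        tree_labels = gm.accessions
    else:
        tree_freqs = freqs.to_numpy()
        tree_labels = list(freqs.index)
    tree = popgen.bootstrap_support(tree_freqs, tree_labels,
                                    n_replicates=cfg.n_bootstrap,
                                    seed=cfg.sim.seed)
    pio.write_newick(tree, out / "nj_tree.nwk")
    return (["qmatrix.csv", "subpops.csv", "allele_freqs.csv",
             "coancestry.csv", "nj_tree.nwk"],
            {"qmatrix.csv": len(q.accessions), "K": k})


def _stage_seltest(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    gm = pio.read_genotype_csv(out / "genotypes.csv")
    labels = pd.read_csv(out / "subpops.csv", index_col=0)["subpop"]
    theta = popgen.coancestry(gm, labels)
    blups = pd.read_csv(out / "blups.csv")
    herit = pd.read_csv(out / "heritability.csv").set_index(["trait", "model"])
    n_draws = mcmc_retention(cfg.mcmc_iterations, cfg.mcmc_burn_in,
                             cfg.mcmc_thin)
    rows = []
    joint = blups[blups["model"] == "joint"]
    for trait, sub in joint.groupby("trait"):
        bv = sub.set_index("accession")["blup"]
        lab = labels.reindex(bv.index)
        means = [bv[lab == sp].mean() for sp in theta.subpops]
        sigma2_a = float(herit.loc[(trait, "joint"), "sigma2_g"])
        if not np.isfinite(sigma2_a) or sigma2_a <= 0:
            continue
        res = popgen.selection_S(means, sigma2_a, theta, n_draws=n_draws,
                                 seed=cfg.sim.seed, trait=trait)
        rows.append({"trait": trait, "S": res.s, "n_draws": res.n_draws,
                     "D_observed": res.d_observed})
    df = pd.DataFrame(rows)
    df.to_csv(out / "selection_s.csv", index=False)
    return ["selection_s.csv"], {"selection_s.csv": len(df)}


def _stage_gwas(cfg: RunConfig, out: Path) -> tuple[list[str], dict]:
    gm = pio.read_genotype_csv(out / "genotypes.csv")
    blues = pd.read_csv(out / "blues.csv")
    blups = pd.read_csv(out / "blups.csv")
    labels = pd.read_csv(out / "subpops.csv", index_col=0)["subpop"]
    pcs = pgwas.genotype_pca(gm)
    kin = pgwas.kinship(gm)
    qtl_frames = []
    scan_files = []
    trait_blues = {}
    for trait in sorted(blues["trait"].unique()):
        b_e = blues[(blues["trait"] == trait) & (blues["model"] == "joint")]
        b_p = blups[(blups["trait"] == trait) & (blups["model"] == "joint")]
        y_e = b_e.set_index("accession")["blue"]
        y_p = b_p.set_index("accession")["blup"]
        trait_blues[trait] = y_e
        scan_e = pgwas.mlm_scan(y_e, gm, pcs, kin, alpha=cfg.alpha,
                                trait=trait, basis="BLUE")
        scan_p = pgwas.mlm_scan(y_p, gm, pcs, kin, alpha=cfg.alpha,
                                trait=trait, basis="BLUP")
        fn = f"gwas_{trait.replace(':', '_')}.csv"
        man = scan_e.table[["chrom", "pos", "neg_log10_p"]].copy()
        man["threshold"] = -np.log10(scan_e.threshold_p)
        man.to_csv(out / fn, index=False)
        scan_files.append(fn)
        qtl_frames.append(pgwas.high_confidence(scan_e, scan_p))
    qtl = (pd.concat(qtl_frames, ignore_index=True) if qtl_frames
           else pd.DataFrame(columns=["snp", "chrom", "pos", "trait"]))
    qtl.to_csv(out / "qtl_high_confidence.csv", index=False)
    files = scan_files + ["qtl_high_confidence.csv"]
    if len(qtl):
        follow = pgwas.qtl_subpop_follow_up(qtl, gm, labels, trait_blues)
        follow.to_csv(out / "qtl_follow_up.csv", index=False)
        files.append("qtl_follow_up.csv")
        if cfg.annotation:
            ann = pio.read_gff3_genes(cfg.annotation)
            hits = pgwas.genes_near(qtl, ann)
            pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
                out / "gene_windows.csv", index=False)
            files.append("gene_windows.csv")
    return files, {"qtl_high_confidence.csv": len(qtl)}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fit_curves": _stage_fit_curves,
    "traits": _stage_traits,
    "quantgen": _stage_quantgen,
    "plasticity": _stage_plasticity,
    "structure": _stage_structure,
    "seltest": _stage_seltest,
    "gwas": _stage_gwas,
}

_STAGE_INPUTS = {
    "simulate": (),
    "fit_curves": ("curve_manifest.csv",),
    "traits": ("plots.csv",),
    "quantgen": ("trait_table.csv",),
    "plasticity": ("blues.csv",),
    "structure": ("genotypes.csv",),
    "seltest": ("subpops.csv", "blups.csv", "heritability.csv"),
    "gwas": ("genotypes.csv", "blues.csv", "blups.csv", "subpops.csv"),
}


def run(config: RunConfig) -> list[StageReport]:
    """Execute the configured stages in dependency order.

    A stage whose upstream artifact is missing raises a FileNotFoundError
    naming the stage that must be rerun.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    reports = []
    producers = {
        "curve_manifest.csv": "simulate", "plots.csv": "simulate",
        "genotypes.csv": "simulate", "trait_table.csv": "traits",
        "blues.csv": "quantgen", "blups.csv": "quantgen",
        "heritability.csv": "quantgen", "subpops.csv": "structure",
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        for need in _STAGE_INPUTS[stage]:
            if not (out / need).exists() and stage != "simulate":
                missing_from = producers.get(need, "simulate")
                raise FileNotFoundError(
                    f"stage {stage!r} needs {need}; rerun stage "
                    f"{missing_from!r} first")
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            files, rows = _STAGE_FNS[stage](config, out)
        reports.append(_report(stage, out, files, rows, caught, t0))
    payload = [dataclasses.asdict(r) for r in reports]
    (out / "run_report.json").write_text(json.dumps(payload, indent=2))
    return reports
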