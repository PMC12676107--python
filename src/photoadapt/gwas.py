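"""Single-marker mixed-linear-model association scan and follow-up.

The scan corrects for population structure with principal components
and for relatedness with a VanRaden kinship matrix: the null model
y = PC·β + u + ε with var(u) = σu²·K is fitted once by exact REML on
the kinship eigenbasis, and each SNP is then tested by generalized
least squares at the null variance ratio (the standard
eigendecomposition shortcut for single-marker scans).  Significance
uses the Bonferroni threshold α / n_snps.

Follow-up utilities: the BLUE ∧ BLUP high-confidence intersection,
per-subpopulation allele-frequency + trait contrasts for significant
SNPs, and ±100 kb gene-window queries against a GFF3 annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen import GenotypeMatrix, allele_freq_by_subpop
from .quantgen import subpop_anova_tukey

__all__ = [
    "AssociationScan",
    "GeneWindowHit",
    "genotype_pca",
    "kinship",
    "mlm_scan",
    "high_confidence",
    "qtl_subpop_follow_up",
    "genes_near",
    "GENE_WINDOW_BP",
]

GENE_WINDOW_BP = 100_000


@dataclass
class AssociationScan:
    table: pd.DataFrame  # snp, chrom, pos, effect, se, p, neg_log10_p
    trait: str
    basis: str  # "BLUE" | "BLUP"
    n: int
    threshold_p: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] <= self.threshold_p]


@dataclass
class GeneWindowHit:
    snp_id: str
    gene_id: str
    distance: int  # bp; 0 when the SNP lies inside the gene
    gene_start: int
    gene_end: int


def genotype_pca(genotypes: GenotypeMatrix, n_components: int = 3) -> pd.DataFrame:
    """PCs of the centered-and-scaled 0/1 matrix (mean-imputed missing).

    Monomorphic SNPs are excluded from scaling.
    """
    g = genotypes.imputed()
    p = g.mean(axis=0)
    keep = (p > 0) & (p < 1)
    gc = (g[:, keep] - p[keep]) / np.sqrt(p[keep] * (1.0 - p[keep]))
    u, s, _ = np.linalg.svd(gc, full_matrices=False)
    pcs = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(pcs, index=genotypes.accessions,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix for the selfing 0/1 coding.

    Codes are doubled to allele dosages (0/2), centered at 2p and
    scaled by 2Σp(1−p); under panmixia of fully inbred lines the
    diagonal averages ≈ 1 + F ≈ 2.
    """
    g = genotypes.imputed()
    p = g.mean(axis=0)
    keep = (p > 0) & (p < 1)
    d = 2.0 * g[:, keep]
    z = d - 2.0 * p[keep]
    denom = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    k = z @ z.T / denom
    return pd.DataFrame(k, index=genotypes.accessions,
                        columns=genotypes.accessions)


def _null_reml_ratio(y: np.ndarray, x: np.ndarray, eigvals: np.ndarray,
                     u: np.ndarray) -> float:
    """Exact 1-parameter REML for var(u) = σu²K on the eigenbasis of K.

    Returns the variance ratio λ = σu²/σε² maximising the restricted
    likelihood (profiled over σε²).
    """
    n, p = x.shape
    yt = u.T @ y
    xt = u.T @ x

    def negll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * eigvals + 1.0
        xw = xt / w[:, None]
        xtx = xt.T @ xw
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(xtx, xw.T @ yt)
        r = yt - xt @ beta
        ypy = float(np.sum(r * r / w))
        if ypy <= 0:
            return 1e12
        return 0.5 * ((n - p) * np.log(ypy / (n - p))
                      + np.sum(np.log(w)) + logdet_xtx)

    res = optimize.minimize_scalar(negll, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # compare against the boundary λ → 0 (no genetic variance)
    if negll(-30.0) < res.fun:
        lam = 0.0
    return lam


def mlm_scan(
    phenotype: pd.Series,
    genotypes: GenotypeMatrix,
    pcs: pd.DataFrame | None = None,
    kin: pd.DataFrame | None = None,
    alpha: float = 0.05,
    trait: str = "",
    basis: str = "BLUE",
    min_n: int = 50,
) -> AssociationScan:
    """Mixed-linear-model single-marker scan with PC + kinship correction.

    Missing genotypes are dropped SNP-wise by mean-imputing the tested
    dosage (equivalent to zero-weighting under the centered coding).
    Wald p-values per SNP; Bonferroni threshold α / n_snps.
    """
    common = [a for a in genotypes.accessions if a in phenotype.dropna().index]
    if len(common) < min_n:
        raise ValueError(f"need ≥ {min_n} accessions with phenotype and genotype")
    idx = [genotypes.accessions.index(a) for a in common]
    y = phenotype[common].to_numpy(dtype=float)
    n = len(common)

    if pcs is None:
        pcs = genotype_pca(genotypes)
    if kin is None:
        kin = kinship(genotypes)
    x = np.column_stack([np.ones(n), pcs.loc[common].to_numpy()])
    k = kin.loc[common, common].to_numpy()

    lam_floor = 1e-8
    w_eig, u = np.linalg.eigh(0.5 * (k + k.T))
    if w_eig.min() < -1e-8:
        warnings.warn("kinship not PSD; eigenvalues floored at 1e-8")
    w_eig = np.maximum(w_eig, lam_floor)  # silent repair of round-off

    lam = _null_reml_ratio(y, x, w_eig, u)
    weights = 1.0 / (lam * w_eig + 1.0)

    yt = u.T @ y
    xt = u.T @ x
    xw = xt * weights[:, None]
    xtx_inv = np.linalg.inv(xt.T @ xw)
    # M = W − WX(X'WX)⁻¹X'W applied on the rotated scale
    my = weights * yt - xw @ (xtx_inv @ (xw.T @ yt))

    g = genotypes.imputed()[idx]
    gt = u.T @ g
    mg = weights[:, None] * gt - xw @ (xtx_inv @ (xw.T @ gt))

    gmg = np.einsum("ij,ij->j", gt, mg)
    gmy = gt.T @ my
    ymy = float(yt @ my)
    dof = n - x.shape[1] - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gmy / gmg
        sse = ymy - beta * gmy
        s2 = np.maximum(sse, 0.0) / dof
        se = np.sqrt(s2 / gmg)
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    mono = ~(gmg > 1e-12)
    pvals[mono] = 1.0
    beta[mono] = 0.0
    se[mono] = np.nan

    thr = alpha / genotypes.n_snps
    table = pd.DataFrame({
        "snp": genotypes.snp_ids,
        "chrom": genotypes.chrom,
        "pos": genotypes.pos,
        "effect": beta,
        "se": se,
        "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
        "neg_log10_p": -np.log10(np.clip(pvals, np.finfo(float).tiny, 1.0)),
    })
    return AssociationScan(table=table, trait=trait, basis=basis, n=n,
                           threshold_p=thr)


def high_confidence(scan_blue: AssociationScan,
                    scan_blup: AssociationScan) -> pd.DataFrame:
    """SNP–trait pairs significant in both the BLUE and the BLUP scan."""
    sig_blue = scan_blue.significant.set_index("snp")
    sig_blup = scan_blup.significant.set_index("snp")
    both = sig_blue.index.intersection(sig_blup.index)
    out = sig_blue.loc[both, ["chrom", "pos"]].copy()
    out["trait"] = scan_blue.trait
    out["neg_log10_p_blue"] = sig_blue.loc[both, "neg_log10_p"]
    out["neg_log10_p_blup"] = sig_blup.loc[both, "neg_log10_p"]
    return out.reset_index()


def qtl_subpop_follow_up(
    qtl: pd.DataFrame,
    genotypes: GenotypeMatrix,
    labels: pd.Series,
    trait_values: dict,
) -> pd.DataFrame:
    """Allele frequencies per subpopulation and the trait's subpop ANOVA
    for each high-confidence QTL row.

    ``trait_values`` maps trait name → accession-level Series (BLUEs).
    """
    freqs = allele_freq_by_subpop(genotypes, labels)
    rows = []
    for rec in qtl.itertuples(index=False):
        fr = freqs[rec.snp]
        tv = trait_values[rec.trait].dropna()
        lab = labels.reindex(tv.index)
        ok = lab.notna() & (lab != "admixed")
        f_stat, p_val, letters, _ = subpop_anova_tukey(tv[ok], lab[ok])
        row = {"snp": rec.snp, "trait": rec.trait,
               "anova_F": f_stat, "anova_p": p_val}
        for sp in freqs.index:
            row[f"freq_{sp}"] = fr[sp]
            row[f"letter_{sp}"] = letters.get(sp, "")
        rows.append(row)
    return pd.DataFrame(rows)


def genes_near(
    qtl: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = GENE_WINDOW_BP,
) -> list[GeneWindowHit]:
    """Genes whose span overlaps [pos − window, pos + window] per QTL.

    ``annotation`` needs columns gene_id, chrom, start, end (1-based
    inclusive, strand ignored).  Distance is 0 for a SNP inside the
    gene, else the gap to the nearest gene edge.  A QTL chromosome
    absent from the annotation yields no hits and a warning listing
    the available names.
    """
    hits: list[GeneWindowHit] = []
    chroms = set(annotation["chrom"].astype(str))
    for rec in qtl.itertuples(index=False):
        chrom = str(rec.chrom)
        if chrom not in chroms:
            warnings.warn(f"chromosome {chrom!r} not in annotation; "
                          f"available: {sorted(chroms)}")
            continue
        sub = annotation[annotation["chrom"].astype(str) == chrom]
        lo, hi = rec.pos - window, rec.pos + window
        sel = sub[(sub["end"] >= lo) & (sub["start"] <= hi)]
        for g in sel.itertuples(index=False):
            if g.start <= rec.pos <= g.end:
                dist = 0
            else:
                dist = int(min(abs(rec.pos - g.start), abs(rec.pos - g.end)))
            hits.append(GeneWindowHit(snp_id=rec.snp, gene_id=str(g.gene_id),
                                      distance=dist, gene_start=int(g.start),
                                      gene_end=int(g.end)))
    return hits
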