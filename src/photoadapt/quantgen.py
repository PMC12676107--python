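"""Quantitative genetics on alpha-lattice trial data.

Mixed models with genotype random (BLUPs, genotypic variance, PEV) or
fixed (BLUEs via GLS), with replicate, block-within-replicate and
column as random design terms and days-post-heading (DPH) as a fixed
covariate; joint-year models add a year main effect plus
genotype×year and design×year interactions.

From these fits: broad-sense heritability by the Cullis and
Piepho–Möhring mean-PEV formulas, between-year phenotypic plasticity,
Pearson correlation matrices, one-way ANOVA with Tukey HSD compact
letter displays across subpopulations, and the nested two-way ANOVA of
the targeted watering experiment with percent-change summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import RandomTerm, RemlResult, reml_fit

__all__ = [
    "MixedFitResult",
    "HeritabilityResult",
    "derive_traits",
    "fit_mixed",
    "heritability",
    "plasticity",
    "correlations",
    "subpop_anova_tukey",
    "compact_letter_display",
    "treatment_compare",
]


@dataclass
class MixedFitResult:
    trait: str
    model: str  # "year2021" | "year2022" | "joint"
    genotype_as: str  # "random" | "fixed"
    variance_components: dict
    blues: pd.Series | None
    blups: pd.Series | None
    pev: pd.Series | None  # per-genotype prediction error variance
    sigma2_g: float
    mean_pev: float  # mean variance of a BLUP difference (v̄Δ)
    population_mean: float
    loglik: float
    converged: bool
    reml: RemlResult = field(repr=False, default=None)


@dataclass
class HeritabilityResult:
    h2_cullis: float
    h2_pm: float
    out_of_range: bool  # true when either estimate fell below 0


@dataclass
class PlasticityResult:
    values: pd.Series  # accession → plasticity (trait units)
    skipped: list[str]


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------

def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add iWUE = Asat/gs, SLA = leaf_area/leaf_mass and C:N = %C/%N.

    A zero or missing denominator leaves the derived trait missing for
    that plot, with a warning.
    """
    out = records.copy()
    specs = [("iWUE", "Asat", "gs"), ("SLA", "leaf_area", "leaf_mass"),
             ("C:N", "%C", "%N")]
    for name, num, den in specs:
        if num in out.columns and den in out.columns:
            d = out[den].to_numpy(dtype=float)
            bad = ~(d > 0)
            if bad.any():
                warnings.warn(f"{bad.sum()} plot(s) with non-positive {den}; "
                              f"{name} set missing")
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = out[num].to_numpy(dtype=float) / d
            vals[bad] = np.nan
            out[name] = vals
    return out


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _dummies(keys: pd.Series) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(keys.astype(str))
    return d.to_numpy(dtype=float), list(d.columns)


def _design(records: pd.DataFrame, trait: str, model: str,
            genotype_as: str, design_terms: bool):
    df = records.dropna(subset=[trait]).copy()
    if model in ("year2021", "year2022"):
        year = int(model[4:])
        df = df[df["year"] == year]
        if df.empty:
            raise ValueError(f"no records for {model}")
    elif model != "joint":
        raise ValueError("model must be year2021, year2022 or joint")

    counts = df.groupby("accession").size()
    if (counts >= 2).mean() < 0.8:
        warnings.warn("fewer than 80% of accessions have ≥2 observations")

    y = df[trait].to_numpy(dtype=float)
    dph = df["dph"].to_numpy(dtype=float) if "dph" in df else np.zeros(len(df))

    zg, g_levels = _dummies(df["accession"])
    random_terms: list[RandomTerm] = []
    if genotype_as == "random":
        random_terms.append(RandomTerm("genotype", zg, g_levels))
        x_cols = [np.ones(len(df))]
        x_names = ["intercept"]
    elif genotype_as == "fixed":
        x_cols = [zg[:, j] for j in range(zg.shape[1])]
        x_names = [f"g:{lv}" for lv in g_levels]
    else:
        raise ValueError("genotype_as must be 'random' or 'fixed'")

    if model == "joint":
        yr = (df["year"] == df["year"].max()).to_numpy(dtype=float)
        x_cols.append(yr)
        x_names.append("year")
        if genotype_as == "random":
            zgy, gy_levels = _dummies(df["accession"].astype(str) + ":" +
                                      df["year"].astype(str))
            random_terms.append(RandomTerm("genotype:year", zgy, gy_levels))
        if design_terms:
            for nm, key in [
                ("replicate", df["year"].astype(str) + ":" + df["replicate"].astype(str)),
                ("block", df["year"].astype(str) + ":" + df["replicate"].astype(str)
                 + ":" + df["block"].astype(str)),
                ("column", df["year"].astype(str) + ":" + df["column"].astype(str)),
            ]:
                z, lv = _dummies(key)
                random_terms.append(RandomTerm(nm, z, lv))
    elif design_terms:
        for nm, key in [
            ("replicate", df["replicate"].astype(str)),
            ("block", df["replicate"].astype(str) + ":" + df["block"].astype(str)),
            ("column", df["column"].astype(str)),
        ]:
            z, lv = _dummies(key)
            random_terms.append(RandomTerm(nm, z, lv))

    if "dph" in df and df["dph"].nunique() > 1:
        x_cols.append(dph)
        x_names.append("dph")
    x = np.column_stack(x_cols)
    return df, y, x, x_names, random_terms, g_levels, dph


def fit_mixed(
    records: pd.DataFrame,
    trait: str,
    model: str = "joint",
    genotype_as: str = "random",
    design_terms: bool = True,
    max_iter: int = 200,
) -> MixedFitResult:
    """REML mixed model for one trait.

    ``genotype_as="random"`` yields BLUPs (genotype deviations), the
    genotypic variance σg², per-genotype PEV and the mean variance of
    a BLUP difference; ``genotype_as="fixed"`` yields BLUEs by
    generalized least squares, expressed as deviations from the
    estimated population mean (genotype adjusted means evaluated at the
    average DPH).
    """
    df, y, x, x_names, random_terms, g_levels, dph = _design(
        records, trait, model, genotype_as, design_terms)

    res = reml_fit(y, x, random_terms, fixed_names=x_names, max_iter=max_iter,
                   pev_terms=("genotype",))

    beta = pd.Series(res.beta, index=x_names)
    dph_adj = beta.get("dph", 0.0) * (dph.mean() if len(dph) else 0.0)

    if genotype_as == "random":
        sigma2_g = res.sigma2.get("genotype", 0.0)
        blups = pd.Series(res.blups["genotype"], index=g_levels, name=trait)
        pev_mat = res.pev["genotype"]
        pev = pd.Series(np.diag(pev_mat), index=g_levels, name="pev")
        mean_pev = res.mean_pairwise_pev("genotype")
        pop_mean = float(beta["intercept"] + dph_adj)
        if model == "joint":
            pop_mean += 0.5 * float(beta.get("year", 0.0))
        blues = None
    else:
        g_cols = [nm for nm in x_names if nm.startswith("g:")]
        est = beta[g_cols].to_numpy() + dph_adj
        if model == "joint":
            est = est + 0.5 * beta.get("year", 0.0)
        pop_mean = float(est.mean())
        blues = pd.Series(est - pop_mean,
                          index=[nm[2:] for nm in g_cols], name=trait)
        blups = None
        pev = None
        sigma2_g = np.nan
        mean_pev = np.nan

    return MixedFitResult(
        trait=trait, model=model, genotype_as=genotype_as,
        variance_components=dict(res.sigma2),
        blues=blues, blups=blups, pev=pev,
        sigma2_g=float(sigma2_g), mean_pev=float(mean_pev),
        population_mean=pop_mean, loglik=res.loglik,
        converged=res.converged, reml=res,
    )


def heritability(fit: MixedFitResult) -> HeritabilityResult:
    """Broad-sense heritability from mean PEV and genotypic variance:

        H²_PM     = 1 − PEV̄ / σg²
        H²_Cullis = 1 − PEV̄ / (2 σg²)

    with PEV̄ the fit's mean prediction-error variance of genotypic
    BLUP contrasts.  Values below 0 are reported unclamped, flagged.
    """
    if not np.isfinite(fit.sigma2_g) or fit.sigma2_g <= 0:
        return HeritabilityResult(h2_cullis=np.nan, h2_pm=np.nan,
                                  out_of_range=True)
    h_pm = 1.0 - fit.mean_pev / fit.sigma2_g
    h_c = 1.0 - fit.mean_pev / (2.0 * fit.sigma2_g)
    return HeritabilityResult(h2_cullis=float(h_c), h2_pm=float(h_pm),
                              out_of_range=bool(h_pm < 0 or h_c < 0))


def plasticity(
    blues_2021: pd.Series,
    blues_2022: pd.Series,
    population_means: dict,
) -> PlasticityResult:
    """Between-year plasticity per accession:

    (PopMean₂₀₂₁ + BLUE₂₀₂₁) − (PopMean₂₀₂₂ + BLUE₂₀₂₂),

    defined only for accessions with BLUEs in both years.
    """
    common = blues_2021.index.intersection(blues_2022.index)
    skipped = sorted(set(blues_2021.index).symmetric_difference(blues_2022.index))
    vals = ((population_means[2021] + blues_2021[common])
            - (population_means[2022] + blues_2022[common]))
    return PlasticityResult(values=vals.rename("plasticity"), skipped=skipped)


# ---------------------------------------------------------------------------
# correlations / ANOVA / Tukey
# ---------------------------------------------------------------------------

def correlations(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p-values on pairwise-complete observations.

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 df; pairs with fewer
    than 4 complete observations report r but a missing p.
    """
    cols = list(trait_table.columns)
    r_mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p_mat.values, np.nan)
    for a, b in itertools.combinations(cols, 2):
        pair = trait_table[[a, b]].dropna()
        n = len(pair)
        if n < 2 or pair[a].std() == 0 or pair[b].std() == 0:
            r, p = np.nan, np.nan
        else:
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            if n < 4 or abs(r) >= 1.0:
                p = np.nan if n < 4 else 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return r_mat, p_mat


def compact_letter_display(groups: list[str], sig: dict) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig[(a, b)]`` is True when groups a and b differ significantly;
    groups sharing a letter are not significantly different.
    """
    letters_sets: list[set] = [set(groups)]
    for pair, is_sig in sorted(sig.items()):
        if not is_sig:
            continue
        a, b = pair
        for s in [s for s in letters_sets if a in s and b in s]:
            letters_sets.remove(s)
            letters_sets.extend([s - {a}, s - {b}])
        # absorb: drop sets contained in (or equal to) another set
        letters_sets = [
            s for i, s in enumerate(letters_sets)
            if s and not any(
                (s < t) or (s == t and i > j)
                for j, t in enumerate(letters_sets) if i != j)
        ]
    letters_sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letters_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def subpop_anova_tukey(values, labels, alpha: float = 0.05):
    """One-way ANOVA across groups plus Tukey HSD letter groupings.

    Groups with fewer than 2 observations are excluded with a warning.
    Returns (F, p, letters, tukey_pairs) where ``tukey_pairs`` maps the
    sorted group pair to its Tukey-adjusted p-value (studentized-range
    distribution).
    """
    s = pd.DataFrame({"y": np.asarray(values, dtype=float),
                      "g": np.asarray(labels)}).dropna()
    sizes = s.groupby("g").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding group(s) with n<2: {small}")
        s = s[~s["g"].isin(small)]
    groups = sorted(s["g"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with n ≥ 2")
    arrays = [s.loc[s["g"] == g, "y"].to_numpy() for g in groups]
    f_stat, p_val = stats.f_oneway(*arrays)

    n_tot = sum(map(len, arrays))
    k = len(groups)
    df_w = n_tot - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    pairs = {}
    sig = {}
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        diff = arrays[i].mean() - arrays[j].mean()
        se = np.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_w))
        key = tuple(sorted((gi, gj)))
        pairs[key] = p
        sig[key] = p < alpha
    letters = compact_letter_display(groups, sig)
    return float(f_stat), float(p_val), letters, pairs


# ---------------------------------------------------------------------------
# targeted watering experiment
# ---------------------------------------------------------------------------

def treatment_compare(
    records: pd.DataFrame,
    trait: str,
    log_transform: bool = False,
    alpha: float = 0.05,
):
    """Nested two-way ANOVA of the watering experiment plus percent change.

    Model: trait ~ treatment * subpop + genotype(subpop) [+ treatment
    interaction with the nested genotype].  Genotypes missing a
    treatment level are excluded from interaction terms (dropped from
    the data with a warning).  Percent change per subpopulation and
    per accession is (mean₈₀ − mean₄₀) / mean₈₀ × 100.  Normality
    (Shapiro on residuals) and equal variance (Levene on median
    deviations) screens are reported, never acted on.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.dropna(subset=[trait]).copy()
    df = df.rename(columns={trait: "y"})
    if log_transform:
        if (df["y"] <= 0).any():
            raise ValueError("log transform requested with non-positive values")
        df["y"] = np.log(df["y"])

    full = df.groupby("accession")["treatment"].nunique()
    incomplete = full[full < df["treatment"].nunique()].index.tolist()
    if incomplete:
        warnings.warn(f"genotype(s) missing a treatment level excluded from "
                      f"interactions: {incomplete}")
        df = df[~df["accession"].isin(incomplete)]

    model = smf.ols(
        "y ~ C(treatment) * C(subpop) + C(subpop):C(accession) "
        "+ C(treatment):C(subpop):C(accession)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)

    # Tukey over treatment × subpop cell means
    cells = df["treatment"].astype(str) + "/" + df["subpop"].astype(str)
    _, _, letters, tukey_pairs = subpop_anova_tukey(df["y"], cells, alpha=alpha)

    # percent change on the original trait scale
    raw = records.dropna(subset=[trait])
    def pct(sub: pd.DataFrame) -> float:
        m80 = sub.loc[sub["treatment"] == "rswc80", trait].mean()
        m40 = sub.loc[sub["treatment"] == "rswc40", trait].mean()
        return float((m80 - m40) / m80 * 100.0) if m80 else np.nan
    pct_subpop = raw.groupby("subpop").apply(pct, include_groups=False)
    pct_accession = raw.groupby("accession").apply(pct, include_groups=False)

    resid = model.resid
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
    lev_groups = [g["y"].to_numpy() for _, g in df.groupby(cells)]
    levene_p = float(stats.levene(*lev_groups, center="median").pvalue)

    return {
        "anova": anova,
        "tukey_pairs": tukey_pairs,
        "letters": letters,
        "percent_change_subpop": pct_subpop,
        "percent_change_accession": pct_accession,
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "log_transformed": log_transform,
    }
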