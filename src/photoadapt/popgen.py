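"""Population structure, genetic distance and the drift-vs-selection test.

The panel is a selfing wild-barley diversity collection, so genotypes
are fully homozygous and coded 0/1 (reference/alternate); an
accession's 0/1 codes double as degenerate allele frequencies for
individual-level distances.

Contents:

* :class:`GenotypeMatrix` — accessions × biallelic SNPs with a 1-based
  bp map on chromosomes 1H–7H.
* Nei standard genetic distance and a neighbour-joining tree with
  bootstrap support over loci.
* A simplified latent-factor admixture estimator (truncated SVD +
  alternating constrained least squares) with an eigenvalue-gap rule
  for the number of clusters K, and the >50% assignment rule.
* Subpopulation allele frequencies, a moment-based coancestry matrix,
  and a Monte-Carlo drift-null selection test producing the S
  statistic (S ≈ 0.5 drift, ≈ 1 divergent, ≈ 0 stabilising selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "GenotypeMatrix",
    "QMatrix",
    "CoancestryMatrix",
    "SelectionS",
    "ADMIXED_LABEL",
    "nei_distance",
    "nei_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "tree_bipartitions",
    "estimate_admixture",
    "choose_k",
    "assign_subpops",
    "allele_freq_by_subpop",
    "coancestry",
    "selection_S",
]

ADMIXED_LABEL = "admixed"
MISSING = -1  # sentinel in the int8 code matrix

CHROMOSOMES = tuple(f"{i}H" for i in range(1, 8))


@dataclass
class GenotypeMatrix:
    """Accessions × biallelic SNPs, codes ∈ {0, 1, -1(missing)}."""

    codes: np.ndarray  # int8, n_accessions × n_snps
    accessions: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # str per SNP
    pos: np.ndarray  # int, 1-based bp

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.codes.shape
        if len(self.accessions) != n or len(self.snp_ids) != m:
            raise ValueError("label lengths do not match code matrix shape")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate snp ids")
        bad = ~np.isin(self.codes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("codes must be 0, 1 or -1 (missing)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within {c}")

    @property
    def n_accessions(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def as_float(self) -> np.ndarray:
        """Codes as float with NaN for missing."""
        out = self.codes.astype(float)
        out[self.codes == MISSING] = np.nan
        return out

    def imputed(self) -> np.ndarray:
        """Mean-imputed float matrix (per-SNP mean of observed codes)."""
        g = self.as_float()
        mu = np.nanmean(g, axis=0)
        mu = np.where(np.isfinite(mu), mu, 0.5)
        idx = np.where(np.isnan(g))
        g[idx] = mu[idx[1]]
        return g

    def frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing codes."""
        return np.nanmean(self.as_float(), axis=0)


@dataclass
class QMatrix:
    """Admixture proportions: accessions × K clusters, rows on the simplex."""

    q: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < -1e-9):
            raise ValueError("negative admixture proportion")
        if np.any(np.abs(self.q.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("Q rows must sum to 1")

    @property
    def k(self) -> int:
        return self.q.shape[1]


@dataclass
class CoancestryMatrix:
    theta: np.ndarray  # subpop × subpop
    subpops: list[str]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.allclose(self.theta, self.theta.T, atol=1e-10):
            raise ValueError("coancestry matrix must be symmetric")
        w = np.linalg.eigvalsh(self.theta)
        if w.min() < -1e-8:
            raise ValueError("coancestry matrix not PSD within tolerance")


@dataclass
class SelectionS:
    trait: str
    s: float
    n_draws: int
    d_observed: float


# ---------------------------------------------------------------------------
# Nei distance and neighbour joining
# ---------------------------------------------------------------------------

def _nei_j_terms(fx: np.ndarray, fy: np.ndarray):
    jx = np.mean(fx ** 2 + (1.0 - fx) ** 2)
    jy = np.mean(fy ** 2 + (1.0 - fy) ** 2)
    jxy = np.mean(fx * fy + (1.0 - fx) * (1.0 - fy))
    return jx, jy, jxy


def nei_distance(freqs_x, freqs_y, cap: float = 10.0) -> float:
    """Nei's standard genetic distance D = −ln(Jxy / sqrt(Jx·Jy)).

    J terms are averaged over loci of matched biallelic frequency
    vectors.  Jxy = 0 makes D infinite; it is replaced by ``cap`` with
    a warning.
    """
    fx = np.asarray(freqs_x, dtype=float)
    fy = np.asarray(freqs_y, dtype=float)
    if fx.shape != fy.shape:
        raise ValueError("frequency vectors must have matched loci")
    if np.any((fx < 0) | (fx > 1) | (fy < 0) | (fy > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    jx, jy, jxy = _nei_j_terms(fx, fy)
    if jxy <= 0:
        warnings.warn("Jxy = 0: Nei distance infinite, replaced by cap")
        return cap
    return float(min(-np.log(jxy / np.sqrt(jx * jy)), cap))


def nei_distance_matrix(freqs: np.ndarray, cap: float = 10.0) -> np.ndarray:
    """Pairwise Nei distance between rows of a frequency matrix."""
    f = np.asarray(freqs, dtype=float)
    n = f.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(f[i], f[j], cap=cap)
    return d


def nj_tree(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou–Nei neighbour joining with the standard Q criterion.

    Ties in the Q criterion are broken by the lexicographically lowest
    (i, j) index pair, making the agglomeration order deterministic.
    Returns an unrooted tree (trifurcating root) as a skbio TreeNode.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / label mismatch")
    nodes = [TreeNode(name=str(lab)) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin of flattened row-major scan
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        a, b = active[i], active[j]
        parent = TreeNode()
        nodes[a].length = float(li)
        nodes[b].length = float(lj)
        parent.extend([nodes[a], nodes[b]])
        # distances from the new node to the remaining actives
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for t in active:
            if t in (a, b):
                continue
            d[new_idx, t] = d[t, new_idx] = 0.5 * (d[a, t] + d[b, t] - dij)
        active = [t for t in active if t not in (a, b)] + [new_idx]

    root = TreeNode()
    if len(active) == 3:
        x, y, z = active
        lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
        ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
        lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
        for t, L in zip((x, y, z), (lx, ly, lz)):
            nodes[t].length = float(L)
            root.append(nodes[t])
    else:  # 2 or fewer taxa
        for t in active:
            if nodes[t].length is None:
                nodes[t].length = float(d[active[0], active[1]] / 2) if len(active) == 2 else 0.0
            root.append(nodes[t])
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each normalised to
    the side not containing the lexicographically first taxon."""
    taxa = sorted(t.name for t in tree.tips())
    ref = taxa[0]
    full = frozenset(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if ref in side:
            side = full - side
        parts.add(side)
    return parts


def bootstrap_support(
    freqs: np.ndarray,
    labels: list[str],
    n_replicates: int = 100,
    seed: int | None = None,
    cap: float = 10.0,
) -> TreeNode:
    """NJ tree of Nei distances with bootstrap support over loci.

    ``freqs`` rows are per-taxon allele frequencies (0/1 codes for
    individual accessions).  Support, the fraction of replicate trees
    containing each internal bipartition, is stored on internal nodes
    as ``node.support`` and as the node name (two decimals).
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(freqs, dtype=float)
    n_loci = f.shape[1]
    tree = nj_tree(nei_distance_matrix(f, cap=cap), labels)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, n_loci, size=n_loci)
        rep = nj_tree(nei_distance_matrix(f[:, cols], cap=cap), labels)
        for part in tree_bipartitions(rep):
            counts[part] = counts.get(part, 0) + 1
    taxa = sorted(labels)
    full = frozenset(str(t) for t in taxa)
    ref = sorted(full)[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if ref in side:
            side = full - side
        sup = counts.get(side, 0) / n_replicates
        node.support = sup
        node.name = f"{sup:.2f}"
    return tree


# ---------------------------------------------------------------------------
# admixture estimation
# ---------------------------------------------------------------------------

def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of v onto the probability simplex."""
    v = np.atleast_2d(v)
    n, k = v.shape
    u = -np.sort(-v, axis=1)
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


def estimate_admixture(
    genotypes: GenotypeMatrix,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> QMatrix:
    """Admixture proportions by truncated SVD + alternating constrained LS.

    Missing codes are mean-imputed; a k-means partition of the top-K
    principal components seeds Q; alternating least squares then
    constrains cluster allele frequencies to [0, 1] and Q rows to the
    simplex until the relative change in reconstruction error drops
    below ``tol``.
    """
    from sklearn.cluster import KMeans

    n = genotypes.n_accessions
    if k >= n:
        raise ValueError("K must be smaller than the number of accessions")
    miss_rate = np.mean(genotypes.codes == MISSING, axis=1)
    if np.any(miss_rate >= 0.5):
        raise ValueError("accession(s) with ≥50% missing genotypes")

    g = genotypes.imputed()
    gc = g - g.mean(axis=0)
    # rank-k truncated SVD of the centered matrix for the seed space
    u, s, _ = np.linalg.svd(gc, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
    q = np.full((n, k), 0.05 / max(k - 1, 1))
    q[np.arange(n), km.labels_] = 0.95
    q = q / q.sum(axis=1, keepdims=True)

    ridge = 1e-8 * np.eye(k)
    prev = np.inf
    for _ in range(max_iter):
        f = np.linalg.solve(q.T @ q + ridge, q.T @ g)
        np.clip(f, 0.0, 1.0, out=f)
        qt = np.linalg.solve(f @ f.T + ridge, f @ g.T).T
        q = _project_simplex(qt)
        err = float(np.linalg.norm(g - q @ f))
        if prev < np.inf and abs(prev - err) <= tol * max(prev, 1e-12):
            break
        prev = err
    return QMatrix(q=q, accessions=list(genotypes.accessions))


def choose_k(genotypes: GenotypeMatrix, max_k: int = 15) -> int:
    """Number of clusters by the largest relative eigenvalue gap.

    With K subpopulations the centered genotype covariance carries
    K−1 structure eigenvalues, so the gap index plus one is returned.
    """
    g = genotypes.imputed()
    gc = g - g.mean(axis=0)
    n = gc.shape[0]
    lam = np.linalg.eigvalsh(gc @ gc.T / max(gc.shape[1], 1))[::-1]
    top = lam[: min(max_k, n - 1)]
    top = np.maximum(top, 1e-12)
    ratios = top[:-1] / top[1:]
    return int(np.argmax(ratios)) + 2  # gap after K-1 structure axes


def assign_subpops(q: QMatrix, threshold: float = 0.5) -> pd.Series:
    """Cluster label per accession: argmax cluster when its proportion
    strictly exceeds ``threshold``, else "admixed"."""
    best = q.q.argmax(axis=1)
    maxp = q.q.max(axis=1)
    labels = np.where(maxp > threshold,
                      np.char.add("subpop", (best + 1).astype(str)),
                      ADMIXED_LABEL)
    return pd.Series(labels, index=q.accessions, name="subpop")


# ---------------------------------------------------------------------------
# allele frequencies, coancestry, selection test
# ---------------------------------------------------------------------------

def allele_freq_by_subpop(genotypes: GenotypeMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-subpopulation alternate-allele frequency (mean of non-missing
    0/1 codes); admixed accessions are excluded.  Rows = subpops,
    columns = snp ids; all-missing cells are NaN."""
    labels = pd.Series(labels).reindex(genotypes.accessions)
    g = genotypes.as_float()
    rows = {}
    for sp in sorted(set(labels) - {ADMIXED_LABEL}):
        sel = (labels == sp).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            rows[sp] = np.nanmean(g[sel], axis=0)
    return pd.DataFrame(rows, index=genotypes.snp_ids).T


def coancestry(genotypes: GenotypeMatrix, labels: pd.Series) -> CoancestryMatrix:
    """Moment-based subpopulation coancestry.

    θ_AB = mean over polymorphic loci of (p_A − p̄)(p_B − p̄) / (p̄(1 − p̄))
    with p̄ the unweighted across-subpop mean frequency, shrunk to the
    nearest positive semidefinite matrix by eigenvalue clipping.
    """
    freqs = allele_freq_by_subpop(genotypes, labels)
    p = freqs.to_numpy()
    pbar = p.mean(axis=0)
    keep = (pbar > 0) & (pbar < 1) & np.all(np.isfinite(p), axis=0)
    if keep.sum() == 0:
        raise ValueError("no polymorphic loci with complete subpop frequencies")
    p = p[:, keep]
    pbar = pbar[keep]
    dev = p - pbar
    w = 1.0 / (pbar * (1.0 - pbar))
    theta = (dev * w) @ dev.T / keep.sum()
    # nearest-PSD shrink
    lam, vec = np.linalg.eigh(0.5 * (theta + theta.T))
    theta = (vec * np.maximum(lam, 0.0)) @ vec.T
    theta = 0.5 * (theta + theta.T)
    return CoancestryMatrix(theta=theta, subpops=list(freqs.index))


def selection_S(
    subpop_means,
    sigma2_a: float,
    theta: CoancestryMatrix,
    n_draws: int = 5000,
    seed: int | None = None,
    trait: str = "",
) -> SelectionS:
    """Monte-Carlo drift-null test for selection on subpopulation means.

    Under pure drift the subpopulation mean additive values follow
    MVN(µ1, 2·σ_A²·θ).  The observed Mahalanobis divergence (with µ
    replaced by the coancestry-weighted grand mean and the covariance
    inverted by pseudoinverse) is compared against ``n_draws`` null
    draws; S is the fraction of draws with divergence ≤ observed.
    """
    m = np.asarray(subpop_means, dtype=float)
    s = len(m)
    if theta.theta.shape != (s, s):
        raise ValueError("subpop means / coancestry dimension mismatch")
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    sigma = 2.0 * sigma2_a * theta.theta
    sig_pinv = np.linalg.pinv(sigma, rcond=1e-10, hermitian=True)
    if not np.all(np.isfinite(sig_pinv)):
        raise ValueError("coancestry matrix numerically singular")
    ones = np.ones(s)
    denom = ones @ sig_pinv @ ones
    if denom > 1e-9 * max(np.trace(sig_pinv), 1e-30):
        w = (sig_pinv @ ones) / denom
    else:
        # 1 lies in the null space of Σ⁺ (mean-centered coancestry):
        # the divergence is invariant to the centering, so the plain
        # mean serves as the grand mean.
        w = ones / s

    def divergence(x: np.ndarray) -> np.ndarray:
        mu = x @ w
        d = x - mu[..., None]
        return np.einsum("...i,ij,...j->...", d, sig_pinv, d)

    d_obs = float(divergence(m))

    rng = np.random.default_rng(seed)
    lam, vec = np.linalg.eigh(sigma)
    root = vec * np.sqrt(np.maximum(lam, 0.0))
    draws = rng.standard_normal((n_draws, s)) @ root.T
    d_null = divergence(draws)
    s_stat = float(np.mean(d_null <= d_obs))
    return SelectionS(trait=trait, s=s_stat, n_draws=n_draws, d_observed=d_obs)
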