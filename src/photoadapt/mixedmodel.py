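"""Dense REML machinery for crossed random-effects models.

Fits y = Xβ + Σ_i Z_i u_i + ε with u_i ~ N(0, σ_i² I) by restricted
maximum likelihood, profiled over the residual variance and optimised
over the log variance ratios γ_i = σ_i²/σε².  Problem sizes here are
field-trial scale (a few hundred to ~1500 plots), so everything is
dense Cholesky algebra.

Provides BLUPs, BLUEs (via GLS), per-level prediction error variances
(PEV) from the mixed-model-equations inverse, and the mean variance of
a BLUP difference — the "PEV̄" that the Cullis and Piepho–Möhring
heritability formulas consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, linalg

__all__ = ["RandomTerm", "RemlResult", "reml_fit", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class RandomTerm:
    name: str
    z: np.ndarray  # n × q incidence matrix
    levels: list[str]


@dataclass
class RemlResult:
    beta: np.ndarray
    fixed_names: list[str]
    sigma2: dict  # term name → variance component (includes "residual")
    loglik: float
    blups: dict  # term name → per-level BLUP vector
    pev: dict  # term name → full PEV matrix (per random term)
    n_iter: int
    converged: bool

    def mean_pairwise_pev(self, term: str) -> float:
        """Mean variance of a difference between two levels' BLUPs,
        v̄Δ = mean_{i<j}(PEV_ii + PEV_jj − 2 PEV_ij)."""
        p = self.pev[term]
        g = p.shape[0]
        if g < 2:
            return float(2.0 * np.trace(p) / max(g, 1))
        tr = np.trace(p)
        total = p.sum()
        return float(2.0 * (g * tr - total) / (g * (g - 1)))

    def mean_pev_diag(self, term: str) -> float:
        return float(np.mean(np.diag(self.pev[term])))


def _check_design(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the aliased columns for the error message
        q, r = np.linalg.qr(x)
        aliased = [names[j] for j in range(x.shape[1])
                   if abs(r[j, j]) < 1e-8 * max(abs(np.diag(r)).max(), 1.0)]
        raise ValueError(f"singular fixed design; aliased terms: {aliased}")


class _RemlWorkspace:
    """Precomputed cross-products so each REML objective evaluation
    costs one q×q Cholesky (q = total random-effect levels) instead of
    any n×n work: with U = [Z_1 … Z_k] and G = diag(γ),
    H⁻¹ = I − U G^{1/2} M⁻¹ G^{1/2} U' where M = I_q + G^{1/2} U'U G^{1/2}.
    """

    def __init__(self, y, x, zs):
        self.n, self.p = x.shape
        self.sizes = [z.shape[1] for z in zs]
        u = np.hstack(zs)
        self.cuu = u.T @ u
        self.cux = u.T @ x
        self.cuy = u.T @ y
        self.cxx = x.T @ x
        self.cxy = x.T @ y
        self.cyy = float(y @ y)

    def _expand(self, gammas):
        return np.repeat(np.sqrt(gammas), self.sizes)

    def core(self, gammas):
        """(logdet H, X'H⁻¹X, X'H⁻¹y, y'H⁻¹y) for variance ratios γ."""
        rg = self._expand(gammas)
        m = self.cuu * np.outer(rg, rg)
        m[np.diag_indices_from(m)] += 1.0
        c, low = linalg.cho_factor(m, lower=True, check_finite=False)
        logdet_h = 2.0 * np.sum(np.log(np.diag(c)))
        gux = rg[:, None] * self.cux
        guy = rg * self.cuy
        sx = linalg.cho_solve((c, low), gux, check_finite=False)
        sy = linalg.cho_solve((c, low), guy, check_finite=False)
        xhx = self.cxx - gux.T @ sx
        xhy = self.cxy - gux.T @ sy
        yhy = self.cyy - guy @ sy
        return logdet_h, xhx, xhy, yhy

    def negloglik(self, gammas):
        gammas = np.clip(np.asarray(gammas, dtype=float), 0.0, 1e12)
        try:
            logdet_h, xhx, xhy, yhy = self.core(gammas)
        except np.linalg.LinAlgError:
            return 1e12
        sign, logdet_xtx = np.linalg.slogdet(xhx)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(xhx, xhy)
        ypy = float(yhy - xhy @ beta)
        if ypy <= 0:
            return 1e12
        dof = self.n - self.p
        return 0.5 * (dof * np.log(ypy / dof) + logdet_h + logdet_xtx + dof)


def reml_fit(
    y: np.ndarray,
    x: np.ndarray,
    random_terms: list[RandomTerm],
    fixed_names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    pev_terms: tuple[str, ...] | None = None,
) -> RemlResult:
    """REML fit of a crossed random-effects linear mixed model.

    Negative variance components are handled by the log-ratio
    parameterisation (the boundary γ → 0 is reached asymptotically and
    clamped to exactly zero below 1e-8).  PEV matrices are computed for
    the terms in ``pev_terms`` (default: all).
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    _check_design(x, fixed_names)
    zs = [t.z.astype(float) for t in random_terms]
    k = len(zs)

    if k == 0:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        s2e = float(resid @ resid / max(n - p, 1))
        return RemlResult(beta=beta, fixed_names=fixed_names,
                          sigma2={"residual": s2e}, loglik=np.nan,
                          blups={}, pev={}, n_iter=0, converged=True)

    ws = _RemlWorkspace(y, x, zs)
    # Bounded quasi-Newton directly on the variance ratios: γ = 0 is a
    # clean boundary (negative components constrained to zero) rather
    # than a flat log tail.  Two starts guard against local flats.
    res = None
    for g0 in (np.ones(k), np.full(k, 0.1)):
        cand = optimize.minimize(
            ws.negloglik, g0, method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * k,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10,
                     "eps": 1e-6},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise ConvergenceError("REML objective diverged")
    gammas = np.clip(res.x, 0.0, 1e12)
    gammas[gammas < 1e-8] = 0.0  # boundary: variance constrained to 0

    h = np.eye(n)
    for g, z in zip(gammas, zs):
        if g > 0:
            h += g * (z @ z.T)
    c, low = linalg.cho_factor(h, lower=True, check_finite=False)
    hix = linalg.cho_solve((c, low), x, check_finite=False)
    hiy = linalg.cho_solve((c, low), y, check_finite=False)
    xtx = x.T @ hix
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ hiy)
    resid = y - x @ beta
    ypy = float(resid @ (hiy - hix @ beta))
    s2e = ypy / (n - p)

    sigma2 = {t.name: float(g * s2e) for t, g in zip(random_terms, gammas)}
    sigma2["residual"] = float(s2e)

    # BLUPs: û_i = γ_i Z_i' H⁻¹ (y − Xβ̂)
    e_h = hiy - hix @ beta
    blups = {t.name: g * (t.z.T @ e_h) for t, g in zip(random_terms, gammas)}

    # PEV_i = σ_i² I − (σ_i⁴/σε²) (Z'H⁻¹Z − B'(X'H⁻¹X)⁻¹B)
    want = set(pev_terms) if pev_terms is not None else {t.name for t in random_terms}
    pev = {}
    for t, g in zip(random_terms, gammas):
        if t.name not in want:
            continue
        s2i = g * s2e
        if s2i == 0.0:
            pev[t.name] = np.zeros((t.z.shape[1], t.z.shape[1]))
            continue
        hiz = linalg.cho_solve((c, low), t.z, check_finite=False)
        ztz = t.z.T @ hiz
        b = x.T @ hiz
        pev[t.name] = s2i * np.eye(t.z.shape[1]) - (s2i ** 2 / s2e) * (
            ztz - b.T @ xtx_inv @ b)

    return RemlResult(
        beta=beta, fixed_names=fixed_names, sigma2=sigma2,
        loglik=float(-res.fun), blups=blups, pev=pev,
        n_iter=int(res.nit), converged=bool(res.success),
    )
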