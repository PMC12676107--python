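"""Biochemical fitting of leaf gas-exchange curves.

Implements the Farquhar–von Caemmerer–Berry (FvCB) model of C3
photosynthesis and its inverse problem: given a measured A–Ci curve
(net assimilation versus intercellular CO2), recover the maximum
Rubisco carboxylation rate (Vcmax), the maximum electron-transport
rate for RuBP regeneration (Jmax), triose-phosphate utilisation (TPU)
and day respiration (Rd).  Transition points between the limiting
processes are located with the bilinear method: every admissible
assignment of observations to the Rubisco-, RuBP- and TPU-limited
segments is scored by linearised least squares and the assignment with
the smallest total SSE wins.

Also fits the non-rectangular hyperbola (NRH) to light-response (A–Q)
curves, and computes stomatal limitation by comparing operating
assimilation with the assimilation the fitted model predicts were the
intercellular CO2 equal to ambient (infinite conductance).

All fits assume a leaf temperature of 25°C; the Michaelis constants and
the CO2 compensation point default to the Bernacchi 25°C values on a
Ci basis (no mesophyll-conductance correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "FvCBParams",
    "AciCurve",
    "AqCurve",
    "FvCBFit",
    "AqFit",
    "SLResult",
    "FitError",
    "fvcb_forward",
    "fvcb_limitation",
    "fit_aci",
    "stomatal_limitation",
    "nrh_forward",
    "fit_aq",
]

#: Bernacchi (25°C) kinetic constants, Ci basis.
KC_25 = 404.9  # µmol mol⁻¹
KO_25 = 278.4  # mmol mol⁻¹
GAMMA_STAR_25 = 42.75  # µmol mol⁻¹
O2_MMOL = 210.0  # mmol mol⁻¹

#: Theoretical ceiling for the apparent quantum yield of CO2 fixation.
PHI_MAX_THEORY = 0.125


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted (too few points, divergence,
    or a solution outside the physically meaningful domain)."""


@dataclass(frozen=True)
class FvCBParams:
    """FvCB parameter set. Rates in µmol m⁻² s⁻¹, Kc/Γ* in µmol mol⁻¹,
    Ko/O in mmol mol⁻¹. ``tpu=None`` disables the TPU ceiling."""

    vcmax: float
    jmax: float
    rd: float
    tpu: float | None = None
    gamma_star: float = GAMMA_STAR_25
    kc: float = KC_25
    ko: float = KO_25
    o: float = O2_MMOL

    def __post_init__(self) -> None:
        for name in ("vcmax", "jmax", "rd", "gamma_star", "kc", "ko", "o"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.tpu is not None and self.tpu <= 0:
            raise ValueError("tpu must be positive when set")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc·(1 + O/Ko)."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass
class AciCurve:
    """One A–Ci response curve from a single leaf."""

    ci: np.ndarray  # µmol mol⁻¹
    a_net: np.ndarray  # µmol m⁻² s⁻¹
    ca_ref: np.ndarray | None = None  # reference CO2 setpoints, µmol mol⁻¹
    gs_op: float | None = None  # operating-point gs, mol m⁻² s⁻¹
    tleaf: float = 25.0  # °C

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if self.ci.shape != self.a_net.shape or self.ci.ndim != 1:
            raise ValueError("ci and a_net must be 1-D vectors of equal length")
        if len(self.ci) < 5:
            raise ValueError("an A-Ci curve needs at least 5 observations")
        if np.any(self.ci <= 0):
            raise ValueError("ci must be strictly positive")


@dataclass
class AqCurve:
    """One light-response curve: net assimilation at a ladder of PAR levels."""

    q: np.ndarray  # µmol m⁻² s⁻¹ PAR
    a_net: np.ndarray  # µmol m⁻² s⁻¹

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.a_net = np.asarray(self.a_net, dtype=float)
        if self.q.shape != self.a_net.shape or self.q.ndim != 1:
            raise ValueError("q and a_net must be 1-D vectors of equal length")
        if len(self.q) < 5:
            raise ValueError("an A-Q curve needs at least 5 light levels")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")


@dataclass
class FvCBFit:
    estimates: FvCBParams
    ci_transition_c_to_j: float
    ci_transition_j_to_p: float | None
    limitation_state: list[str]  # per observation: "Ac" | "Aj" | "Ap"
    rmse: float
    tpu_active: bool
    sse: float = field(default=np.nan)


@dataclass
class AqFit:
    phi: float  # mol CO2 mol⁻¹ photons
    asat_gross: float  # µmol m⁻² s⁻¹
    theta: float  # curvature, (0, 1]
    r_l: float  # respiration in the light, µmol m⁻² s⁻¹
    rmse: float
    phi_exceeds_theory: bool = False


@dataclass
class SLResult:
    sl: float
    a_at_ca: float
    a_operating: float


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _fvcb_states(ci: np.ndarray, p: FvCBParams) -> tuple[np.ndarray, np.ndarray]:
    """Gross assimilation and limitation state (0=Ac, 1=Aj, 2=Ap).

    The limiting process is chosen on the carboxylation rates
    Wc = Vcmax·Ci/(Ci + Km) and Wj = J·Ci/(4Ci + 8Γ*); gross
    assimilation is (1 − Γ*/Ci)·min(Wc, Wj), capped by the TPU ceiling
    3·TPU.  Above Γ* this is identical to taking min(Ac, Aj) on the
    net expressions; below Γ* it keeps the Rubisco-limited branch (the
    naive min would switch to Aj merely because it is more negative).
    """
    wc = p.vcmax * ci / (ci + p.km)
    wj = p.jmax * ci / (4.0 * ci + 8.0 * p.gamma_star)
    scale = 1.0 - p.gamma_star / ci
    gross = scale * np.minimum(wc, wj)
    state = np.where(wc <= wj, 0, 1)
    if p.tpu is not None:
        cap = 3.0 * p.tpu
        state = np.where(gross > cap, 2, state)
        gross = np.minimum(gross, cap)
    return gross, state


def fvcb_forward(ci, params: FvCBParams):
    """Net assimilation min(Ac, Aj, Ap) − Rd at intercellular CO2 ``ci``.

    Ac = Vcmax·(Ci−Γ*)/(Ci + Kc(1+O/Ko)), Aj = J·(Ci−Γ*)/(4Ci + 8Γ*)
    with J = Jmax (saturating light, matching a 1800 µmol m⁻² s⁻¹ PAR
    protocol) and Ap = 3·TPU; the limiting branch is selected on the
    carboxylation rates (see :func:`_fvcb_states`).  Scalar in, scalar
    out.
    """
    ci_arr = np.atleast_1d(np.asarray(ci, dtype=float))
    if np.any(ci_arr <= 0):
        raise ValueError("ci must be strictly positive")
    gross, _ = _fvcb_states(ci_arr, params)
    a = gross - params.rd
    return a[0] if np.isscalar(ci) or np.ndim(ci) == 0 else a


def fvcb_limitation(ci, params: FvCBParams) -> list[str]:
    """Which process limits assimilation at each ``ci`` ("Ac"/"Aj"/"Ap")."""
    ci_arr = np.atleast_1d(np.asarray(ci, dtype=float))
    _, state = _fvcb_states(ci_arr, params)
    return [("Ac", "Aj", "Ap")[int(i)] for i in state]


def nrh_forward(q, phi: float, asat_gross: float, theta: float, r_l: float):
    """Non-rectangular hyperbola light response.

    A(Q) = [φQ + As − sqrt((φQ + As)² − 4θφQAs)] / (2θ) − R_L, with the
    θ→0 limit handled as the rectangular hyperbola.
    """
    q = np.asarray(q, dtype=float)
    pq = phi * q
    if theta < 1e-9:
        gross = pq * asat_gross / np.where(pq + asat_gross > 0, pq + asat_gross, 1.0)
    else:
        s = pq + asat_gross
        disc = np.maximum(s * s - 4.0 * theta * pq * asat_gross, 0.0)
        gross = (s - np.sqrt(disc)) / (2.0 * theta)
    return gross - r_l


# ---------------------------------------------------------------------------
# A-Ci fitting (bilinear method)
# ---------------------------------------------------------------------------

def _segment_lstsq(
    ci: np.ndarray,
    a: np.ndarray,
    state: np.ndarray,
    constants: FvCBParams,
    fit_rd: bool,
    rd_fixed: float,
) -> tuple[dict, float] | None:
    """Linear least squares for one assignment of points to segments.

    ``state``: integer per point, 0 = Ac, 1 = Aj, 2 = Ap.  Solves for
    (Vcmax, Jmax[, TPU][, Rd]) with non-negativity bounds; returns the
    parameter dict and the SSE, or None if the system is degenerate.
    """
    km = constants.km
    gs = constants.gamma_star
    x_c = (ci - gs) / (ci + km)
    x_j = (ci - gs) / (4.0 * ci + 8.0 * gs)

    has_tpu = bool(np.any(state == 2))
    cols = [np.where(state == 0, x_c, 0.0), np.where(state == 1, x_j, 0.0)]
    if has_tpu:
        cols.append(np.where(state == 2, 3.0, 0.0))
    rhs = a.astype(float)
    if fit_rd:
        cols.append(-np.ones_like(rhs))
    else:
        rhs = rhs + rd_fixed
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return None
    res = optimize.lsq_linear(design, rhs, bounds=(0.0, np.inf), method="bvls")
    sse = float(2.0 * res.cost)
    sol = res.x
    out = {"vcmax": sol[0], "jmax": sol[1]}
    k = 2
    if has_tpu:
        out["tpu"] = sol[k]
        k += 1
    out["rd"] = sol[k] if fit_rd else rd_fixed
    return out, sse


def _candidate_splits(order_ci: np.ndarray, lo: int, hi: int) -> list[int]:
    """Split indices k (first point of the upper segment) in [lo, hi]
    skipping ties so that equal Ci values are never separated."""
    return [
        k for k in range(lo, hi + 1)
        if order_ci[k] > order_ci[k - 1]
    ]


def fit_aci(
    curve: AciCurve,
    constants: FvCBParams | None = None,
    fit_rd: bool = True,
    rd_fixed: float = 1.5,
    tpu_noise_sd: float = 0.5,
) -> FvCBFit:
    """Fit the FvCB model to an A–Ci curve by the bilinear method.

    Candidate Ci transition points are enumerated between consecutive
    distinct sorted observations; each candidate assignment is fitted by
    (bounded) linear least squares on the Rubisco- and RuBP-limited
    transforms with a shared Rd, and the assignment with minimum SSE is
    selected.  A TPU segment is added only when the TPU-detection rule
    triggers: the two highest-Ci residuals of the two-segment fit are
    both negative and their mean shortfall exceeds one noise SD
    (``tpu_noise_sd``).

    ``constants`` supplies Γ*, Kc, Ko and O (Bernacchi 25°C defaults);
    its rate entries are ignored.
    """
    if constants is None:
        constants = FvCBParams(vcmax=1, jmax=1, rd=0)
    n = len(curve.ci)
    if n < 5:
        raise FitError("need at least 5 usable observations")

    order = np.argsort(curve.ci, kind="stable")
    ci = curve.ci[order]
    a = curve.a_net[order]

    # --- stage 1: two-segment (Ac | Aj) enumeration --------------------
    best: tuple[float, dict, np.ndarray] | None = None
    for k in _candidate_splits(ci, 3, n - 2):  # ≥3 below, ≥2 above
        state = np.where(np.arange(n) < k, 0, 1)
        fitted = _segment_lstsq(ci, a, state, constants, fit_rd, rd_fixed)
        if fitted is None:
            continue
        params, sse = fitted
        if best is None or sse < best[0]:
            best = (sse, params, state)
    if best is None:
        raise FitError("no admissible transition point (degenerate curve)")
    sse2, params2, state2 = best

    # --- TPU detection rule on the two-segment fit ---------------------
    p2 = FvCBParams(
        vcmax=params2["vcmax"], jmax=params2["jmax"], rd=params2["rd"],
        gamma_star=constants.gamma_star, kc=constants.kc,
        ko=constants.ko, o=constants.o,
    )
    resid2 = a - np.asarray(fvcb_forward(ci, p2))
    top2 = resid2[-2:]
    # A TPU plateau misfit by the Aj line leaves the highest-Ci point
    # overshot by the fit; either signature (joint shortfall, or a
    # single > 1-SD undershoot at the top) opens the TPU stage.
    tpu_triggered = bool(
        (np.all(top2 < 0) and (-top2.mean() > tpu_noise_sd))
        or (top2.min() < -tpu_noise_sd)
    )

    sse_best, params_best, state_best = sse2, params2, state2
    tpu_active = False
    if tpu_triggered:
        for k1 in _candidate_splits(ci, 3, n - 4):
            for k2 in _candidate_splits(ci, max(k1 + 2, 4), n - 2):
                # Ac: [0,k1), Aj: [k1,k2), Ap: [k2,n) — ≥2 Aj, ≥2 Ap points
                state = np.zeros(n, dtype=int)
                state[k1:k2] = 1
                state[k2:] = 2
                fitted = _segment_lstsq(ci, a, state, constants, fit_rd, rd_fixed)
                if fitted is None:
                    continue
                params, sse = fitted
                if params.get("tpu", 0.0) <= 0:
                    continue
                # guard against chance plateaus: require a real improvement
                if sse < sse_best - tpu_noise_sd ** 2:
                    sse_best, params_best, state_best = sse, params, state
                    tpu_active = True

    if params_best["vcmax"] < 1e-6 or params_best["jmax"] < 1e-6:
        raise FitError(
            "bilinear solution hit a non-positive Vcmax/Jmax bound; "
            "curve flagged as a failed fit"
        )

    estimates = FvCBParams(
        vcmax=params_best["vcmax"],
        jmax=params_best["jmax"],
        rd=params_best["rd"],
        tpu=params_best.get("tpu") if tpu_active else None,
        gamma_star=constants.gamma_star,
        kc=constants.kc,
        ko=constants.ko,
        o=constants.o,
    )

    # transitions halfway between the bracketing observations
    k_cj = int(np.searchsorted(state_best, 1))
    ci_cj = 0.5 * (ci[k_cj - 1] + ci[k_cj]) if 0 < k_cj < n else float(ci[-1])
    ci_jp = None
    if tpu_active:
        k_jp = int(np.searchsorted(state_best, 2))
        ci_jp = 0.5 * (ci[k_jp - 1] + ci[k_jp])

    pred = np.asarray(fvcb_forward(ci, estimates))
    rmse = float(np.sqrt(np.mean((a - pred) ** 2)))

    # report limitation states in the original observation order
    labels = np.array(["Ac", "Aj", "Ap"])[state_best]
    back = np.empty(n, dtype=object)
    back[order] = labels
    return FvCBFit(
        estimates=estimates,
        ci_transition_c_to_j=float(ci_cj),
        ci_transition_j_to_p=ci_jp,
        limitation_state=list(back),
        rmse=rmse,
        tpu_active=tpu_active,
        sse=float(sse_best),
    )


def stomatal_limitation(fit: FvCBFit, ca: float, a_operating: float) -> SLResult:
    """Stomatal limitation SL = (A(Ci=Ca) − A_operating) / A(Ci=Ca).

    A(Ci=Ca) is the assimilation the fitted FvCB model predicts at
    infinite stomatal conductance (intercellular CO2 equal to ambient).
    """
    if ca <= 0:
        raise ValueError("ca must be positive")
    a_at_ca = float(fvcb_forward(ca, fit.estimates))
    if a_at_ca <= 0:
        raise FitError("assimilation at Ci = Ca is non-positive; SL undefined")
    return SLResult(sl=(a_at_ca - a_operating) / a_at_ca,
                    a_at_ca=a_at_ca, a_operating=a_operating)


# ---------------------------------------------------------------------------
# A-Q fitting
# ---------------------------------------------------------------------------

def fit_aq(curve: AqCurve, theta_starts: Sequence[float] = (0.3, 0.6, 0.9)) -> AqFit:
    """Fit the non-rectangular hyperbola to a light-response curve.

    Multi-start nonlinear least squares over the curvature starts in
    ``theta_starts``; the best converged start wins.  φ is bounded by
    its theoretical maximum of 0.125 mol CO2 mol⁻¹ photons; a fit
    pinned at that bound is flagged.
    """
    q, a = curve.q, curve.a_net
    if q.max() <= 0 or q.max() / max(q[q > 0].min(), 1e-9) < 10:
        raise FitError("light levels must span at least one order of magnitude")

    a_span = max(a.max() - a.min(), 1e-3)
    phi0 = min(max((a.max() - a.min()) / max(q.max(), 1.0) * 2.0, 1e-3), 0.1)
    r0 = max(-a.min(), 0.1)
    best = None
    errs = []
    for th0 in theta_starts:
        try:
            popt, _ = optimize.curve_fit(
                nrh_forward, q, a,
                p0=[phi0, a.max() + r0, th0, r0],
                bounds=([1e-6, 1e-3, 1e-6, 0.0],
                        [PHI_MAX_THEORY, 10.0 * (a.max() + r0 + a_span), 1.0, 50.0]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # no convergence for this start
            errs.append(f"theta0={th0}: {exc}")
            continue
        sse = float(np.sum((a - nrh_forward(q, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("A-Q fit failed for every start: " + "; ".join(errs))
    sse, (phi, asat, theta, r_l) = best
    return AqFit(
        phi=float(phi),
        asat_gross=float(asat),
        theta=float(theta),
        r_l=float(r_l),
        rmse=float(np.sqrt(sse / len(q))),
        phi_exceeds_theory=bool(phi >= PHI_MAX_THEORY - 1e-9),
    )
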