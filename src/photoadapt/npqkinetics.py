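"""NPQ induction/relaxation and ΦPSII recovery kinetics.

Pulse-amplitude-modulated fluorescence traces are converted into
non-photochemical quenching (NPQ) and PSII operating efficiency
(ΦPSII) series:

    NPQ(t)    = Fm / Fm'(t) − 1
    ΦPSII(t)  = (Fm'(t) − Fs(t)) / Fm'(t)
    Fv/Fm     = (Fm − F0) / Fm

The light phase (actinic on, default 0–600 s) is summarised by a
linear initial slope plus a saturating exponential
``NPQ(t) = A·(1 − exp(−k·t))``; the dark phase (default 600–1400 s,
time re-zeroed at light-off) by an exponential decay with offset
``NPQ(t′) = A·exp(−k·t′) + c`` for NPQ and a saturating recovery
``ΦPSII(t′) = c + A·(1 − exp(−k·t′))`` for ΦPSII.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "FluorTrace",
    "NpqKineticFit",
    "derive_series",
    "fit_induction",
    "fit_relaxation",
    "fit_trace",
]

#: multi-start grid for the exponential rate constants (s⁻¹)
RATE_STARTS = (0.001, 0.01, 0.1)

#: window (s from light-on) for the linear initial NPQ slope
LINEAR_WINDOW_S = 60.0


@dataclass
class FluorTrace:
    """One induction–relaxation fluorescence trace.

    ``fs`` and ``fm_prime`` are sampled at the saturating-pulse times in
    ``time`` (seconds since actinic light on).  ``fm_dark``/``f0_dark``
    are the dark-adapted maxima/minima measured before the light phase.
    """

    time: np.ndarray
    fs: np.ndarray
    fm_prime: np.ndarray
    fm_dark: float
    f0_dark: float
    actinic_on: float = 0.0
    actinic_off: float = 600.0
    end: float = 1400.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fs = np.asarray(self.fs, dtype=float)
        self.fm_prime = np.asarray(self.fm_prime, dtype=float)
        if not (self.time.shape == self.fs.shape == self.fm_prime.shape):
            raise ValueError("time, fs and fm_prime must have equal shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.fm_dark > self.f0_dark > 0):
            raise ValueError("need fm_dark > f0_dark > 0")


@dataclass
class NpqKineticFit:
    """All light-dependent-reaction kinetic traits from one trace."""

    npq_linear: float
    ind_amp: float
    ind_rate: float
    rel_amp: float
    rel_rate: float
    rel_res: float
    rec_amp: float
    rec_rate: float
    rec_res: float
    max_npq: float
    final_npq: float
    final_phipsii: float
    fv_fm: float
    flags: list[str] = field(default_factory=list)


def derive_series(trace: FluorTrace):
    """Convert a fluorescence trace into (time, NPQ, ΦPSII, Fv/Fm).

    Points with non-positive Fm' are dropped with a warning; if more
    than 20% of points are dropped the trace is rejected.
    """
    ok = trace.fm_prime > 0
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} pulse(s) with non-positive Fm'")
        if n_bad > 0.2 * len(ok):
            raise ValueError("more than 20% of pulses unusable")
    t = trace.time[ok]
    fmp = trace.fm_prime[ok]
    fs = trace.fs[ok]
    npq = trace.fm_dark / fmp - 1.0
    phipsii = (fmp - fs) / fmp
    fv_fm = (trace.fm_dark - trace.f0_dark) / trace.fm_dark
    return t, npq, phipsii, fv_fm


def _exp_saturating(t, amp, rate):
    return amp * (1.0 - np.exp(-rate * t))


def _exp_decay(t, amp, rate, res):
    return amp * np.exp(-rate * t) + res


def _exp_recovery(t, res, amp, rate):
    return res + amp * (1.0 - np.exp(-rate * t))


def _multistart_fit(model, t, y, p0_grid, bounds):
    best = None
    for p0 in p0_grid:
        try:
            popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                         maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    return None if best is None else best[1]


def fit_induction(t: np.ndarray, npq: np.ndarray,
                  linear_window: float = LINEAR_WINDOW_S):
    """Fit the light-phase NPQ series (t in seconds since light-on).

    Returns (npq_linear, ind_amp, ind_rate, max_npq, final_npq, flags).
    The linear slope is the least-squares slope over the first
    ``linear_window`` seconds including the definitional origin
    (NPQ = 0 at light-on); it is always computable.  The exponential
    amplitude/rate are multi-start nonlinear LS and are flagged (NaN)
    when the series carries no induction signal.
    """
    t = np.asarray(t, dtype=float)
    npq = np.asarray(npq, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 light-phase points")
    flags: list[str] = []

    # linear initial slope through the origin window
    win = t <= linear_window
    tw = np.concatenate([[0.0], t[win]])
    yw = np.concatenate([[0.0], npq[win]])
    npq_linear = float(np.polyfit(tw, yw, 1)[0]) if len(tw) >= 2 else 0.0

    max_npq = float(np.max(npq))
    final_npq = float(npq[-1])

    if np.ptp(npq) < 1e-12:  # no induction signal at all
        flags.append("induction_fit_failed")
        ind_amp, ind_rate = np.nan, np.nan
    else:
        amp0 = max(max_npq, 1e-6)
        grid = [(amp0, r) for r in RATE_STARTS]
        popt = _multistart_fit(_exp_saturating, t, npq, grid,
                               ([0.0, 1e-6], [10.0 * amp0 + 1.0, 10.0]))
        if popt is None or popt[0] < 1e-8:
            flags.append("induction_fit_failed")
            ind_amp, ind_rate = np.nan, np.nan
        else:
            ind_amp, ind_rate = float(popt[0]), float(popt[1])
    return npq_linear, ind_amp, ind_rate, max_npq, final_npq, flags


def fit_relaxation(t_dark: np.ndarray, npq: np.ndarray, phipsii: np.ndarray):
    """Fit the dark-phase NPQ decay and ΦPSII recovery.

    ``t_dark`` is re-zeroed at light-off.  Returns
    (rel_amp, rel_rate, rel_res, rec_amp, rec_rate, rec_res, flags).
    """
    t = np.asarray(t_dark, dtype=float)
    npq = np.asarray(npq, dtype=float)
    phipsii = np.asarray(phipsii, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 dark-phase points")
    flags: list[str] = []

    span = max(float(npq.max() - npq.min()), 0.0)
    amp0 = max(span, 1e-6)
    res0 = float(npq.min())
    grid = [(amp0, r, res0) for r in RATE_STARTS]
    popt = _multistart_fit(
        _exp_decay, t, npq, grid,
        ([0.0, 1e-6, 0.0], [10.0 * amp0 + 1.0, 10.0, max(npq.max(), 1e-6)]),
    )
    if popt is None:
        flags.append("relaxation_fit_failed")
        rel_amp = rel_rate = rel_res = np.nan
    else:
        rel_amp, rel_rate, rel_res = map(float, popt)
        if rel_amp < 1e-8:  # constant series: amplitude 0, offset = level
            rel_rate = np.nan
            flags.append("relaxation_amplitude_zero")

    pspan = max(float(phipsii.max() - phipsii.min()), 1e-6)
    grid_p = [(float(phipsii[0]), pspan, r) for r in RATE_STARTS]
    popt_p = _multistart_fit(
        _exp_recovery, t, phipsii, grid_p,
        ([0.0, 0.0, 1e-6], [1.0, 1.0, 10.0]),
    )
    if popt_p is None:
        flags.append("recovery_fit_failed")
        rec_res = rec_amp = rec_rate = np.nan
    else:
        rec_res, rec_amp, rec_rate = map(float, popt_p)
    return rel_amp, rel_rate, rel_res, rec_amp, rec_rate, rec_res, flags


def fit_trace(trace: FluorTrace, linear_window: float = LINEAR_WINDOW_S) -> NpqKineticFit:
    """Full kinetic summary of one trace (light + dark phases)."""
    t, npq, phipsii, fv_fm = derive_series(trace)
    light = t <= trace.actinic_off
    dark = t > trace.actinic_off
    if light.sum() < 4 or dark.sum() < 4:
        raise ValueError("need at least 4 pulses in each phase")

    npq_linear, ind_amp, ind_rate, max_npq, final_npq, fl1 = fit_induction(
        t[light], npq[light], linear_window=linear_window)
    final_phipsii = float(phipsii[light][-1])
    rel_amp, rel_rate, rel_res, rec_amp, rec_rate, rec_res, fl2 = fit_relaxation(
        t[dark] - trace.actinic_off, npq[dark], phipsii[dark])

    return NpqKineticFit(
        npq_linear=npq_linear, ind_amp=ind_amp, ind_rate=ind_rate,
        rel_amp=rel_amp, rel_rate=rel_rate, rel_res=rel_res,
        rec_amp=rec_amp, rec_rate=rec_rate, rec_res=rec_res,
        max_npq=max_npq, final_npq=final_npq,
        final_phipsii=final_phipsii, fv_fm=fv_fm,
        flags=fl1 + fl2,
    )
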