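"""Nonlinear least-squares estimators for multi-echo UTE decay curves.

Three fitters cover the three acquisition protocols:

* :func:`fit_abbreviated` -- the abbreviated paradigm: baseline fixed to the
  mean of the late (TE2) echoes, then a two-parameter bounded least-squares
  fit of the baseline-corrected mono-exponential model to the sub-millisecond
  (TE1) echoes.
* :func:`fit_biexp` -- conventional four-parameter bi-exponential fit of a
  full-coverage echo train, implemented by variable projection (the two pool
  amplitudes are solved linearly for each candidate pair of relaxation times)
  with a multi-start over a log-spaced (t2s, t2l) lattice.
* :func:`fit_t2l_monoexp` -- mono-exponential fit of late echoes from the
  variable-TE protocol to estimate the long component alone.

Estimates carry a ``flags`` tuple; a non-empty tuple marks a boundary-pinned
or otherwise suspect solution rather than failing silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal_model import EchoSchedule

__all__ = [
    "DecayCurve",
    "ApparentEstimate",
    "BiexpEstimate",
    "estimate_baseline",
    "fit_abbreviated",
    "fit_biexp",
    "fit_t2l_monoexp",
    "FitError",
]

# bounds for the abbreviated two-parameter fit
T2S_APP_BOUNDS = (0.05, 10.0)  # ms
FBW_APP_BOUNDS = (0.0, 0.9999)

# bounds for the bi-exponential fit
T2S_BOUNDS = (0.05, 5.0)  # ms
T2L_BOUNDS = (5.0, 100.0)  # ms
_T2S_STARTS = (0.3, 1.0, 3.0)
_T2L_STARTS = (10.0, 30.0)

_LS_OPTS = dict(xtol=1e-12, ftol=1e-12, gtol=1e-12)


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted or no start converges."""


@dataclass(frozen=True)
class DecayCurve:
    """A measured (or simulated) magnitude decay curve: TE -> signal."""

    tes: np.ndarray
    signals: np.ndarray
    schedule_ref: str = ""

    def __post_init__(self) -> None:
        tes = np.atleast_1d(np.asarray(self.tes, dtype=float))
        sig = np.atleast_1d(np.asarray(self.signals, dtype=float))
        if tes.shape != sig.shape:
            raise ValueError("tes and signals must have equal length")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("tes must be strictly ascending")
        if np.any(sig < 0):
            raise ValueError("signals must be non-negative")
        object.__setattr__(self, "tes", tes)
        object.__setattr__(self, "signals", sig)

    def subset(self, tes) -> "DecayCurve":
        """Restrict the curve to the given echo times (must all be present)."""
        want = np.atleast_1d(np.asarray(tes, dtype=float))
        idx = []
        for t in want:
            hit = np.flatnonzero(np.isclose(self.tes, t))
            if hit.size == 0:
                raise ValueError(f"echo time {t} ms not present in curve")
            idx.append(hit[0])
        idx = np.sort(np.array(idx))
        return DecayCurve(self.tes[idx], self.signals[idx], self.schedule_ref)


@dataclass(frozen=True)
class ApparentEstimate:
    """Output of the abbreviated baseline-corrected mono-exponential fit."""

    t2s_app: float
    f_bw_app: float
    baseline: float
    amplitude: float
    rss: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BiexpEstimate:
    """Output of the conventional four-parameter bi-exponential fit."""

    s0: float
    f_bw: float
    t2s: float
    t2l: float
    rss: float
    flags: tuple[str, ...] = ()


def estimate_baseline(curve: DecayCurve) -> float:
    """Baseline as the arithmetic mean of the late-echo (TE2) signals."""
    if curve.signals.size == 0:
        raise FitError("empty TE2 set: cannot estimate baseline")
    return float(np.mean(curve.signals))


def _pinned(value: float, lo: float, hi: float, rtol: float = 1e-4) -> bool:
    span = hi - lo
    return value - lo < rtol * span or hi - value < rtol * span


def fit_abbreviated(curve: DecayCurve, schedule: EchoSchedule) -> ApparentEstimate:
    """Fit the baseline-corrected mono-exponential model to an abbreviated curve.

    The baseline is fixed to the mean signal of the schedule's TE2 echoes; the
    apparent relaxation time ``t2s_app`` and apparent bound-water fraction
    ``f_bw_app`` are then found by bounded least squares on the TE1 echoes
    against ``baseline/(1 - f_bw_app) * exp(-TE/t2s_app) + baseline``.

    Initialization is deterministic: ``t2s_app`` from the two-point log-slope
    of the first/last baseline-subtracted TE1 signals (clamped to [0.1, 5] ms),
    ``f_bw_app`` from the amplitude implied by the first TE1 signal.
    Boundary-pinned solutions are flagged, not rejected.
    """
    te1 = schedule.te1_array
    y1 = curve.subset(te1).signals
    baseline = estimate_baseline(curve.subset(schedule.te2_array))
    if baseline <= 0:
        raise FitError("non-positive baseline")
    if np.any(y1 <= 0):
        raise FitError("non-positive TE1 signals")

    d = y1 - baseline
    eps = 1e-12
    slope_num = max(np.log(max(d[0], eps) / max(d[-1], eps)), 1e-6)
    t2s0 = float(np.clip((te1[-1] - te1[0]) / slope_num, 0.1, 5.0))
    amp0 = max(d[0], eps)
    f0 = float(np.clip(1.0 - baseline / max(amp0, baseline * (1 + 1e-3)), 1e-3, 0.99))

    def resid(p):
        f, t2s = p
        return baseline / (1.0 - f) * np.exp(-te1 / t2s) + baseline - y1

    res = least_squares(
        resid,
        x0=[f0, t2s0],
        bounds=([FBW_APP_BOUNDS[0], T2S_APP_BOUNDS[0]], [FBW_APP_BOUNDS[1], T2S_APP_BOUNDS[1]]),
        **_LS_OPTS,
    )
    if not res.success:
        raise FitError("abbreviated fit did not converge")
    f_bw_app, t2s_app = res.x
    flags = []
    if _pinned(t2s_app, *T2S_APP_BOUNDS):
        flags.append("t2s_app_at_bound")
    if _pinned(f_bw_app, *FBW_APP_BOUNDS):
        flags.append("f_bw_app_at_bound")
    return ApparentEstimate(
        t2s_app=float(t2s_app),
        f_bw_app=float(f_bw_app),
        baseline=float(baseline),
        amplitude=float(baseline / (1.0 - f_bw_app)),
        rss=float(2.0 * res.cost),
        flags=tuple(flags),
    )


def _varpro_resid(logp, te, y):
    t2s, t2l = np.exp(logp)
    M = np.stack([np.exp(-te / t2s), np.exp(-te / t2l)], axis=1)
    amps, *_ = np.linalg.lstsq(M, y, rcond=None)
    return M @ amps - y


def fit_biexp(
    curve: DecayCurve,
    x0: tuple[float, float] | None = None,
    drop_te: float | None = None,
) -> BiexpEstimate:
    """Four-parameter bi-exponential fit by variable projection.

    For each candidate pair of relaxation times the two pool amplitudes are
    the exact linear least-squares solution, so only (t2s, t2l) are optimized
    (in log space, bounded).  A log-spaced multi-start lattice guards against
    the multi-modality of multi-exponential fitting; pass ``x0 = (t2s, t2l)``
    to use a single warm start instead.  ``drop_te`` removes one echo (e.g.
    the 20 ms echo, discarded in vivo for low SNR) before fitting.
    """
    te, y = curve.tes, curve.signals
    if drop_te is not None:
        keep = ~np.isclose(te, drop_te)
        te, y = te[keep], y[keep]
    if np.unique(te).size < 6:
        raise FitError("bi-exponential fit needs >= 6 distinct echo times")

    lb = np.log([T2S_BOUNDS[0], T2L_BOUNDS[0]])
    ub = np.log([T2S_BOUNDS[1], T2L_BOUNDS[1]])
    starts = (
        [(float(np.clip(x0[0], *T2S_BOUNDS)), float(np.clip(x0[1], *T2L_BOUNDS)))]
        if x0 is not None
        else [(a, b) for a in _T2S_STARTS for b in _T2L_STARTS]
    )
    best = None
    for s in starts:
        try:
            res = least_squares(
                _varpro_resid, np.log(s), bounds=(lb, ub), args=(te, y), **_LS_OPTS
            )
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("all bi-exponential starts failed")

    t2s, t2l = np.exp(best.x)
    M = np.stack([np.exp(-te / t2s), np.exp(-te / t2l)], axis=1)
    amps, *_ = np.linalg.lstsq(M, y, rcond=None)
    if t2s > t2l:
        t2s, t2l = t2l, t2s
        amps = amps[::-1]
    s0 = float(amps.sum())
    flags = []
    if s0 <= 0:
        flags.append("nonpositive_s0")
        f_bw = float("nan")
    else:
        f_bw = float(amps[0] / s0)
    if np.any(amps < 0):
        flags.append("negative_amplitude")
    if _pinned(t2s, *T2S_BOUNDS):
        flags.append("t2s_at_bound")
    if _pinned(t2l, *T2L_BOUNDS):
        flags.append("t2l_at_bound")
    return BiexpEstimate(
        s0=s0,
        f_bw=f_bw,
        t2s=float(t2s),
        t2l=float(t2l),
        rss=float(2.0 * best.cost),
        flags=tuple(flags),
    )


def fit_t2l_monoexp(curve: DecayCurve, min_te: float = 3.0):
    """Long-component relaxation time from a mono-exponential fit of late echoes.

    Echoes below ``min_te`` (default 3 ms) are excluded so that a fast
    component with T2s* <= 2 ms has decayed by >= ~78% before the first
    included echo.  Fits ``C * exp(-TE/t2l)`` by bounded least squares,
    initialized from the closed-form log-linear regression.

    Returns ``(t2l, flags)``; a non-decaying input pins t2l at the upper
    bound and is flagged.
    """
    keep = curve.tes >= min_te
    te, y = curve.tes[keep], curve.signals[keep]
    if te.size < 3:
        raise FitError("need at least 3 echoes at or above min_te")
    if np.any(y <= 0):
        raise FitError("non-positive signals in long-component fit")

    slope, logc = np.polyfit(te, np.log(y), 1)
    t2l0 = float(np.clip(-1.0 / slope if slope < 0 else T2L_BOUNDS[1], *T2L_BOUNDS))
    c0 = float(np.exp(logc))

    def resid(p):
        c, t2l = p
        return c * np.exp(-te / t2l) - y

    res = least_squares(
        resid,
        x0=[c0, t2l0],
        bounds=([0.0, T2L_BOUNDS[0]], [np.inf, T2L_BOUNDS[1]]),
        **_LS_OPTS,
    )
    if not res.success:
        raise FitError("long-component fit did not converge")
    t2l = float(res.x[1])
    flags = ("t2l_at_bound",) if _pinned(t2l, *T2L_BOUNDS) else ()
    return t2l, flags
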