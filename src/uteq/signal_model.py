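"""Forward models for bicomponent UTE signal decay and the protocol echo schedules.

Magnitude UTE signal from collagen-rich tissue is modelled as the sum of a
fast-decaying, collagen-bound water pool (effective relaxation time ``T2s*``,
sub-millisecond to ~2 ms) and a slow free-water pool (``T2l*``, ~15-25 ms).
Two forward models are provided:

* :func:`biexp_signal` -- the standard bi-exponential decay,
  ``S(TE) = S0 [ f_bw exp(-TE/T2s*) + (1 - f_bw) exp(-TE/T2l*) ]``;
* :func:`abbreviated_signal` -- the baseline-corrected mono-exponential model
  used by the abbreviated protocol,
  ``S(TE) = baseline/(1 - f_bw,app) exp(-TE/T2s,app*) + baseline``,
  which treats the slow pool as a constant offset over sub-millisecond TEs.

All times are milliseconds; signals are arbitrary units (S0 defaults to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EchoSchedule",
    "TissueParams",
    "biexp_signal",
    "abbreviated_signal",
    "standard_schedules",
]


@dataclass(frozen=True)
class EchoSchedule:
    """Ordered echo times of a UTE protocol.

    ``te1`` holds the sub-millisecond echoes used to fit the fast component,
    ``te2`` the late echoes used to estimate the constant baseline.  For
    single-train protocols (e.g. the variable-TE gradient echo used for the
    long component) ``te2`` may be empty.
    """

    name: str
    te1: tuple[float, ...]
    te2: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        te1 = tuple(float(t) for t in self.te1)
        te2 = tuple(float(t) for t in self.te2)
        object.__setattr__(self, "te1", te1)
        object.__setattr__(self, "te2", te2)
        if not te1:
            raise ValueError("schedule needs at least one TE1 echo")
        for seq, lbl in ((te1, "te1"), (te2, "te2")):
            if any(t <= 0 for t in seq):
                raise ValueError(f"{lbl} echo times must be positive")
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{lbl} echo times must be strictly ascending")

    @property
    def all_tes(self) -> np.ndarray:
        """All echo times, ascending."""
        return np.sort(np.array(self.te1 + self.te2, dtype=float))

    @property
    def te1_array(self) -> np.ndarray:
        return np.asarray(self.te1, dtype=float)

    @property
    def te2_array(self) -> np.ndarray:
        return np.asarray(self.te2, dtype=float)


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth bi-exponential tissue parameters.

    s0
        TE=0 signal, arbitrary units (> 0).
    f_bw
        Bound-water signal fraction at TE=0, in (0, 1).
    t2s, t2l
        Fast / slow effective transverse relaxation times in ms, 0 < t2s < t2l.
    """

    s0: float = 1.0
    f_bw: float = 0.85
    t2s: float = 1.4
    t2l: float = 20.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if not 0 < self.f_bw < 1:
            raise ValueError("f_bw must lie in (0, 1)")
        if not 0 < self.t2s < self.t2l:
            raise ValueError("need 0 < t2s < t2l")


def biexp_signal(params: TissueParams, te):
    """Bi-exponential magnitude signal at echo time(s) ``te`` (ms).

    Vectorized over ``te``; returns a scalar for scalar input.
    """
    te_arr = np.asarray(te, dtype=float)
    if np.any(te_arr < 0):
        raise ValueError("echo times must be non-negative")
    out = params.s0 * (
        params.f_bw * np.exp(-te_arr / params.t2s)
        + (1.0 - params.f_bw) * np.exp(-te_arr / params.t2l)
    )
    return out if out.ndim else float(out)


def abbreviated_signal(t2s_app: float, f_bw_app: float, baseline: float, te):
    """Baseline-corrected mono-exponential signal at echo time(s) ``te`` (ms).

    The amplitude of the decaying term is ``baseline / (1 - f_bw_app)``, so the
    apparent bound-water fraction is recovered from a fitted amplitude ``A`` as
    ``f_bw_app = 1 - baseline / A``.
    """
    if not 0 < f_bw_app < 1:
        raise ValueError("f_bw_app must lie in (0, 1)")
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    te_arr = np.asarray(te, dtype=float)
    if np.any(te_arr < 0):
        raise ValueError("echo times must be non-negative")
    amp = baseline / (1.0 - f_bw_app)
    out = amp * np.exp(-te_arr / t2s_app) + baseline
    return out if out.ndim else float(out)


def standard_schedules() -> dict[str, EchoSchedule]:
    """The three acquisition presets: abbreviated, full and vTE.

    * ``abbreviated`` -- three double-echo UTE pairs, TE1/TE2 of
      0.1/4.0, 0.27/5.0, 0.5/6.0 ms (fast-component fitting protocol).
    * ``full`` -- five pairs, TE1/TE2 of 0.1/4.0, 0.27/7.0, 0.5/10.0,
      1.0/14.0, 2.0/20.0 ms (conventional bi-exponential protocol).
    * ``vte`` -- variable-TE gradient echo, TEs 0.88, 3.24, 5.37, 7.5,
      10, 13, 19 ms (long-component estimation).
    """
    return {
        "abbreviated": EchoSchedule(
            "abbreviated", te1=(0.1, 0.27, 0.5), te2=(4.0, 5.0, 6.0)
        ),
        "full": EchoSchedule(
            "full", te1=(0.1, 0.27, 0.5, 1.0, 2.0), te2=(4.0, 7.0, 10.0, 14.0, 20.0)
        ),
        "vte": EchoSchedule("vte", te1=(0.88, 3.24, 5.37, 7.5, 10.0, 13.0, 19.0)),
    }
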