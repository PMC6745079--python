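"""Monte-Carlo comparison of the bias-corrected abbreviated estimator with
full bi-exponential fitting across SNR levels.

For each ground-truth node of a clinical parameter grid, noiseless curves are
rendered on the abbreviated and full echo schedules, additive zero-mean
Gaussian noise with per-echo standard deviation S0/SNR is drawn per replicate,
and both pipelines are run:

* abbreviated: baseline-corrected mono-exponential fit, then polynomial bias
  correction (calibrated at T2l* = 20 ms);
* full: conventional bi-exponential fit.

Errors are absolute percent deviations from truth, averaged over grid nodes
and replicates.  Gaussian (not Rician) noise is the default: at the studied
SNR levels (>= 200 after ROI averaging) the magnitude-bias difference is
negligible; a Rician option exists for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias_calibration import (
    SNR_STUDY_FBW_RANGE,
    CorrectionModel,
    apply_correction,
    clinical_grid_axes,
)
from .estimation import DecayCurve, FitError, fit_abbreviated, fit_biexp
from .signal_model import TissueParams, biexp_signal, standard_schedules

__all__ = ["SnrStudyConfig", "run_snr_study", "summarize"]


@dataclass(frozen=True)
class SnrStudyConfig:
    """Configuration of the Monte-Carlo SNR study.

    Defaults mirror the published study conditions: SNR levels 1000 down to
    200, a clinical grid of T2s* in [0.5, 2.0] ms and f_bw in [0.70, 0.95]
    with T2l* fixed at 20 ms.  The grid is a coarse 7 x 6 lattice with 500
    replicates per node -- the published replicate count and grid density are
    unstated, so these are desk-scale choices dense enough for stable means.
    """

    snr_levels: tuple[float, ...] = (1000.0, 800.0, 600.0, 400.0, 200.0)
    n_reps: int = 500
    seed: int = 0
    t2s_nodes: tuple[float, ...] = tuple(np.linspace(0.5, 2.0, 7))
    fbw_nodes: tuple[float, ...] = tuple(np.linspace(*SNR_STUDY_FBW_RANGE, 6))
    t2l: float = 20.0
    s0: float = 1.0
    rician: bool = False
    warm_start_biexp: bool = True
    drop_longest_te: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.snr_levels):
            raise ValueError("SNR levels must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _add_noise(rng, clean: np.ndarray, sigma: float, rician: bool) -> np.ndarray:
    if rician:
        re = clean + rng.normal(0.0, sigma, clean.shape)
        im = rng.normal(0.0, sigma, clean.shape)
        return np.hypot(re, im)
    return clean + rng.normal(0.0, sigma, clean.shape)


def run_snr_study(config: SnrStudyConfig, correction: CorrectionModel) -> pd.DataFrame:
    """Run the Monte-Carlo study; returns a long-format replicate table.

    Columns: snr, method ("abbreviated_corrected" | "full_biexp"), parameter
    ("t2s" | "f_bw"), truth values, estimate and absolute percent error.
    Noisy signals are clipped at zero (magnitudes).  Fits raising
    :class:`~uteq.estimation.FitError` are counted in the ``failed`` column
    of :func:`summarize` input via NaN rows.  Fully reproducible given
    ``config.seed``.
    """
    if correction.t2l_assumed != config.t2l:
        raise ValueError(
            "correction model calibrated at %.3g ms but study uses T2l = %.3g ms"
            % (correction.t2l_assumed, config.t2l)
        )
    scheds = standard_schedules()
    abbrev, full = scheds["abbreviated"], scheds["full"]
    te_full = full.all_tes
    rng = np.random.default_rng(config.seed)

    rows = []
    for t2s in config.t2s_nodes:
        for fbw in config.fbw_nodes:
            params = TissueParams(s0=config.s0, f_bw=fbw, t2s=t2s, t2l=config.t2l)
            clean_ab = biexp_signal(params, abbrev.all_tes)
            clean_full = biexp_signal(params, te_full)
            warm = None
            if config.warm_start_biexp:
                ref = fit_biexp(
                    DecayCurve(te_full, clean_full, "full"),
                    drop_te=20.0 if config.drop_longest_te else None,
                )
                warm = (ref.t2s, ref.t2l)
            for snr in config.snr_levels:
                sigma = config.s0 / snr
                for rep in range(config.n_reps):
                    y_ab = np.clip(
                        _add_noise(rng, clean_ab, sigma, config.rician), 0.0, None
                    )
                    y_full = np.clip(
                        _add_noise(rng, clean_full, sigma, config.rician), 0.0, None
                    )
                    try:
                        app = fit_abbreviated(
                            DecayCurve(abbrev.all_tes, y_ab, "abbreviated"), abbrev
                        )
                        with warnings.catch_warnings():
                            # noise routinely pushes apparent values just past
                            # the calibration rectangle; flags carry the info
                            warnings.simplefilter("ignore", UserWarning)
                            corr = apply_correction(app, correction)
                        ab_t2s, ab_fbw = corr.t2s, corr.f_bw
                    except FitError:
                        ab_t2s = ab_fbw = np.nan
                    try:
                        bi = fit_biexp(
                            DecayCurve(te_full, y_full, "full"),
                            x0=warm,
                            drop_te=20.0 if config.drop_longest_te else None,
                        )
                        bi_t2s, bi_fbw = bi.t2s, bi.f_bw
                    except FitError:
                        bi_t2s = bi_fbw = np.nan
                    for method, est_t, est_f in (
                        ("abbreviated_corrected", ab_t2s, ab_fbw),
                        ("full_biexp", bi_t2s, bi_fbw),
                    ):
                        rows.append(
                            (snr, method, t2s, fbw, rep, est_t, est_f)
                        )
    df = pd.DataFrame(
        rows,
        columns=["snr", "method", "t2s_true", "fbw_true", "rep", "t2s_est", "fbw_est"],
    )
    df["abs_pct_err_t2s"] = 100 * np.abs(df.t2s_est - df.t2s_true) / df.t2s_true
    df["abs_pct_err_fbw"] = 100 * np.abs(df.fbw_est - df.fbw_true) / df.fbw_true
    return df


def summarize(result: pd.DataFrame) -> pd.DataFrame:
    """Collapse a replicate table to the published-table shape.

    Rows are SNR levels; columns are method x parameter mean +/- sd of the
    absolute percent error over all grid nodes and replicates.  Failed
    (NaN) fits are excluded and counted.
    """
    if result.empty:
        raise ValueError("empty study result")
    recs = []
    for (snr, method), g in result.groupby(["snr", "method"], sort=False):
        for par, col in (("t2s", "abs_pct_err_t2s"), ("f_bw", "abs_pct_err_fbw")):
            vals = g[col].dropna()
            recs.append(
                {
                    "snr": snr,
                    "method": method,
                    "parameter": par,
                    "mean_abs_pct_error": float(vals.mean()),
                    "sd_pct_error": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                    "failed": int(g[col].isna().sum()),
                }
            )
    long = pd.DataFrame(recs)
    wide = long.pivot_table(
        index="snr",
        columns=["method", "parameter"],
        values="mean_abs_pct_error",
        sort=False,
    ).sort_index(ascending=False)
    wide.attrs["long"] = long
    return wide


def format_report(wide: pd.DataFrame) -> str:
    """Fixed-precision text rendering of the summary table."""
    lines = ["SNR study: mean absolute % error (rows: SNR, desc)"]
    header = "  ".join(
        f"{m}/{p}" for m, p in wide.columns.to_flat_index()
    )
    lines.append(f"{'snr':>6}  {header}")
    for snr, row in wide.iterrows():
        cells = "  ".join(f"{v:.6g}" for v in row.values)
        lines.append(f"{snr:>6g}  {cells}")
    return "\n".join(lines)
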