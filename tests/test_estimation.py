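"""Fitter contracts: self-consistency, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uteq import (
    DecayCurve,
    FitError,
    abbreviated_signal,
    biexp_signal,
    estimate_baseline,
    fit_abbreviated,
    fit_biexp,
    fit_t2l_monoexp,
    TissueParams,
)

from conftest import make_biexp_curve


def abbrev_grid_oracle(te1, y1, baseline, t2s_lo=0.05, t2s_hi=10.0, n=20000):
    """Independent dense profile search for the abbreviated fit.

    For each candidate t2s the optimal amplitude is the closed-form linear
    least-squares solution; scans t2s on a dense grid and returns the
    (t2s, f_bw_app) at the global SSE minimum.
    """
    t2s_grid = np.linspace(t2s_lo, t2s_hi, n)
    E = np.exp(-te1[None, :] / t2s_grid[:, None])  # (n, 3)
    d = y1 - baseline
    amp = np.clip((E * d).sum(axis=1) / (E * E).sum(axis=1), baseline, None)
    sse = ((amp[:, None] * E + baseline - y1) ** 2).sum(axis=1)
    k = int(np.argmin(sse))
    return t2s_grid[k], 1.0 - baseline / amp[k]


class TestEstimateBaseline:
    def test_mean_of_constants(self):
        c = DecayCurve([4.0, 5.0, 6.0], [2.0, 2.0, 2.0])
        assert estimate_baseline(c) == 2.0

    def test_arithmetic_mean(self):
        assert estimate_baseline(DecayCurve([4, 5, 6], [3, 4, 5])) == 4.0

    def test_noiseless_biexp_curve_value(self, abbreviated):
        # independent evaluation of the forward model at the three TE2s
        curve = make_biexp_curve(abbreviated).subset([4.0, 5.0, 6.0])
        assert estimate_baseline(curve) == pytest.approx(
            0.14505590647061983, abs=1e-15
        )


class TestFitAbbreviated:
    def test_self_consistency_exact_model(self, abbreviated):
        # generating model is the fitted model class: recovery to >= 6 digits
        t2s, f, b = 1.0, 0.8, 0.2
        tes = abbreviated.all_tes
        sig = abbreviated_signal(t2s, f, b, tes)
        # force the late echoes to the exact baseline so the model premise
        # (fully decayed fast pool by TE2) holds exactly
        sig[tes >= 4.0] = b
        est = fit_abbreviated(DecayCurve(tes, sig), abbreviated)
        assert est.t2s_app == pytest.approx(t2s, rel=1e-6)
        assert est.f_bw_app == pytest.approx(f, rel=1e-6)

    def test_known_overestimation_regime(self, abbreviated):
        # slow-pool leakage into TE1 inflates short T2s* by ~10% at
        # t2s=0.5 ms, f_bw=0.75
        est = fit_abbreviated(
            make_biexp_curve(abbreviated, f_bw=0.75, t2s=0.5), abbreviated
        )
        assert 0.08 < (est.t2s_app - 0.5) / 0.5 < 0.12

    @pytest.mark.parametrize(
        "t2s,f_bw", [(1.0, 0.85), (0.6, 0.9), (1.8, 0.78), (1.2, 0.5)]
    )
    def test_matches_dense_grid_search_oracle(self, abbreviated, t2s, f_bw):
        curve = make_biexp_curve(abbreviated, f_bw=f_bw, t2s=t2s)
        est = fit_abbreviated(curve, abbreviated)
        te1 = abbreviated.te1_array
        t2s_o, f_o = abbrev_grid_oracle(
            te1, curve.subset(te1).signals, est.baseline
        )
        assert est.t2s_app == pytest.approx(t2s_o, abs=1e-3)
        assert est.f_bw_app == pytest.approx(f_o, abs=1e-3)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, abbreviated, scale):
        curve = make_biexp_curve(abbreviated)
        scaled = DecayCurve(curve.tes, curve.signals * scale)
        a = fit_abbreviated(curve, abbreviated)
        b = fit_abbreviated(scaled, abbreviated)
        assert b.t2s_app == pytest.approx(a.t2s_app, rel=1e-8)
        assert b.f_bw_app == pytest.approx(a.f_bw_app, rel=1e-8)
        assert b.baseline == pytest.approx(a.baseline * scale, rel=1e-12)

    def test_bias_sign_flip_across_grid(self, abbreviated):
        # apparent-T2s bias goes from overestimation (low t2s, low f_bw)
        # to underestimation (high t2s, high f_bw)
        lo = fit_abbreviated(
            make_biexp_curve(abbreviated, f_bw=0.75, t2s=0.5), abbreviated
        )
        hi = fit_abbreviated(
            make_biexp_curve(abbreviated, f_bw=0.95, t2s=2.0), abbreviated
        )
        assert lo.t2s_app > 0.5
        assert hi.t2s_app < 2.0

    def test_degenerate_low_fraction_is_flagged(self, abbreviated):
        # fast amplitude below baseline: f_bw,app pinned at 0 and flagged
        est = fit_abbreviated(
            make_biexp_curve(abbreviated, f_bw=0.25, t2s=2.0), abbreviated
        )
        assert "f_bw_app_at_bound" in est.flags


class TestFitBiexp:
    def test_exact_recovery_noiseless(self, schedules):
        full = schedules["full"]
        curve = make_biexp_curve(full, s0=1.3, f_bw=0.8, t2s=1.0, t2l=20.0)
        est = fit_biexp(curve)
        assert est.s0 == pytest.approx(1.3, rel=1e-6)
        assert est.f_bw == pytest.approx(0.8, rel=1e-6)
        assert est.t2s == pytest.approx(1.0, rel=1e-6)
        assert est.t2l == pytest.approx(20.0, rel=1e-6)
        assert not est.flags

    def test_matches_coarse_4d_grid_oracle(self, schedules):
        # brute-force 4-D grid: lowest SSE within grid resolution
        full = schedules["full"]
        truth = dict(s0=1.0, f_bw=0.8, t2s=1.0, t2l=20.0)
        curve = make_biexp_curve(full, **truth)
        s0g = np.arange(0.8, 1.21, 0.05)
        fg = np.arange(0.70, 0.901, 0.02)
        tsg = np.arange(0.8, 1.21, 0.02)
        tlg = np.arange(15.0, 25.1, 1.0)
        S0, F, TS, TL = np.meshgrid(s0g, fg, tsg, tlg, indexing="ij")
        sse = np.zeros_like(S0)
        for te, y in zip(curve.tes, curve.signals):
            model = S0 * (F * np.exp(-te / TS) + (1 - F) * np.exp(-te / TL))
            sse += (model - y) ** 2
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        est = fit_biexp(curve)
        assert abs(est.s0 - S0[idx]) <= 0.05
        assert abs(est.f_bw - F[idx]) <= 0.02
        assert abs(est.t2s - TS[idx]) <= 0.02
        assert abs(est.t2l - TL[idx]) <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_noiseless_recovery(self, schedules, seed):
        rng = np.random.default_rng(seed)
        full = schedules["full"]
        truth = dict(
            s0=rng.uniform(0.5, 2.0),
            f_bw=rng.uniform(0.3, 0.9),
            t2s=rng.uniform(0.4, 2.5),
            t2l=rng.uniform(12.0, 30.0),
        )
        est = fit_biexp(make_biexp_curve(full, **truth))
        for k in truth:
            assert getattr(est, k) == pytest.approx(truth[k], rel=1e-5), k

    def test_too_few_echoes_rejected(self):
        with pytest.raises(FitError):
            fit_biexp(DecayCurve([0.1, 0.5, 2, 5, 10], np.ones(5) * 0.5))

    def test_drop_te_excludes_echo(self, schedules):
        full = schedules["full"]
        curve = make_biexp_curve(full)
        est = fit_biexp(curve, drop_te=20.0)
        assert est.t2s == pytest.approx(1.4, rel=1e-6)


class TestFitT2lMonoexp:
    def test_exact_single_exponential(self, schedules):
        vte = schedules["vte"]
        tes = vte.all_tes
        t2l, flags = fit_t2l_monoexp(DecayCurve(tes, 0.5 * np.exp(-tes / 20.0)))
        assert t2l == pytest.approx(20.0, rel=1e-8)
        assert not flags

    def test_matches_loglinear_oracle_on_biexp_tail(self, schedules):
        vte = schedules["vte"]
        curve = make_biexp_curve(vte, f_bw=0.4, t2s=0.5, t2l=20.0)
        keep = curve.tes >= 3.0
        slope, _ = np.polyfit(curve.tes[keep], np.log(curve.signals[keep]), 1)
        t2l, _ = fit_t2l_monoexp(curve, min_te=3.0)
        # nonlinear and log-linear fits weight residuals differently; with a
        # nearly-pure tail they agree closely
        assert t2l == pytest.approx(-1.0 / slope, rel=1e-3)

    def test_constant_signal_pinned_and_flagged(self, schedules):
        tes = schedules["vte"].all_tes
        t2l, flags = fit_t2l_monoexp(DecayCurve(tes, np.full(tes.size, 0.7)))
        assert "t2l_at_bound" in flags

    def test_too_few_late_echoes_rejected(self):
        with pytest.raises(FitError):
            fit_t2l_monoexp(DecayCurve([4.0, 6.0], [0.5, 0.4]), min_te=3.0)
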