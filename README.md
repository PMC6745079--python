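# uteq

Quantitative analysis of bicomponent T2\* decay from **abbreviated
ultrashort-echo-time (UTE) MRI**.

Collagen-rich tissue — ACL grafts, tendon, cortical bone — contains a
fast-decaying collagen-bound water pool (T2s\* ~ 0.5–2 ms) invisible to
conventional MRI, plus a slow free-water pool (T2l\* ~ 20 ms). Resolving both
normally requires a long multi-echo UTE acquisition and a four-parameter
bi-exponential fit

    S(TE) = S0 · [ f_bw · e^(−TE/T2s*) + (1 − f_bw) · e^(−TE/T2l*) ].

The abbreviated paradigm implemented here instead acquires just three double
echoes (TE1/TE2 of 0.1/4.0, 0.27/5.0, 0.5/6.0 ms) and fits the
sub-millisecond echoes with a **baseline-corrected mono-exponential** model,

    S(TE) = baseline/(1 − f_bw,app) · e^(−TE/T2s,app*) + baseline,

where the baseline (the slow pool, nearly constant below 0.5 ms) is the mean
of the three late echoes. The apparent parameters carry a deterministic,
noise-free bias; `uteq` tabulates that bias on simulated parameter grids,
calibrates a fourth-order bivariate polynomial correction, and validates the
corrected estimator against full bi-exponential fitting in Monte-Carlo
experiments across SNR levels. ROI utilities (graft/bone interface growth,
orientation to B0, Dice overlap, intra-rater error) and a synthetic
multi-echo phantom generator complete the pipeline, so everything is testable
without scanner data.

Intended users: researchers in quantitative musculoskeletal MRI who want
short, clinically tolerable protocols for longitudinal monitoring of graft
and tendon remodelling.

## Worked example

Simulate the clinical bias grid, calibrate the correction, and run the full
chain on one tissue (true T2s\* = 1.4 ms, f_bw = 0.85, T2l\* = 20 ms):

```python
from uteq import (
    DecayCurve, TissueParams, apply_correction, biexp_signal,
    clinical_grid_axes, fit_abbreviated, fit_correction,
    simulate_bias_grid, standard_schedules,
)

sched = standard_schedules()["abbreviated"]
t2s_ax, fbw_ax = clinical_grid_axes()          # 61 x 41 nodes, f_bw 0.75-0.95
grid = simulate_bias_grid(t2s_ax, fbw_ax, t2l=20.0, schedule=sched)
print(grid.summary())
model = fit_correction(grid)

p = TissueParams(s0=1.0, f_bw=0.85, t2s=1.4, t2l=20.0)
tes = sched.all_tes
curve = DecayCurve(tes, biexp_signal(p, tes), "abbreviated")
est = fit_abbreviated(curve, sched)
print(f"apparent:  t2s_app={est.t2s_app:.4f} ms  f_bw_app={est.f_bw_app:.4f}")
corr = apply_correction(est, model)
print(f"corrected: t2s={corr.t2s:.4f} ms  f_bw={corr.f_bw:.4f}")
```

Output:

```
{'mean_abs_rel_bias_t2s_pct': 3.6485, 'mean_abs_rel_bias_fbw_pct': 3.3691,
 'mean_rel_bias_t2s_pct': -0.1431, 'mean_rel_bias_fbw_pct': -2.4562,
 'n_nodes': 2501, 'n_flagged': 0}
apparent:  t2s_app=1.3846 ms  f_bw_app=0.8304
corrected: t2s=1.3999 ms  f_bw=0.8500
```

Over the clinically relevant graft range the uncorrected abbreviated fit is
biased by ~3.6% (T2s\*) and ~3.4% (f_bw) on average; after the polynomial
correction the example tissue is recovered to 0.01% — the correction removes
essentially all of the model-mismatch bias when the assumed T2l\* is right.

The same workflows are available from the shell:

```sh
uteq calibrate --t2l 20 --out correction.json
uteq snr-study --correction correction.json --reps 500 --seed 1 --out table.csv
uteq phantom --snr 1000 --seed 2 --out phantom/
uteq roi-report --images phantom/echo_*.nii.gz --masks phantom/mask_*.nii.gz \
    --correction correction.json --out report.csv
```

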