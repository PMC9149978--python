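"""Estimate T1, T2 and proton density of one tissue from simulated series.

Simulates the two standard spin-echo series for a liver-like tissue — a
variable-TR series (TE 20 ms) and a variable-TE series (TR 2000 ms) — with
1% Gaussian noise, then runs the three per-pixel estimators. The printed
estimates should sit within a few percent of the true values; the T2 fit
uses the saturation correction (with the fitted T1) and signal^2-weighted
log-least-squares.
"""

import numpy as np

import pseudomr as p
from pseudomr.relaxometry import fit_rho, fit_t1, fit_t2

truth = p.TissueParams(t1=586, t2=54, rho=720)
rng = np.random.default_rng(7)

tr_grid = np.array(p.phantom.T1_SERIES_TR_MS)
te_grid = np.array(p.phantom.T2_SERIES_TE_MS)
s_tr = np.array([p.spin_echo_signal(truth, s) for s in p.t1_series_params()])
s_te = np.array([p.spin_echo_signal(truth, s) for s in p.t2_series_params()])
sd = 0.01 * s_tr.max()
s_tr = np.clip(s_tr + rng.normal(0, sd, s_tr.shape), 0, None)
s_te = s_te + rng.normal(0, sd, s_te.shape)

f1 = fit_t1(tr_grid, s_tr)
f2 = fit_t2(te_grid, s_te, t1=f1.t1, tr=2000.0, weighted=True)
f3 = fit_rho(tr_grid, s_tr, 20.0, f1.t1, f2.t2)

print(f"T1:  true {truth.t1:7.1f} ms   estimated {f1.t1:7.1f} ms")
print(f"T2:  true {truth.t2:7.1f} ms   estimated {f2.t2:7.1f} ms")
print(f"rho: true {truth.rho:7.1f} au   estimated {f3.rho:7.1f} au")
print(f"(noise sd = 1% of the peak series signal; {f2.n_used} TE points used)")
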