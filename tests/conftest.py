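"""Shared fixtures: small phantoms and one session-scoped end-to-end study."""

from __future__ import annotations

import numpy as np
import pytest

import pseudomr as p


def simulate_tissue_series(tissue, *, noise_sd=0.0, seed=0):
    """Scalar-pixel acquisition: signals over the standard TR and TE grids."""
    rng = np.random.default_rng(seed)
    tr_vals = np.array(p.phantom.T1_SERIES_TR_MS)
    te_vals = np.array(p.phantom.T2_SERIES_TE_MS)
    s_tr = np.array(
        [p.spin_echo_signal(tissue, s) for s in p.t1_series_params()]
    )
    s_te = np.array(
        [p.spin_echo_signal(tissue, s) for s in p.t2_series_params()]
    )
    if noise_sd > 0:
        s_tr = np.clip(s_tr + rng.normal(0, noise_sd, s_tr.shape), 0, None)
        s_te = s_te + rng.normal(0, noise_sd, s_te.shape)
    return tr_vals, s_tr, te_vals, s_te


@pytest.fixture(scope="session")
def study():
    """Full cross-slice study: mapping learned on slice A, applied to slice B.

    128 x 128 phantoms, 9-average CT at 10 HU noise, MR noise at 1% of the
    peak noiseless signal. Computed once per session.
    """
    a = p.default_phantom("A", (128, 128), seed=10)
    b = p.default_phantom("B", (128, 128), seed=11)
    seqs1, seqs2 = p.t1_series_params(), p.t2_series_params()
    peak = max(p.synthesize_weighted_image(a.truth_maps, s).max() for s in seqs1 + seqs2)
    mr_sd = 0.01 * peak
    tr_series = p.simulate_mr_series(a, seqs1, noise_sd=mr_sd, seed=20)
    te_series = p.simulate_mr_series(a, seqs2, noise_sd=mr_sd, seed=21)
    maps_a = p.compute_parameter_maps(tr_series, te_series, a.mask)
    ct_a, _ = p.simulate_ct(a, seed=22)
    ct_b, _ = p.simulate_ct(b, seed=23)
    feats_a = p.ct_window_features(ct_a, a.mask)
    feats_b = p.ct_window_features(ct_b, b.mask)
    model = p.build_mapping(feats_a, maps_a)
    maps_b = p.apply_mapping(model, feats_b)
    return {
        "a": a,
        "b": b,
        "mr_sd": mr_sd,
        "maps_a": maps_a,
        "ct_a": ct_a,
        "ct_b": ct_b,
        "feats_a": feats_a,
        "feats_b": feats_b,
        "model": model,
        "maps_b": maps_b,
    }


@pytest.fixture()
def two_tissue_phantom():
    """Two non-contacting rectangular tissues (no partial-volume pixels)."""
    specs = [
        p.TissueSpec(
            label="t_a", geometry=("rect", 4, 4, 12, 12), t1=300.0, t2=80.0,
            rho=500.0, hu_mean=50.0, hu_texture_sd=3.0,
        ),
        p.TissueSpec(
            label="t_b", geometry=("rect", 20, 20, 10, 10), t1=900.0, t2=120.0,
            rho=800.0, hu_mean=20.0, hu_texture_sd=5.0,
        ),
    ]
    return p.make_phantom(specs, (36, 36), seed=5)
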