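"""T1/T2/rho estimators: exact noiseless recovery, oracles, degeneracies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pseudomr as p
from pseudomr.errors import (
    DegenerateFitError,
    EmptyMaskError,
    InsufficientDataError,
    StructuralError,
)
from pseudomr.relaxometry import fit_rho, fit_t1, fit_t2, zero_intercept_slope

from conftest import simulate_tissue_series

TR_GRID = np.array([100.0, 200, 400, 800, 1250, 2000, 4000, 5000])
TE_GRID = np.array([10.0, 15, 25, 40, 60, 90, 130, 180, 240])


def _signals_tr(tissue, te=20.0):
    return np.array(
        [p.spin_echo_signal(tissue, p.SequenceParams(te=te, tr=tr)) for tr in TR_GRID]
    )


def _signals_te(tissue, tr=2000.0):
    return np.array(
        [p.spin_echo_signal(tissue, p.SequenceParams(te=te, tr=tr)) for te in TE_GRID]
    )


def grid_search_t1(tr, signals, t1_grid):
    """Independent coarse oracle: scan T1, solve (C1, C2) linearly, keep best."""
    best = (np.inf, None)
    for t1 in t1_grid:
        basis = np.column_stack([np.ones_like(tr), np.exp(-tr / t1)])
        coef, res, *_ = np.linalg.lstsq(basis, signals, rcond=None)
        sse = float(((basis @ coef - signals) ** 2).sum())
        if sse < best[0]:
            best = (sse, t1)
    return best[1]


class TestFitT1:
    def test_noiseless_recovery_at_standard_grid(self):
        tissue = p.TissueParams(t1=300, t2=80, rho=500)
        res = fit_t1(TR_GRID, _signals_tr(tissue))
        assert res.t1 == pytest.approx(300, rel=1e-3)
        assert res.c3 == pytest.approx(1 / res.t1)

    def test_constant_signals_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_t1(TR_GRID, np.full(8, 5.0))

    def test_too_few_tr_values(self):
        with pytest.raises(InsufficientDataError):
            fit_t1([100, 200, 400], [1.0, 2.0, 3.0])

    def test_noisy_fit_beats_coarse_grid_oracle(self):
        """Monte-Carlo at 1% noise: median error no worse than an
        independent grid-search least-squares oracle."""
        tissue = p.TissueParams(t1=300, t2=80, rho=500)
        clean = _signals_tr(tissue)
        sd = 0.01 * clean.max()
        rng = np.random.default_rng(42)
        t1_grid = np.geomspace(50, 3000, 120)
        fit_err, oracle_err = [], []
        for _ in range(300):
            noisy = np.clip(clean + rng.normal(0, sd, clean.shape), 0, None)
            fit_err.append(abs(fit_t1(TR_GRID, noisy).t1 - 300) / 300)
            oracle_err.append(abs(grid_search_t1(TR_GRID, noisy, t1_grid) - 300) / 300)
        med_fit = np.median(fit_err)
        med_oracle = np.median(oracle_err)
        assert med_fit <= med_oracle * 1.05 + 1e-4
        assert med_fit < 0.05


class TestFitT2:
    def test_pure_exponential_recovered_exactly(self):
        for k in (1.0, 37.5, 1e4):
            res = fit_t2(TE_GRID, k * np.exp(-TE_GRID / 100.0))
            assert res.t2 == pytest.approx(100.0, rel=1e-10)
            assert res.n_used == TE_GRID.size

    def test_exact_line_through_two_points(self):
        te = np.array([10.0, 60.0, 110.0])
        s = np.exp(-0.01 * te)  # consistent third point on the same line
        res = fit_t2(te, s)
        assert res.c2 == pytest.approx(-0.01, abs=1e-12)
        assert res.t2 == pytest.approx(100.0, rel=1e-10)

    def test_scale_invariance(self):
        s = np.exp(-TE_GRID / 70.0)
        assert fit_t2(TE_GRID, s).t2 == pytest.approx(fit_t2(TE_GRID, 123.4 * s).t2)

    def test_too_few_positive_signals(self):
        with pytest.raises(InsufficientDataError):
            fit_t2(TE_GRID, np.r_[1.0, 0.5, np.zeros(7)])

    def test_growing_signals_flagged(self):
        with pytest.raises(DegenerateFitError):
            fit_t2(TE_GRID, np.exp(+TE_GRID / 100.0))

    def test_full_model_bias_matches_closed_form_ols_oracle(self):
        """Fitting the log-linear model to exact full-model signals is biased;
        the bias must equal an independent closed-form OLS on those values,
        and the saturation correction must remove it."""
        tissue = p.TissueParams(t1=400, t2=100, rho=800)
        s = _signals_te(tissue, tr=2000.0)
        # independent oracle: textbook OLS of ln(s) on TE
        y = np.log(s)
        slope = ((TE_GRID - TE_GRID.mean()) * (y - y.mean())).sum() / (
            (TE_GRID - TE_GRID.mean()) ** 2
        ).sum()
        t2_oracle = -1.0 / slope
        plain = fit_t2(TE_GRID, s)
        assert plain.t2 == pytest.approx(t2_oracle, rel=1e-10)
        assert plain.t2 != pytest.approx(100.0, rel=1e-4)  # the bias is real
        corrected = fit_t2(TE_GRID, s, t1=400.0, tr=2000.0)
        assert corrected.t2 == pytest.approx(100.0, rel=1e-9)


class TestFitRho:
    def test_noiseless_self_consistency(self):
        tissue = p.TissueParams(t1=500, t2=90, rho=750)
        res = fit_rho(TR_GRID, _signals_tr(tissue), 20.0, 500.0, 90.0)
        assert res.rho == pytest.approx(750, rel=1e-10)

    def test_all_zero_signals(self):
        res = fit_rho(TR_GRID, np.zeros(8), 20.0, 500.0, 90.0)
        assert res.rho == 0.0

    def test_hand_computed_zero_intercept_slope(self):
        # sum(A x)/sum(x^2) = 17.925/1.7925 = 10 exactly
        assert zero_intercept_slope([0.5, 0.8, 0.95], [5, 8, 9.5]) == pytest.approx(10.0)

    def test_linear_in_signal_scale(self):
        tissue = p.TissueParams(t1=500, t2=90, rho=750)
        s = _signals_tr(tissue)
        r1 = fit_rho(TR_GRID, s, 20.0, 500.0, 90.0).rho
        r3 = fit_rho(TR_GRID, 3 * s, 20.0, 500.0, 90.0).rho
        assert r3 == pytest.approx(3 * r1, rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    t1=st.floats(200, 2000),
    t2=st.floats(40, 300),
    rho=st.floats(100, 1000),
)
def test_noiseless_parameter_recovery_property(t1, t2, rho):
    """Any tissue in the physiological box is recovered to 0.5% from
    noiseless series on the standard TR/TE grids."""
    tissue = p.TissueParams(t1=t1, t2=t2, rho=rho)
    tr_vals, s_tr, te_vals, s_te = simulate_tissue_series(tissue)
    f1 = fit_t1(tr_vals, s_tr)
    f2 = fit_t2(te_vals, s_te, t1=f1.t1, tr=2000.0)
    f3 = fit_rho(tr_vals, s_tr, 20.0, f1.t1, f2.t2)
    assert abs(f1.t1 - t1) / t1 < 0.005
    assert abs(f2.t2 - t2) / t2 < 0.005
    assert abs(f3.rho - rho) / rho < 0.005


class TestAcquisitionSeries:
    def _params(self, trs, te=20.0):
        return [p.SequenceParams(te=te, tr=tr) for tr in trs]

    def test_sorted_by_varying_parameter(self):
        imgs = np.arange(4 * 2 * 2, dtype=float).reshape(4, 2, 2)
        series = p.AcquisitionSeries(
            images=imgs, params=self._params([800, 100, 400, 200]), kind="variable_tr"
        )
        assert list(series.tr_values) == [100, 200, 400, 800]

    def test_duplicate_varying_parameter_rejected(self):
        imgs = np.zeros((4, 2, 2))
        with pytest.raises(StructuralError):
            p.AcquisitionSeries(
                images=imgs, params=self._params([100, 100, 400, 800]), kind="variable_tr"
            )

    def test_inconsistent_fixed_parameter_rejected(self):
        imgs = np.zeros((4, 2, 2))
        params = self._params([100, 200, 400, 800])
        params[2] = p.SequenceParams(te=25.0, tr=400)
        with pytest.raises(StructuralError):
            p.AcquisitionSeries(images=imgs, params=params, kind="variable_tr")

    def test_minimum_image_counts(self):
        with pytest.raises(StructuralError):
            p.AcquisitionSeries(
                images=np.zeros((3, 2, 2)),
                params=self._params([100, 200, 400]),
                kind="variable_tr",
            )


class TestComputeParameterMaps:
    def test_noiseless_phantom_recovery(self, two_tissue_phantom):
        ph = two_tissue_phantom
        tr_series = p.simulate_mr_series(ph, p.t1_series_params(), seed=0)
        te_series = p.simulate_mr_series(ph, p.t2_series_params(), seed=0)
        maps = p.compute_parameter_maps(tr_series, te_series, ph.mask)
        assert maps.mask.sum() == ph.mask.sum()
        for k in ("t1", "t2", "rho"):
            est = getattr(maps, k)[maps.mask]
            tru = getattr(ph.truth_maps, k)[maps.mask]
            assert np.max(np.abs(est - tru) / tru) < 0.005

    def test_single_pixel_mask_matches_scalar_fits(self, two_tissue_phantom):
        ph = two_tissue_phantom
        tr_series = p.simulate_mr_series(ph, p.t1_series_params(), seed=0)
        te_series = p.simulate_mr_series(ph, p.t2_series_params(), seed=0)
        mask = np.zeros(ph.shape, dtype=bool)
        mask[8, 8] = True
        maps = p.compute_parameter_maps(tr_series, te_series, mask)
        f1 = fit_t1(tr_series.tr_values, tr_series.signals_at(8, 8))
        f2 = fit_t2(
            te_series.te_values, te_series.signals_at(8, 8), t1=f1.t1, tr=2000.0,
            weighted=True,
        )
        assert maps.t1[8, 8] == pytest.approx(f1.t1)
        assert maps.t2[8, 8] == pytest.approx(f2.t2)

    def test_empty_mask_rejected(self, two_tissue_phantom):
        ph = two_tissue_phantom
        tr_series = p.simulate_mr_series(ph, p.t1_series_params(), seed=0)
        te_series = p.simulate_mr_series(ph, p.t2_series_params(), seed=0)
        with pytest.raises(EmptyMaskError):
            p.compute_parameter_maps(tr_series, te_series, np.zeros(ph.shape, bool))

    def test_unfittable_pixels_dropped_not_raised(self, two_tissue_phantom):
        ph = two_tissue_phantom
        tr_series = p.simulate_mr_series(ph, p.t1_series_params(), seed=0)
        te_series = p.simulate_mr_series(ph, p.t2_series_params(), seed=0)
        # corrupt one pixel into a constant series (outside any tissue mask rules)
        r, c = 8, 8
        tr_series.images[:, r, c] = 7.0
        mask = np.zeros(ph.shape, dtype=bool)
        mask[r, c] = True
        mask[8, 9] = True
        maps = p.compute_parameter_maps(tr_series, te_series, mask)
        assert not maps.mask[r, c]
        assert maps.mask[8, 9]
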