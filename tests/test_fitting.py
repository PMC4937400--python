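"""Gordon-Taylor family fits and the Gaussian viability / EC50 pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sugarglass.fitting import (
    FitError,
    ec50,
    ec50_closed_form,
    fit_gordon_taylor,
    fit_modified_gt,
    fit_viability,
    gaussian_predict,
    gt_predict,
    mgt_predict,
    x_t_from_content,
)

# the eight simulated water contents (gH2O/gdw)
CONTENTS = np.array([0.0, 0.01, 0.02, 0.05, 0.1, 0.5, 1.0, 2.0])
XT = 1.0 / (1.0 + CONTENTS)


class TestPredictions:
    def test_gt_endpoints_exact(self):
        assert gt_predict(1.0, 388.0, 136.0, 0.2) == 388.0
        assert gt_predict(0.0, 388.0, 136.0, 0.2) == 136.0

    def test_gt_k1_unity_is_linear_interpolation(self):
        assert gt_predict(0.5, 388.0, 136.0, 1.0) == pytest.approx(262.0)

    def test_mgt_endpoints_exact(self):
        assert mgt_predict(1.0, 3.77, 1.19, 3.4) == 3.77
        assert mgt_predict(0.0, 3.77, 1.19, 3.4) == 1.19

    def test_mgt_midpoint_hand_value(self):
        # (0.5*3.77 + 3.4*0.5*1.19) / (0.5 + 3.4*0.5)
        assert mgt_predict(0.5, 3.77, 1.19, 3.4) == pytest.approx(1.7764, abs=1e-4)

    def test_gaussian_peak_and_baseline(self):
        assert gaussian_predict(0.6, 0.1, 0.9, 0.6, 0.2) == pytest.approx(1.0)
        assert gaussian_predict(100.0, 0.1, 0.9, 0.6, 0.2) == pytest.approx(0.1)

    def test_gaussian_half_maximum_point(self):
        assert gaussian_predict(0.35, 0.0, 1.0, 0.6, 0.2123) == pytest.approx(0.5, abs=1e-3)

    def test_reparameterization_invariance(self):
        """Predictions agree whether composition enters as x_t or as R."""
        r = np.array([0.01, 0.1, 0.5, 2.0])
        assert np.allclose(
            mgt_predict(x_t_from_content(r), 3.77, 1.19, 3.4),
            mgt_predict(1.0 / (1.0 + r), 3.77, 1.19, 3.4),
        )


class TestGordonTaylor:
    def test_plant_and_recover_noiseless(self):
        y = gt_predict(XT, 388.0, 136.0, 0.2)
        fit = fit_gordon_taylor(XT, y, 388.0, 136.0)
        assert fit.k1 == pytest.approx(0.2, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_linear_data_gives_unit_k1(self):
        y = gt_predict(XT, 388.0, 136.0, 1.0)
        fit = fit_gordon_taylor(XT, y, 388.0, 136.0)
        assert fit.k1 == pytest.approx(1.0, abs=1e-6)

    def test_single_point_is_error(self):
        with pytest.raises(FitError):
            fit_gordon_taylor([0.5], [260.0], 388.0, 136.0)

    def test_fixed_endpoints_hold_exactly(self):
        y = gt_predict(XT, 388.0, 136.0, 0.35)
        fit = fit_gordon_taylor(XT, y + 0.5, 388.0, 136.0)
        assert fit.predict(1.0) == 388.0
        assert fit.predict(0.0) == 136.0


class TestModifiedGT:
    @pytest.mark.parametrize(
        "n_pure,k2,n_inf",
        [(3.77, 3.4, 1.19), (3.29, 2.8, 1.12)],
        ids=["glassy", "ambient"],
    )
    def test_plant_and_recover_noiseless(self, n_pure, k2, n_inf):
        y = mgt_predict(XT, n_pure, n_inf, k2)
        fit = fit_modified_gt(XT, y, n_pure)
        assert fit.k2 == pytest.approx(k2, abs=1e-4)
        assert fit.n_inf == pytest.approx(n_inf, abs=1e-4)
        assert fit.r2 == pytest.approx(1.0)

    def test_accepts_water_content_axis(self):
        y = mgt_predict(XT, 3.77, 1.19, 3.4)
        fit = fit_modified_gt(CONTENTS, y, 3.77, x_is_content=True)
        assert fit.k2 == pytest.approx(3.4, abs=1e-4)

    def test_constant_data_flagged(self):
        fit = fit_modified_gt(XT, np.full_like(XT, 3.77), 3.77)
        assert any("unidentifiable" in f for f in fit.flags)
        assert fit.n_inf == pytest.approx(3.77)

    def test_noise_recovery_is_unbiased_and_efficient(self):
        """With sd-0.05 noise on the 8 compositions the k2 estimates are
        unbiased and their spread matches the Cramér-Rao bound, so ~95%
        of replicates land within two theoretical standard errors."""
        import warnings

        eps = 1e-6
        truth = mgt_predict(XT, 3.77, 1.19, 3.4)
        J = np.column_stack(
            [
                (mgt_predict(XT, 3.77, 1.19, 3.4 + eps) - truth) / eps,
                (mgt_predict(XT, 3.77, 1.19 + eps, 3.4) - truth) / eps,
            ]
        )
        sd_k2 = 0.05 * np.sqrt(np.linalg.inv(J.T @ J)[0, 0])
        estimates = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(200):
                rng = np.random.default_rng(seed)
                y = truth + rng.normal(0, 0.05, XT.size)
                estimates.append(fit_modified_gt(XT, y, 3.77).k2)
        estimates = np.array(estimates)
        assert abs(estimates.mean() - 3.4) < 3 * sd_k2 / np.sqrt(200) + 0.05
        assert estimates.std() < 1.3 * sd_k2  # no excess spread over the bound
        assert np.mean(np.abs(estimates - 3.4) <= 2 * sd_k2) >= 0.90

    def test_r2_decreases_with_noise(self):
        sds = (0.01, 0.05, 0.15)
        means = []
        for sd in sds:
            vals = []
            for seed in range(40):
                rng = np.random.default_rng(1000 + seed)
                y = mgt_predict(XT, 3.77, 1.19, 3.4) + rng.normal(0, sd, XT.size)
                vals.append(fit_modified_gt(XT, y, 3.77).r2)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestViability:
    X = np.array([0.05, 0.1, 0.2, 0.35, 0.5, 1.0, 2.0])

    def test_plant_and_recover_noiseless(self):
        y = gaussian_predict(self.X, 0.05, 0.92, 0.62, 0.21)
        fit = fit_viability(self.X, y)
        assert fit.y0 == pytest.approx(0.05, abs=1e-5)
        assert fit.a == pytest.approx(0.92, abs=1e-5)
        assert fit.xc == pytest.approx(0.62, abs=1e-5)
        assert fit.w == pytest.approx(0.21, abs=1e-5)

    def test_flat_data_flagged(self):
        fit = fit_viability(self.X, np.full(self.X.size, 0.7))
        assert fit.a == pytest.approx(0.0)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_descending_branch_below_xc(self):
        """Viability ~1 at high water, ~0 when dry: fitted curve descends
        monotonically as water is removed below xc."""
        y = gaussian_predict(self.X, 0.0, 1.0, 0.9, 0.45)
        fit = fit_viability(self.X, y)
        grid = np.linspace(0.05, min(fit.xc, 2.0), 50)
        vals = fit.predict(grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_too_few_points_is_error(self):
        with pytest.raises(FitError):
            fit_viability([0.1, 0.5, 1.0, 2.0], [0.1, 0.5, 0.9, 1.0])


class TestEC50:
    def test_reference_curve(self):
        y = gaussian_predict(TestViability.X, 0.0, 1.0, 0.6, 0.2123)
        fit = fit_viability(TestViability.X, y)
        assert ec50(fit) == pytest.approx(0.35, abs=1e-3)
        assert fit.predict(ec50(fit)) == pytest.approx(0.5, abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.floats(0.3, 1.5),
        st.floats(0.05, 0.5),
    )
    def test_matches_closed_form_when_baseline_zero(self, xc, w):
        from sugarglass.fitting import ViabilityFit

        fit = ViabilityFit(y0=0.0, a=1.0, xc=xc, w=w, r2=1.0)
        assert ec50(fit) == pytest.approx(
            ec50_closed_form(0.0, 1.0, xc, w), abs=1e-8
        )

    def test_no_crossing_is_error(self):
        from sugarglass.fitting import ViabilityFit

        fit = ViabilityFit(y0=0.6, a=0.4, xc=0.6, w=0.2, r2=1.0)
        with pytest.raises(FitError, match="EC50 undefined"):
            ec50(fit)
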