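import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ngrscreen.dose_response import (
    GRFit,
    _aoc_params,
    _ngr50_params,
    aoc,
    compute_metrics,
    detect_outliers,
    fit_gr,
    format_ngr50,
    gr_model,
    ngr50,
)
from ngrscreen.errors import InsufficientDataError

GRID7 = np.logspace(0.0, math.log10(5000.0), 7)


def _fit_from_params(grinf, gec50, hill):
    return GRFit(
        grinf=grinf,
        gec50=gec50,
        hill=hill,
        residuals=np.zeros(7),
        outlier_flags=np.zeros(7, dtype=bool),
        refitted=False,
        refit_skipped=False,
        rmse=0.0,
        n_points=7,
        converged=True,
    )


class TestGRModel:
    @given(
        st.floats(-1, 1),
        st.floats(1e-2, 1e5),
        st.floats(0.1, 10),
    )
    def test_zero_concentration_is_one(self, grinf, gec50, hill):
        assert gr_model(0.0, grinf, gec50, hill) == pytest.approx(1.0)

    @given(st.floats(-1, 1), st.floats(1e-2, 1e5), st.floats(0.1, 10))
    def test_half_effect_at_gec50(self, grinf, gec50, hill):
        assert gr_model(gec50, grinf, gec50, hill) == pytest.approx((1 + grinf) / 2)

    @pytest.mark.parametrize("grinf", [-1.0, -0.5, 0.0, 0.7])
    def test_infinite_concentration_limit(self, grinf):
        assert gr_model(1e30, grinf, 100.0, 2.0) == pytest.approx(grinf, abs=1e-12)
        assert gr_model(np.inf, grinf, 100.0, 2.0) == pytest.approx(grinf)

    def test_vectorized_and_monotone(self):
        c = np.logspace(-1, 5, 50)
        y = gr_model(c, -0.8, 100.0, 2.0)
        assert y.shape == c.shape
        assert (np.diff(y) < 0).all()


class TestFit:
    def test_recovers_noise_free_parameters(self):
        y = gr_model(GRID7, -0.5, 100.0, 2.0)
        fit = fit_gr(GRID7, y)
        assert fit.converged and not fit.refitted
        assert fit.grinf == pytest.approx(-0.5, abs=1e-6)
        assert fit.gec50 == pytest.approx(100.0, rel=1e-6)
        assert fit.hill == pytest.approx(2.0, rel=1e-6)

    def test_inert_profile_pins_grinf_near_one(self):
        fit = fit_gr(GRID7, np.ones(7))
        assert fit.converged
        assert fit.predict(GRID7) == pytest.approx(np.ones(7), abs=1e-3)
        assert aoc(fit, GRID7[0], GRID7[-1]) == pytest.approx(0.0, abs=1e-3)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_gr(GRID7[:4], np.ones(4))
        with pytest.raises(InsufficientDataError):
            fit_gr([1.0, 1.0, 10.0, 10.0, 10.0], np.ones(5))

    def test_corrupted_point_flagged_and_refit(self):
        c = np.append(GRID7, GRID7[-1])
        y = gr_model(c, -0.8, 50.0, 2.0)
        y[-1] = 0.9  # corrupted replicate at top dose
        fit = fit_gr(c, y)
        assert fit.converged and fit.refitted
        assert fit.outlier_flags[-1]
        assert fit.outlier_flags.sum() == 1
        assert fit.grinf == pytest.approx(-0.8, abs=5e-2)
        assert fit.gec50 == pytest.approx(50.0, rel=5e-2)
        assert fit.hill == pytest.approx(2.0, rel=5e-2)

    def test_refit_skipped_when_too_few_points_remain(self, monkeypatch):
        import ngrscreen.dose_response as dr

        c = GRID7[:5]
        y = gr_model(c, -0.8, 50.0, 2.0)
        y[0] = -0.9  # large error at the bottom dose
        monkeypatch.setattr(dr, "MIN_POINTS", 5)
        fit = dr.fit_gr(c, y)
        if fit.outlier_flags.any():
            assert fit.refit_skipped and not fit.refitted

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_gr(GRID7, np.ones(6))


class TestOutlierRule:
    def test_relative_and_absolute_thresholds_conjunctive(self):
        # mean |r| = 0.16 -> relative threshold 0.40; only 0.60 passes both
        flags = detect_outliers([0.01, 0.02, -0.01, 0.60])
        assert flags.tolist() == [False, False, False, True]

    def test_homogeneous_errors_never_flagged(self):
        assert not detect_outliers([0.3, 0.3, 0.3, 0.3]).any()

    def test_absolute_guard(self):
        assert not detect_outliers([0.0, 0.0, 0.0, 0.2]).any()

    def test_sign_insensitive(self):
        assert detect_outliers([0.01, -0.6, 0.02, 0.01]).tolist() == [
            False,
            True,
            False,
            False,
        ]

    @given(
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_matches_brute_force(self, residuals):
        r = np.abs(np.asarray(residuals))
        expected = [(x > 2.5 * r.mean()) and (x > 0.25) for x in r]
        assert detect_outliers(residuals).tolist() == expected


class TestNGR50:
    def test_symmetric_case_equals_gec50(self):
        fit = _fit_from_params(0.0, 123.0, 1.7)
        assert ngr50(fit, 5000.0) == pytest.approx(123.0)

    def test_unreachable_level_gives_sentinel(self):
        assert math.isinf(ngr50(_fit_from_params(0.6, 10.0, 2.0), 5000.0))
        assert math.isinf(ngr50(_fit_from_params(0.5, 10.0, 2.0), 5000.0))

    def test_beyond_cmax_gives_sentinel(self):
        assert math.isinf(ngr50(_fit_from_params(0.0, 4000.0, 2.0), 100.0))

    def test_closed_form_example(self):
        # grinf=-1, gec50=100, h=2: c = 100 * (1/3)^(1/2)
        expected = 100.0 * (1.0 / 3.0) ** 0.5
        assert ngr50(_fit_from_params(-1.0, 100.0, 2.0), 5000.0) == pytest.approx(
            expected
        )

    @given(
        st.floats(-1, 0.45),
        st.floats(1.0, 1e3),
        st.floats(0.3, 5),
    )
    @settings(max_examples=200)
    def test_closed_form_agrees_with_root_finding(self, grinf, gec50, hill):
        c = _ngr50_params(grinf, gec50, hill, math.inf)
        root = brentq(
            lambda x: gr_model(x, grinf, gec50, hill) - 0.5, 1e-12, 1e12, xtol=1e-15
        )
        assert c == pytest.approx(root, rel=1e-9)

    def test_formatting(self):
        assert format_ngr50(math.inf, 5000.0) == "> 5000"
        assert format_ngr50(57.735, 5000.0).startswith("57.735")


class TestAOC:
    def test_inert_flat_curve_is_zero(self):
        assert aoc(_fit_from_params(1.0, 100.0, 2.0), 1.0, 5000.0) == 0.0

    def test_complete_kill_flat_curve_is_one(self):
        # gec50 far below c_min makes the curve sit at grinf over the range
        assert aoc(_fit_from_params(-1.0, 1e-30, 10.0), 1.0, 5000.0) == pytest.approx(
            1.0
        )

    def test_pure_cytostasis_flat_curve_is_half(self):
        assert aoc(_fit_from_params(0.0, 1e-30, 10.0), 1.0, 5000.0) == pytest.approx(
            0.5
        )

    def test_quadrature_converges(self):
        fit = _fit_from_params(-0.7, 80.0, 1.3)
        a = aoc(fit, 1.0, 5000.0, n=513)
        b = aoc(fit, 1.0, 5000.0, n=1025)
        assert abs(a - b) < 1e-6

    def test_bounded(self):
        for grinf in (-1.0, -0.3, 0.4, 1.0):
            val = aoc(_fit_from_params(grinf, 50.0, 2.0), 1.0, 5000.0)
            assert 0.0 <= val <= 1.0

    def test_monotone_in_grinf_and_gec50(self):
        base = _aoc_params(-0.5, 100.0, 2.0, 1.0, 5000.0)
        assert _aoc_params(-0.8, 100.0, 2.0, 1.0, 5000.0) > base
        assert _aoc_params(-0.5, 30.0, 2.0, 1.0, 5000.0) > base

    @given(
        st.floats(-1, 1),
        st.floats(0.5, 1e4),
        st.floats(0.2, 8),
    )
    @settings(max_examples=100)
    def test_always_in_unit_interval(self, grinf, gec50, hill):
        assert 0.0 <= _aoc_params(grinf, gec50, hill, 1.0, 5000.0) <= 1.0

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            aoc(_fit_from_params(0.0, 10.0, 1.0), 100.0, 100.0)


class TestComputeMetrics:
    def test_metrics_columns_and_values(self, clean_plate):
        from ngrscreen.ngr_core import compute_ngr_table

        metrics, fits = compute_metrics(compute_ngr_table(clean_plate))
        assert set(
            [
                "cell_line",
                "drug",
                "culture",
                "replicate_id",
                "GRinf",
                "GEC50_nM",
                "h_GR",
                "NGR50_nM",
                "AOC",
                "n_outliers",
                "converged",
            ]
        ) <= set(metrics.columns)
        assert len(metrics) == 2  # wells_per_dose=2 -> 2 replicate fits
        assert metrics["converged"].all()
        assert all(f.n_points == 7 for f in fits.values())
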