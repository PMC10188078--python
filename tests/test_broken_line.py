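"""Broken-line models: prediction, profiled fitting, selection criteria."""

import math

import numpy as np
import pytest

import layreq as lq
from layreq.broken_line import BrokenLineParams, GRID_STEP, _profile_sse
from layreq.errors import ComparisonError, IdentifiabilityError


class TestPredict:
    def test_lbl_plateau_above_break(self, oxide_ep_model):
        assert lq.predict(oxide_ep_model, 100.0) == pytest.approx(75.77)

    def test_returns_plateau_at_break_exactly(self):
        for form in ("LBL", "QBL"):
            p = BrokenLineParams(form=form, L=50.0, U=-0.1, R=40.0)
            assert lq.predict(p, 40.0) == 50.0

    def test_qbl_below_break(self):
        p = BrokenLineParams(form="QBL", L=78.17, U=-0.009, R=40.0)
        assert lq.predict(p, 10.4) == pytest.approx(78.17 - 0.009 * 29.6 ** 2)
        assert lq.predict(p, 10.4) == pytest.approx(70.28, abs=0.005)

    def test_vectorized(self, oxide_ep_model):
        x = np.array([10.4, 82.0, 100.6])
        y = lq.predict(oxide_ep_model, x)
        assert y.shape == (3,)
        assert y[1] == y[2] == pytest.approx(75.77)

    def test_qbl_smooth_join(self):
        p = BrokenLineParams(form="QBL", L=50.0, U=-0.01, R=40.0)
        eps = 1e-6
        slope = (lq.predict(p, 40.0) - lq.predict(p, 40.0 - eps)) / eps
        assert abs(slope) < 1e-4


class TestFit:
    def test_noise_free_lbl_recovery(self, oxide_ep_model, oxide_doses):
        x = np.array(oxide_doses)
        y = lq.predict(oxide_ep_model, x)
        f = lq.fit(x, y, "LBL")
        assert f.identifiable
        assert f.params.R == pytest.approx(82.0, abs=1e-4)
        assert f.params.L == pytest.approx(75.77, abs=1e-6)
        assert f.params.U == pytest.approx(-0.07, abs=1e-6)
        assert f.quality.sse == pytest.approx(0.0, abs=1e-18)

    def test_noise_free_qbl_with_three_sub_break_doses_recovers(self):
        # three doses below the break pin the vertex exactly
        truth = BrokenLineParams(form="QBL", L=78.17, U=-0.009, R=60.0)
        x = np.array([10.0, 25.0, 45.0, 80.0, 100.0])
        f = lq.fit(x, lq.predict(truth, x), "QBL")
        assert f.identifiable
        assert f.params.R == pytest.approx(60.0, abs=1e-4)
        assert f.params.L == pytest.approx(78.17, abs=1e-5)

    def test_qbl_single_sub_break_dose_is_flagged_flat(self, sulphate_ep_model,
                                                       sulphate_doses):
        """With one dose below the break the SSE profile is identically zero
        over an interval: the break is not identified.  The fitter reports
        the interval's upper edge (largest dose consistent with a response)
        and flags the fit."""
        x = np.array(sulphate_doses)
        y = lq.predict(sulphate_ep_model, x)
        f = lq.fit(x, y, "QBL")
        assert not f.identifiable
        lo, hi = f.flat_interval
        assert lo < 40.0 < hi + 0.1          # generative break lies in the set
        assert f.params.R == pytest.approx(40.25, abs=0.1)
        assert f.quality.sse == pytest.approx(0.0, abs=1e-9)

    def test_constant_response_degenerate(self):
        x = np.array([10.0, 40.0, 70.0, 100.0])
        f = lq.fit(x, np.full(4, 7.0), "LBL")
        assert f.degenerate and f.params.U == 0.0
        assert math.isnan(f.params.R)
        assert f.quality.r2 == 0.0

    def test_too_few_points(self):
        with pytest.raises(IdentifiabilityError):
            lq.fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "LBL")
        with pytest.raises(IdentifiabilityError):
            lq.fit([1.0, 1.0, 2.0, 2.0], [1, 2, 3, 4], "LBL")

    def test_optimizer_dominates_grid_oracle(self, rng):
        """Fitted SSE never exceeds the profiled grid minimum (independent
        lstsq per grid point)."""
        truth = BrokenLineParams(form="LBL", L=75.0, U=-0.07, R=60.0)
        for _ in range(10):
            x = np.sort(rng.uniform(10, 100, 24))
            y = lq.predict(truth, x) + rng.normal(0, 3, 24)
            f = lq.fit(x, y, "LBL")
            grid = np.arange(x.min() + GRID_STEP, x.max() - GRID_STEP / 2,
                             GRID_STEP)
            best = min(_oracle_sse(x, y, r, "LBL") for r in grid)
            assert f.quality.sse <= best + 1e-9

    def test_sse_not_above_constant_model(self, rng):
        x = np.sort(rng.uniform(10, 100, 20))
        y = rng.normal(50, 5, 20)
        for form in ("LBL", "QBL"):
            f = lq.fit(x, y, form)
            sse_const = np.sum((y - y.mean()) ** 2)
            assert f.quality.sse <= sse_const + 1e-9

    def test_stochastic_break_point_recovery(self, oxide_ep_model, oxide_doses):
        """Replicate noise calibrated to the trial: mean break near truth."""
        Rs = []
        for s in range(120):
            x, y = lq.simulate_trait_observations(oxide_ep_model, oxide_doses,
                                                  6, 4.1, seed=5000 + s)
            Rs.append(lq.fit(x, y, "LBL").params.R)
        Rs = np.array(Rs)
        assert abs(Rs.mean() - 82.0) < 10.0


def _oracle_sse(x, y, r, form):
    z = np.where(x < r, r - x, 0.0)
    if form == "QBL":
        z = z * z
    A = np.column_stack([np.ones_like(x), z])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((y - A @ coef) ** 2))


class TestFitQuality:
    def test_closed_form_aic(self):
        y = np.array([0.0, 0.0, 2.0, 0.0])
        pred = np.zeros(4)                       # SSE = 4, N = 4
        q = lq.fit_quality(y, pred, k=1)         # P = 2
        assert q.aic == pytest.approx(4 * math.log(1.0) + 4)

    def test_perfect_fit_sentinel(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        q = lq.fit_quality(y, y, k=3)
        assert q.r2 == 1.0 and q.rmse == 0.0
        assert q.perfect and q.aic == float("-inf")

    def test_matches_direct_summation_oracle(self, rng):
        y = rng.normal(70, 5, 10)
        pred = y + rng.normal(0, 1, 10)
        q = lq.fit_quality(y, pred, k=3)
        sse = sum((a - b) ** 2 for a, b in zip(y, pred))
        sst = sum((a - y.mean()) ** 2 for a in y)
        assert q.sse == pytest.approx(sse, rel=1e-10)
        assert q.r2 == pytest.approx((sst - sse) / sst, rel=1e-10)
        assert q.rmse == pytest.approx(math.sqrt(sse / 10), rel=1e-10)
        assert q.aic == pytest.approx(10 * math.log(sse / 10) + 2 * 4, rel=1e-10)
        assert q.adj_r2 == pytest.approx(1 - (1 - q.r2) * 9 / (10 - 4), rel=1e-10)


class TestSelectModel:
    def test_lbl_generated_data_ranks_lbl_first(self, rng):
        truth = BrokenLineParams(form="LBL", L=75.0, U=-0.07, R=60.0)
        x = np.array([10.0, 25.0, 40.0, 55.0, 80.0, 100.0])
        y = lq.predict(truth, x)
        fits = [lq.fit(x, y, f) for f in ("QBL", "LBL")]
        ranked = lq.select_model(fits)
        assert ranked[0].params.form == "LBL"

    def test_qbl_generated_data_ranks_qbl_first(self):
        truth = BrokenLineParams(form="QBL", L=78.0, U=-0.009, R=60.0)
        x = np.array([10.0, 25.0, 40.0, 55.0, 80.0, 100.0])
        y = lq.predict(truth, x)
        ranked = lq.select_model([lq.fit(x, y, f) for f in ("LBL", "QBL")])
        assert ranked[0].params.form == "QBL"

    def test_identical_fits_keep_input_order(self, rng):
        x = np.sort(rng.uniform(10, 100, 12))
        y = rng.normal(70, 3, 12)
        f1 = lq.fit(x, y, "LBL")
        f2 = lq.fit(x, y, "LBL")
        assert lq.select_model([f1, f2])[0] is f1

    def test_fits_on_different_data_rejected(self, rng):
        x = np.sort(rng.uniform(10, 100, 12))
        f1 = lq.fit(x, rng.normal(70, 3, 12), "LBL")
        f2 = lq.fit(x, rng.normal(70, 3, 12), "LBL")
        with pytest.raises(ComparisonError):
            lq.select_model([f1, f2])
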