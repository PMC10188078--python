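"""Trait formulas and the derived trait table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import layreq as lq
from layreq.errors import DataIntegrityError, UndefinedTraitError
from layreq.traits import compute_traits


class TestHenDayEP:
    @pytest.mark.parametrize("eggs,hd,expected", [
        (0, 336, 0.0),
        (336, 336, 100.0),
        (237, 336, 100 * 237 / 336),   # 70.54 at report precision
    ])
    def test_values(self, eggs, hd, expected):
        assert lq.hen_day_ep(eggs, hd) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(UndefinedTraitError):
            lq.hen_day_ep(10, 0)
        with pytest.raises(DataIntegrityError):
            lq.hen_day_ep(400, 336)


class TestFeedIntakeAndFCR:
    @pytest.mark.parametrize("off,res,hd,expected", [
        (1000, 0, 10, 100.0),
        (0, 0, 10, 0.0),
        (39062, 78, 336, (39062 - 78) / 336),   # 116.0 g/b/d
    ])
    def test_feed_intake(self, off, res, hd, expected):
        assert lq.feed_intake(off, res, hd) == pytest.approx(expected)

    def test_residual_exceeding_offered_rejected(self):
        with pytest.raises(DataIntegrityError):
            lq.feed_intake(100, 200, 10)

    @pytest.mark.parametrize("feed,em,expected", [
        (100, 100, 1.0), (2579, 1000, 2.579),
    ])
    def test_fcr(self, feed, em, expected):
        assert lq.fcr(feed, em) == pytest.approx(expected)

    def test_fcr_zero_egg_mass(self):
        with pytest.raises(UndefinedTraitError):
            lq.fcr(100, 0)

    def test_fcr_of_totals_differs_from_mean_of_period_ratios(self):
        # Two periods with equal feed but unequal egg mass: the ratio of
        # totals is not the average of the period ratios.
        feed = [1000.0, 1000.0]
        em = [500.0, 250.0]
        total_ratio = lq.fcr(sum(feed), sum(em))
        mean_ratio = np.mean([lq.fcr(f, e) for f, e in zip(feed, em)])
        assert total_ratio == pytest.approx(2000 / 750)
        assert total_ratio != pytest.approx(mean_ratio)


class TestEggQualityFormulas:
    @pytest.mark.parametrize("w,l,expected", [
        (50, 50, 100.0), (42, 56, 75.0), (39.9, 57.0, 70.0),
    ])
    def test_shape_index(self, w, l, expected):
        assert lq.shape_index(w, l) == pytest.approx(expected)

    def test_shape_index_width_over_length_rejected(self):
        with pytest.raises(DataIntegrityError):
            lq.shape_index(60, 50)

    def test_haugh_log_argument_ten_gives_100(self):
        w = 60.0
        h = 10.0 - 7.57 + 1.7 * w ** 0.37
        assert lq.haugh_unit(h, w) == pytest.approx(100.0)

    def test_haugh_worked_example(self):
        # 60^0.37 ≈ 4.549 → 100·log10(7 + 7.57 − 7.733) ≈ 83.49
        assert lq.haugh_unit(7.0, 60.0) == pytest.approx(83.49, abs=0.01)

    def test_haugh_undefined_for_nonpositive_argument(self):
        with pytest.raises(UndefinedTraitError):
            lq.haugh_unit(0.01, 5000.0)

    @given(h=st.floats(3.0, 12.0), dh=st.floats(0.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_haugh_increasing_in_albumen_height(self, h, dh):
        w = 60.0
        assert lq.haugh_unit(h + dh, w) > lq.haugh_unit(h, w)

    @pytest.mark.parametrize("shell,egg,expected", [
        (10, 100, 10.0), (5.93, 66.42, 100 * 5.93 / 66.42),
    ])
    def test_relative_shell_weight(self, shell, egg, expected):
        assert lq.relative_shell_weight(shell, egg) == pytest.approx(expected)

    def test_relative_shell_weight_bounds(self):
        with pytest.raises(DataIntegrityError):
            lq.relative_shell_weight(70, 66)

    def test_mean_shell_thickness(self):
        assert lq.mean_shell_thickness(400, 400, 400) == 400
        assert lq.mean_shell_thickness(390, 394, 398) == 394

    @given(st.permutations([390.0, 394.0, 398.0]))
    @settings(max_examples=6, deadline=None)
    def test_thickness_permutation_invariant(self, sites):
        assert lq.mean_shell_thickness(*sites) == pytest.approx(394.0)


class TestTraitTable:
    def test_em_identity_every_row(self, noise_free_replicates):
        tt = compute_traits(noise_free_replicates)
        em = tt["egg_production"] / 100 * tt["egg_weight"]
        assert np.allclose(em, tt["egg_mass"], rtol=1e-9)

    def test_fcr_equals_fi_over_em(self, noise_free_replicates):
        tt = compute_traits(noise_free_replicates)
        assert np.allclose(tt["fcr"], tt["feed_intake"] / tt["egg_mass"],
                           rtol=1e-9)

    def test_overall_row_is_hen_day_weighted(self, design):
        truths = {
            "egg_production": lq.SyntheticTruth(
                models={s: lq.constant_truth(80.0) for s in design.sources}),
        }
        reps = lq.simulate_replicates(design, truths, seed=3)
        tt = compute_traits(reps)
        ov = tt[tt["period"] == "overall"]
        per = tt[tt["period"] != "overall"]
        # equal hen-days per period, so weighted == simple here; totals match
        total_eggs = reps.groupby(["treatment", "replicate"])["eggs_laid"].sum()
        total_hd = reps.groupby(["treatment", "replicate"])["hen_days"].sum()
        expected = (100 * total_eggs / total_hd).reset_index(drop=True)
        assert np.allclose(ov["egg_production"].to_numpy(),
                           expected.to_numpy(), rtol=1e-12)
        assert len(ov) * design.n_periods == len(per)

    def test_albumen_bookkeeping(self, design):
        eggs = lq.simulate_eggs(design, sds={}, seed=5)
        tt = compute_traits_min(eggs)
        total = tt["albumen_weight"] + tt["yolk_weight"]
        # albumen derived by subtraction: egg = albumen + yolk + shell exactly
        merged = eggs.groupby(["treatment", "replicate", "period"]).agg(
            egg=("egg_weight_g", "mean"), shell=("shell_g", "mean"))
        assert np.allclose(total.to_numpy() + merged["shell"].to_numpy(),
                           merged["egg"].to_numpy(), rtol=1e-12)


def compute_traits_min(eggs: pd.DataFrame) -> pd.DataFrame:
    """Egg-quality block only, keyed like the egg table (period rows)."""
    from layreq.traits import _egg_row
    return (eggs.groupby(["treatment", "replicate", "period"])
            .apply(_egg_row, include_groups=False).reset_index())
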