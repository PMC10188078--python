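"""ANOVA, Tukey compact letters, orthogonal dose contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import layreq as lq
from layreq.errors import LayreqError
from layreq.group_stats import anova_report, orthogonal_poly_coefs


def _long(groups: dict) -> pd.DataFrame:
    rows = [{"treatment": g, "y": v} for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


def brute_force_f(groups: dict):
    """Direct sums-of-squares one-way ANOVA (independent oracle)."""
    all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    grand = all_vals.mean()
    ss_t = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_e = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values())
    df_t = len(groups) - 1
    df_e = all_vals.size - len(groups)
    f = (ss_t / df_t) / (ss_e / df_e)
    return f, ss_t, ss_e, df_e


class TestOneWayAnova:
    def test_all_equal_gives_f_zero_p_one(self):
        res = lq.one_way_anova(_long({g: [5.0] * 4 for g in "abc"}), "y")
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        res = lq.one_way_anova(_long({"a": a, "b": b}), "y")
        t, p = stats.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = {g: rng.normal(70 + 2 * i, 4, 6) for i, g in enumerate(range(10))}
        res = lq.one_way_anova(_long(groups), "y")
        f, ss_t, ss_e, df_e = brute_force_f(groups)
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.mse == pytest.approx(ss_e / df_e, rel=1e-10)
        assert res.df_resid == df_e
        assert res.sem == pytest.approx(np.sqrt(res.mse / 6), rel=1e-12)

    def test_ss_decomposition(self, rng):
        groups = {g: rng.normal(0, 1, 5) for g in range(4)}
        all_vals = np.concatenate(list(groups.values()))
        sst = np.sum((all_vals - all_vals.mean()) ** 2)
        _, ss_t, ss_e, _ = brute_force_f(groups)
        assert ss_t + ss_e == pytest.approx(sst, rel=1e-9)

    def test_unbalanced_warns(self, rng):
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 4),
                  "c": rng.normal(0, 1, 6)}
        with pytest.warns(UserWarning, match="unbalanced"):
            res = lq.one_way_anova(_long(groups), "y")
        assert not res.balanced


class TestTukeyCLD:
    def test_identical_means_share_one_letter(self):
        letters = lq.tukey_cld({g: 5.0 for g in "abcd"}, mse=1.0, df=20, r=6)
        assert set(letters.values()) == {"a"}

    def test_widely_separated_means_get_disjoint_letters(self):
        q = stats.studentized_range.ppf(0.95, 2, 10)
        hsd = q * np.sqrt(1.0 / 5)
        letters = lq.tukey_cld({"lo": 0.0, "hi": 10 * hsd}, 1.0, 10, 5)
        assert set(letters["lo"]) & set(letters["hi"]) == set()

    def test_chain_pattern_middle_carries_both_letters(self):
        k, df, r, mse = 3, 12, 5, 1.0
        q = stats.studentized_range.ppf(0.95, k, df)
        hsd = q * np.sqrt(mse / r)
        means = {"A": 0.0, "B": 0.9 * hsd, "C": 1.8 * hsd}
        letters = lq.tukey_cld(means, mse, df, r)
        assert set(letters["A"]) & set(letters["C"]) == set()
        assert set(letters["B"]) >= set(letters["A"]) | set(letters["C"]) \
            or (set(letters["B"]) & set(letters["A"])
                and set(letters["B"]) & set(letters["C"]))

    def test_letters_invariant_under_relabeling(self, rng):
        means = {f"t{i}": m for i, m in enumerate(rng.normal(70, 3, 6))}
        base = lq.tukey_cld(means, mse=4.0, df=30, r=6)
        perm = dict(reversed(list(means.items())))
        relabeled = lq.tukey_cld(perm, mse=4.0, df=30, r=6)
        assert {g: set(v) for g, v in base.items()} == \
               {g: set(v) for g, v in relabeled.items()}

    def test_no_letter_shared_across_hsd(self, rng):
        mse, df, r = 4.0, 50, 6
        q = stats.studentized_range.ppf(0.95, 10, df)
        hsd = q * np.sqrt(mse / r)
        means = {f"t{i}": m for i, m in enumerate(rng.normal(70, 4, 10))}
        letters = lq.tukey_cld(means, mse, df, r)
        for g1 in means:
            for g2 in means:
                if abs(means[g1] - means[g2]) > hsd:
                    assert set(letters[g1]) & set(letters[g2]) == set()

    def test_df_must_be_positive(self):
        with pytest.raises(LayreqError):
            lq.tukey_cld({"a": 1, "b": 2}, 1.0, 0, 3)


class TestPolyContrasts:
    def test_equally_spaced_linear_is_classical_table(self):
        coefs = orthogonal_poly_coefs([0, 1, 2, 3], degree=1)
        lin = coefs[0]
        assert np.allclose(lin / lin[-1] * 3, [-3, -1, 1, 3])

    def test_linear_means_give_zero_quadratic_estimate(self):
        doses = [10.4, 40.2, 70.75, 100.6]
        means = [2.0 + 0.05 * d for d in doses]
        out = lq.poly_dose_contrasts(means, doses, mse=1.0, df=20, r=6)
        assert out["quadratic"]["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert out["linear"]["p"] < 1e-6

    def test_unequal_spacing_matches_gram_schmidt_oracle(self):
        doses = np.array([10.4, 40.2, 70.75, 100.6])
        coefs = orthogonal_poly_coefs(doses, degree=2)
        # independent oracle: QR of the Vandermonde basis
        V = np.vander(doses, 3, increasing=True)
        Q, _ = np.linalg.qr(V)
        for row, col in zip(coefs, (1, 2)):
            ref = Q[:, col]
            sign = np.sign(ref @ row)
            assert np.allclose(row, sign * ref, atol=1e-12)
        assert abs(coefs[0] @ coefs[1]) < 1e-12
        assert abs(coefs.sum(axis=1)).max() < 1e-12

    def test_quadratic_omitted_below_three_levels(self):
        with pytest.warns(UserWarning, match="quadratic"):
            out = lq.poly_dose_contrasts([1.0, 2.0], [0.0, 30.0],
                                         mse=1.0, df=10, r=6)
        assert "quadratic" not in out


class TestTreatmentAnalysis:
    def test_full_table_structure(self, design, noise_free_replicates):
        tt = lq.compute_traits(noise_free_replicates)
        overall = tt[tt["period"] == "overall"].copy()
        # add tiny deterministic jitter so MSE > 0
        rng = np.random.default_rng(0)
        overall["egg_production"] = (overall["egg_production"]
                                     + rng.normal(0, 0.5, len(overall)))
        res = lq.treatment_analysis(overall, "egg_production", design)
        assert set(res.letters) == {t.id for t in design.treatments}
        assert set(res.contrasts) == set(design.sources)
        for c in res.contrasts.values():
            assert 0 <= c["linear"]["p"] <= 1
            assert 0 <= c["quadratic"]["p"] <= 1
        rep = anova_report(res)
        assert {"SEM", "F", "p"} <= set(rep["row"])
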