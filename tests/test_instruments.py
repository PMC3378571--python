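"""Orientation, allele scores, first-stage statistics, search, trend tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bimr.instruments import (
    build_score,
    collapse_low_categories,
    confounder_balance,
    first_stage_fit,
    orient_risk_alleles,
    search_best_instrument,
    trend_test,
)
from bimr.estimation import tsls_fit
from bimr.synthetic import SnpDef, simulate_genotypes


def _random_dosages(rng, n, m, prefix="rs"):
    return pd.DataFrame(
        rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.45, 0.42, 0.13]),
        columns=[f"{prefix}{i}" for i in range(m)],
    )


class TestOrientation:
    def test_positive_slope_unchanged(self, rng):
        d = _random_dosages(rng, 300, 1)
        y = 0.3 * d["rs0"].to_numpy() + rng.standard_normal(300)
        oriented, flips = orient_risk_alleles(d, y)
        assert not flips["rs0"]
        assert (oriented["rs0"] == d["rs0"]).all()

    def test_negative_slope_flipped_to_positive(self, rng):
        d = _random_dosages(rng, 300, 1)
        y = -0.3 * d["rs0"].to_numpy() + rng.standard_normal(300)
        oriented, flips = orient_risk_alleles(d, y)
        assert flips["rs0"]
        slope = np.polyfit(oriented["rs0"], y, 1)[0]
        assert slope > 0

    def test_orienting_twice_is_identity(self, rng):
        d = _random_dosages(rng, 300, 3)
        y = rng.standard_normal(300)
        once, _ = orient_risk_alleles(d, y)
        twice, flips2 = orient_risk_alleles(once, y)
        assert not any(flips2.values())
        pd.testing.assert_frame_equal(once, twice)

    def test_monomorphic_rejected(self, rng):
        d = pd.DataFrame({"rs0": np.ones(50)})
        with pytest.raises(ValueError, match="monomorphic"):
            orient_risk_alleles(d, rng.standard_normal(50))


class TestScore:
    @pytest.mark.parametrize(
        "dosages,expected", [((2, 2, 2), 6), ((0, 0, 0), 0), ((0, 1, 2), 3)]
    )
    def test_additive_sum(self, dosages, expected):
        frame = pd.DataFrame([dosages], columns=["a", "b", "c"], dtype=float)
        assert build_score(frame).iloc[0] == expected

    def test_missing_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            build_score(frame)

    @given(
        st.lists(
            st.tuples(*[st.sampled_from([0.0, 1.0, 2.0])] * 3),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_three_snp_score_bounded_with_seven_categories(self, rows):
        frame = pd.DataFrame(rows, columns=["a", "b", "c"])
        score = build_score(frame)
        assert score.between(0, 6).all()
        assert score.nunique() <= 7

    def test_collapse_merges_low_categories(self):
        out = collapse_low_categories([0, 1, 2, 3, 6])
        assert out.tolist() == [2.0, 2.0, 2.0, 3.0, 6.0]

    def test_collapse_preserves_order(self):
        scores = np.repeat(np.arange(7), 3)
        out = collapse_low_categories(scores)
        assert (np.diff(out) >= 0).all()
        assert sorted(out.unique()) == [2.0, 3.0, 4.0, 5.0, 6.0]

    def test_collapse_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            collapse_low_categories([0, 7])


class TestFirstStage:
    def test_f_r2_identity_single_regressor(self, rng):
        # F = R2 (n-2) / (1 - R2), exact on any single-regressor fit
        for _ in range(20):
            n = int(rng.integers(30, 200))
            x = rng.standard_normal(n)
            y = rng.uniform(0, 1) * x + rng.standard_normal(n)
            fit = first_stage_fit(y, x)
            expected = fit.r_squared * (n - 2) / (1 - fit.r_squared)
            assert fit.f_statistic == pytest.approx(expected, abs=1e-10)

    def test_known_f_from_r2(self, rng):
        # n=102 with sample R2 exactly 0.5 gives F = 0.5*(n-2)/0.5 = 100
        n = 102
        x = np.tile([1.0, -1.0], n // 2)
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= (e @ x) / (x @ x) * x  # orthogonal to x, centered
        e *= np.linalg.norm(x) / np.linalg.norm(e)  # equal norm -> R2 = 1/2
        fit = first_stage_fit(x + e, x)
        assert fit.r_squared == pytest.approx(0.5, abs=1e-12)
        assert fit.f_statistic == pytest.approx(100.0, abs=1e-8)

    def test_perfect_fit_flagged_infinite(self, rng):
        x = rng.standard_normal(50)
        fit = first_stage_fit(2 * x + 1, x)
        assert math.isinf(fit.f_statistic)

    def test_null_instrument_f_near_one(self, rng):
        # E[F] for a null single regressor is (n-2)/(n-4)
        n, reps = 200, 300
        fs = []
        for _ in range(reps):
            fs.append(first_stage_fit(rng.standard_normal(n), rng.standard_normal(n)).f_statistic)
        assert np.mean(fs) == pytest.approx((n - 2) / (n - 4), abs=0.25)

    def test_partial_f_reported_with_covariates(self, rng):
        n = 500
        z = rng.standard_normal(n)
        w = rng.standard_normal(n)
        y = 0.3 * z + 0.5 * w + rng.standard_normal(n)
        fit = first_stage_fit(y, z, covariates=w)
        assert fit.partial_f is not None
        assert 0 < fit.partial_f < fit.f_statistic * 2


class TestSearch:
    def test_enumerates_all_combinations_and_matches_brute_force(self, rng):
        n, m, k = 400, 6, 3
        snps = [SnpDef(f"rs{i}", "FTO", 0.2 + 0.04 * i) for i in range(m)]
        d = simulate_genotypes(n, snps, seed=8)
        y = 0.2 * d["rs2"] - 0.15 * d["rs4"] + rng.standard_normal(n)
        spec, fit, table = search_best_instrument(d, y, k=k)
        assert len(table) == math.comb(m, k)

        # independent brute force: per combination, orient by correlation
        # sign, sum, compute F from the squared correlation
        best_f, best_combo = -np.inf, None
        for combo in itertools.combinations(sorted(d.columns), k):
            sub = d[list(combo)].to_numpy()
            yy = np.asarray(y)
            signs = np.array(
                [1.0 if np.corrcoef(sub[:, j], yy)[0, 1] >= 0 else -1.0 for j in range(k)]
            )
            score = (np.where(signs > 0, sub, 2 - sub)).sum(axis=1)
            r2 = np.corrcoef(score, yy)[0, 1] ** 2
            f = r2 * (n - 2) / (1 - r2)
            if f > best_f:
                best_f, best_combo = f, combo
        assert spec.snp_ids == best_combo
        assert fit.f_statistic == pytest.approx(best_f, rel=1e-10)

    def test_four_choose_three_evaluates_four(self, rng):
        snps = [SnpDef(f"rs{i}", "FTO", 0.3) for i in range(4)]
        d = simulate_genotypes(300, snps, seed=9)
        _, _, table = search_best_instrument(d, rng.standard_normal(300), k=3)
        assert len(table) == 4

    def test_weak_flag_on_null_snps(self, rng):
        snps = [SnpDef(f"rs{i}", "FTO", 0.3) for i in range(4)]
        d = simulate_genotypes(1000, snps, seed=10)
        _, fit, _ = search_best_instrument(d, rng.standard_normal(1000), k=3)
        assert fit.weak

    def test_single_snp_instrument(self, rng):
        snps = [SnpDef(f"rs{i}", "SLC2A9", 0.3) for i in range(3)]
        d = simulate_genotypes(800, snps, seed=11)
        y = 0.25 * d["rs1"] + rng.standard_normal(800)
        spec, fit, _ = search_best_instrument(d, y, k=1)
        assert spec.snp_ids == ("rs1",)
        assert spec.score_type == "single_snp"
        assert not fit.weak

    def test_too_few_candidates_rejected(self, rng):
        d = _random_dosages(rng, 100, 2)
        with pytest.raises(ValueError, match="candidates"):
            search_best_instrument(d, rng.standard_normal(100), k=3)

    def test_downstream_tsls_invariant_to_precoding_flip(self, rng):
        # flipping a SNP's allele coding upstream is absorbed by orientation
        n = 600
        snps = [SnpDef(f"rs{i}", "FTO", 0.3) for i in range(3)]
        d = simulate_genotypes(n, snps, seed=12)
        x = 0.15 * build_score(d).to_numpy() + rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)

        def run(dosages):
            oriented, _ = orient_risk_alleles(dosages, x)
            res, _ = tsls_fit(y, x, build_score(oriented).to_numpy())
            return res.beta

        flipped = d.copy()
        flipped["rs1"] = 2.0 - flipped["rs1"]
        assert run(d) == pytest.approx(run(flipped), abs=1e-10)


class TestTrendTest:
    def test_reversing_levels_flips_sign(self, rng):
        y = rng.standard_normal(200)
        levels = rng.integers(0, 4, size=200)
        z1, p1 = trend_test(y, levels)
        z2, p2 = trend_test(y, levels.max() - levels)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_power_on_monotone_shift(self, rng):
        levels = rng.integers(0, 3, size=300)
        y = 1.0 * levels + rng.standard_normal(300)
        z, p = trend_test(y, levels)
        assert z > 0 and p < 0.001

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            trend_test(rng.standard_normal(50), np.zeros(50))

    def test_type_one_error_near_nominal(self, rng):
        rejected = 0
        reps = 500
        for _ in range(reps):
            levels = rng.integers(0, 5, size=120)
            _, p = trend_test(rng.standard_normal(120), levels)
            rejected += p < 0.05
        assert abs(rejected / reps - 0.05) < 0.02


class TestConfounderBalance:
    def test_positive_control_detected(self, rng):
        z = rng.choice([0.0, 1.0, 2.0], size=1000)
        conf = pd.DataFrame({"lifestyle": 0.5 * z + rng.standard_normal(1000)})
        report = confounder_balance(z, conf)
        assert report.loc[0, "p_value"] < 1e-6
        assert report.loc[0, "kind"] == "continuous"

    def test_independent_confounder_not_flagged(self, rng):
        z = rng.choice([0.0, 1.0, 2.0], size=1000)
        conf = pd.DataFrame(
            {"age": rng.normal(50, 10, 1000), "smoking": rng.integers(0, 2, 1000)}
        )
        report = confounder_balance(z, conf)
        assert set(report["confounder"]) == {"age", "smoking"}
        assert (report["p_value"] > 1e-4).all()  # no spurious strong signal

    def test_empty_confounder_list(self, rng):
        report = confounder_balance(rng.choice([0.0, 1.0], 100), pd.DataFrame())
        assert report.empty

    def test_categorical_uses_chi_square(self, rng):
        z = rng.choice([0.0, 1.0, 2.0], size=500)
        conf = pd.DataFrame({"sex": rng.choice(["M", "F"], size=500)})
        report = confounder_balance(z, conf)
        assert report.loc[0, "kind"] == "categorical"
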