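"""Reliability (ICC), reproducibility (RMSSD), and setting comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneemap.stats import (
    RepeatedMeasures,
    classify_icc,
    compare_settings,
    evaluate_settings,
    icc_two_way_random,
    rmssd,
)
from kneemap.synthetic import make_repeated_dataset


def _icc_anova_oracle(x):
    """Brute-force two-way ANOVA mean squares via explicit sums."""
    n, k = x.shape
    g = x.mean()
    msr = k * sum((x[i].mean() - g) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - g) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + g) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_two_way_random(x) == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1)) * 3
            assert icc_two_way_random(x) == pytest.approx(
                _icc_anova_oracle(x), abs=1e-12
            )

    def test_matches_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(10, 2)) * 5 + rng.normal(size=(10, 1)) * 10
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(10), 2),
                "r": np.tile([0, 1], 10),
                "y": x.reshape(-1),
            }
        )
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_two_way_random(x) == pytest.approx(icc2, abs=1e-10)

    def test_variance_component_limit(self, rng):
        """Mean ICC over many replicate cells approaches
        sigma_b^2 / (sigma_b^2 + sigma_e^2); with only 6 knees the
        estimator carries a small negative finite-sample bias."""
        sb, se = 3.0, 1.0
        iccs = [
            icc_two_way_random(
                rng.normal(0, sb, (6, 1)) + rng.normal(0, se, (6, 2))
            )
            for _ in range(2000)
        ]
        assert np.mean(iccs) == pytest.approx(sb**2 / (sb**2 + se**2), abs=0.06)

    def test_degenerate_zero_variance(self):
        assert np.isnan(icc_two_way_random(np.full((5, 2), 7.0)))

    @given(
        shift=st.floats(-1000, 1000),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariance_under_affine_rescaling(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 2
        base = icc_two_way_random(x)
        assert icc_two_way_random(x * scale + shift) == pytest.approx(base, abs=1e-8)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "icc, expected",
        [
            (0.45, "poor"),
            (0.5, "moderate"),
            (0.6, "moderate"),
            (0.75, "good"),
            (0.80, "good"),
            (0.9, "excellent"),
            (0.95, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_thresholds(self, icc, expected):
        assert classify_icc(icc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


class TestRmssd:
    def test_identical_repeats(self):
        assert rmssd(np.array([[5.0, 5.0], [9.0, 9.0]])) == 0.0

    def test_single_pair_is_sqrt2(self):
        assert rmssd(np.array([[100.0, 102.0]])) == pytest.approx(np.sqrt(2))

    def test_squared_rmssd_unbiased_for_noise_variance(self, rng):
        """Monte-Carlo: mean RMSSD^2 over replicate cells ~ sigma^2."""
        vals = [
            rmssd(rng.normal(0, 10.0, (10, 2))) ** 2 for _ in range(2000)
        ]
        assert np.mean(vals) == pytest.approx(100.0, rel=0.05)

    @given(scale=st.floats(0.01, 100), shift=st.floats(-500, 500))
    @settings(max_examples=25, deadline=None)
    def test_scales_linearly_and_shift_invariant(self, scale, shift):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 10, (6, 2))
        base = rmssd(x)
        assert rmssd(x * scale + shift) == pytest.approx(base * scale, rel=1e-9)


def _wilcoxon_exact_p_oracle(d):
    """Exhaustive signed-rank null: enumerate all 2^n sign patterns."""
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    # two-sided: distance of W+ from its mean
    dev = abs(w_obs - total / 2)
    p = np.mean(np.abs(stats - total / 2) >= dev - 1e-12)
    return p


class TestCompareSettings:
    def test_identical_vectors_degenerate(self):
        v = np.arange(10.0)
        z, p, p_adj, r = compare_settings(v, v)
        assert (z, p, p_adj, r) == (0.0, 1.0, 1.0, 0.0)

    def test_bonferroni_arithmetic(self, rng):
        a = rng.normal(size=30)
        b = a + 1.0
        _, p, p_adj, _ = compare_settings(a, b, n_comparisons=3)
        assert p_adj == pytest.approx(min(1.0, 3 * p))

    def test_exact_mode_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(0.5, 1.0, 10)
        _, p_exact, _, _ = compare_settings(a, b, exact=True)
        d = a - b
        assert p_exact == pytest.approx(_wilcoxon_exact_p_oracle(d), abs=1e-12)

    def test_approx_mode_near_exact_for_n12(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(0.8, 1.0, 12)
        _, p_approx, _, _ = compare_settings(a, b, exact=False)
        _, p_exact, _, _ = compare_settings(a, b, exact=True)
        assert p_approx == pytest.approx(p_exact, abs=0.05)

    def test_effect_size_is_z_over_sqrt_n(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.3, 1.0, 40)
        z, _, _, r = compare_settings(a, b)
        assert r == pytest.approx(abs(z) / np.sqrt(40))


class TestEvaluateSettings:
    def test_perfect_data(self):
        base = np.tile(np.arange(5, dtype=float)[:, None, None] * 10 + 100, (1, 4, 2))
        base += np.arange(4)[None, :, None] * 5.0  # knee differences
        rm = RepeatedMeasures(values=base)
        res = evaluate_settings({"a": rm})
        df = res.per_cell
        assert (df["rmssd"] == 0).all()
        # repeats identical, knees differ -> ICC 1
        assert np.allclose(df["icc"], 1.0)
        assert res.comparisons.empty or (res.comparisons["p_adjusted"] == 1.0).all()

    def test_noise_ordering_recovered(self):
        measures, _ = make_repeated_dataset(
            n_cells=400,
            per_setting_sigmas={"low": 4.0, "mid": 7.0, "high": 10.0},
            seed=5,
        )
        res = evaluate_settings(measures)
        med = res.summary.set_index("setting")["rmssd_median"]
        assert med["low"] < med["mid"] < med["high"]

    def test_grid_mismatch_rejected(self):
        a = RepeatedMeasures(values=np.zeros((5, 3, 2)))
        b = RepeatedMeasures(values=np.zeros((6, 3, 2)))
        with pytest.raises(ValueError, match="grid"):
            evaluate_settings({"a": a, "b": b})

    def test_missing_cells_complete_case(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(100, 10, (3, 5, 2))
        vals[0, 2, 1] = np.nan  # one knee incomplete in cell 0
        res = evaluate_settings({"a": RepeatedMeasures(values=vals)})
        used = res.per_cell.set_index("cell_id")["n_knees_used"]
        assert used.loc[0] == 4 and used.loc[1] == 5
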