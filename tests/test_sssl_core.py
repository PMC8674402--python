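import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from segmap.errors import (
    DegenerateInputError,
    DomainError,
    InputError,
    UndefinedStatisticError,
)
from segmap.sssl_core import (
    anova_blocks,
    arcsine_transform,
    detect_line_qtl,
    estimate_H2,
    estimate_effect,
    round_half_away,
)

from conftest import make_line


class TestArcsineTransform:
    def test_boundaries(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(math.pi / 2)
        assert arcsine_transform(0.5) == pytest.approx(math.pi / 4)

    @pytest.mark.parametrize("bad", [-0.01, 1.01, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            arcsine_transform(bad)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone(self, p, q):
        lo, hi = sorted([p, q])
        assert arcsine_transform(lo) <= arcsine_transform(hi)

    def test_array_input(self):
        out = arcsine_transform([0.0, 0.25, 1.0])
        np.testing.assert_allclose(out, [0.0, math.pi / 6, math.pi / 2])


class TestEstimateEffect:
    def test_forced_arithmetic(self):
        a, r2 = estimate_effect(0.86, 0.54)
        assert a == pytest.approx(0.16)
        assert r2 == pytest.approx(0.16 / 0.54)  # ~0.296

    def test_identity(self):
        assert estimate_effect(0.4, 0.4) == (0.0, 0.0)

    def test_zero_parent(self):
        with pytest.raises(UndefinedStatisticError):
            estimate_effect(0.5, 0.0)

    def test_table_row_consistency(self):
        # implied parent mean a / R2 for a=0.16, R2=29.8% lies inside the
        # parent's printed seasonal range of 44.1-67.7%
        implied = 0.16 / 0.298
        assert 0.441 <= implied <= 0.677

    @given(
        st.floats(0.05, 0.95),
        st.floats(0.01, 0.5),
    )
    def test_antisymmetric_in_shift(self, parent, delta):
        a_plus, r2_plus = estimate_effect(min(parent + delta, 1.0), parent)
        a_minus, r2_minus = estimate_effect(max(parent - delta, 0.0), parent)
        if parent + delta <= 1.0 and parent - delta >= 0.0:
            assert a_plus == pytest.approx(-a_minus)
            assert r2_plus == pytest.approx(-r2_minus)


class TestDetectLineQTL:
    SEASONS = {"a": 0.6, "b": 0.55, "c": 0.5, "d": 0.45}

    def _parent(self, rng, reps=5, sd=0.03):
        return {
            s: list(np.clip(rng.normal(m, sd, reps), 0, 1))
            for s, m in self.SEASONS.items()
        }

    def test_null_line_not_detected(self):
        rng = np.random.default_rng(0)
        parent = self._parent(rng)
        line = make_line("L1", self.SEASONS, rng)
        res = detect_line_qtl(line, parent)
        assert not res.detected

    def test_identical_replicates_not_detected(self):
        from segmap.sssl_core import SSSLLine

        parent = {"a": [0.5, 0.52, 0.48], "b": [0.6, 0.61, 0.59]}
        line = SSSLLine("L1", "D", None, {k: list(v) for k, v in parent.items()})
        res = detect_line_qtl(line, parent)
        assert not res.detected
        assert res.detected_seasons == frozenset()

    def test_strong_shift_detected(self):
        # oracle: direct pooled-t on transformed values must agree per season
        rng = np.random.default_rng(42)
        parent = self._parent(rng)
        shifted = {s: m + 0.30 for s, m in self.SEASONS.items()}
        line = make_line("L1", shifted, rng)
        res = detect_line_qtl(line, parent, alpha=0.001, min_seasons=2)
        assert res.detected
        assert len(res.detected_seasons) >= 2
        for season, stats_ in res.per_season.items():
            t, p = stats.ttest_ind(
                arcsine_transform(np.array(line.phenotypes[season])),
                arcsine_transform(np.array(parent[season])),
                equal_var=True,
            )
            assert stats_.p_value == pytest.approx(p)

    def test_single_season_shift_never_detected(self):
        rng = np.random.default_rng(3)
        parent = self._parent(rng)
        means = dict(self.SEASONS)
        means["a"] += 0.35  # massive shift in one season only
        line = make_line("L1", means, rng, sd=0.01)
        res = detect_line_qtl(line, parent, alpha=0.001, min_seasons=2)
        assert not res.detected

    def test_alpha_one_flags_everything_alpha_zero_nothing(self):
        rng = np.random.default_rng(7)
        parent = self._parent(rng)
        line = make_line("L1", self.SEASONS, rng)
        assert detect_line_qtl(line, parent, alpha=1.0).detected
        assert not detect_line_qtl(line, parent, alpha=0.0).detected

    def test_no_shared_seasons_errors(self):
        from segmap.sssl_core import SSSLLine

        line = SSSLLine("L1", "D", None, {"x": [0.5, 0.6]})
        with pytest.raises(InputError):
            detect_line_qtl(line, {"y": [0.5, 0.6]})

    def test_single_replicate_season_skipped(self, caplog):
        rng = np.random.default_rng(11)
        parent = self._parent(rng)
        line = make_line("L1", self.SEASONS, rng)
        line.phenotypes["a"] = [0.5]  # unusable season
        res = detect_line_qtl(line, parent)
        assert "a" not in res.per_season
        assert set(res.per_season) == {"b", "c", "d"}


class TestHeritability:
    def test_zero_within_variance(self):
        lines = {
            "L1": {"s": [0.2, 0.2, 0.2]},
            "L2": {"s": [0.8, 0.8, 0.8]},
            "L3": {"s": [0.5, 0.5, 0.5]},
        }
        res = estimate_H2(lines)
        assert res.per_season["s"] == pytest.approx(1.0)
        assert res.combined == pytest.approx(1.0)

    def test_identical_line_means(self):
        lines = {
            "L1": {"s": [0.4, 0.6]},
            "L2": {"s": [0.6, 0.4]},
            "L3": {"s": [0.5, 0.5]},
        }
        res = estimate_H2(lines)
        assert res.per_season["s"] == 0.0

    def test_monte_carlo_half(self):
        # sigma2_G == sigma2_e  ->  H2 = 0.5; MC over 100 repetitions
        rng = np.random.default_rng(123)
        sigma = 0.05
        estimates = []
        for _ in range(100):
            effects = rng.normal(0, sigma, 200)
            lines = {
                f"L{i}": {"s": list(0.5 + effects[i] + rng.normal(0, sigma, 10))}
                for i in range(200)
            }
            estimates.append(estimate_H2(lines).per_season["s"])
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_bounds_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(2, 8)
            lines = {
                f"L{i}": {
                    "s1": list(rng.uniform(0, 1, rng.integers(2, 6))),
                    "s2": list(rng.uniform(0, 1, rng.integers(2, 6))),
                }
                for i in range(k)
            }
            res = estimate_H2(lines)
            for h2 in [*res.per_season.values(), res.combined]:
                assert 0.0 <= h2 <= 1.0

    def test_too_few_lines(self):
        with pytest.raises(InputError):
            estimate_H2({"L1": {"s": [0.1, 0.2]}})


class TestAnovaBlocks:
    def test_identical_blocks_F_zero(self):
        f, p = anova_blocks([[1, 2, 3], [1, 2, 3]], transform=False)
        assert f == pytest.approx(0.0)

    def test_hand_anova(self):
        # between-SS 13.5 / df 1 over within-MS 1 -> F = 13.5
        f, p = anova_blocks([[1, 2, 3], [4, 5, 6]], transform=False)
        assert f == pytest.approx(13.5)

    def test_two_group_equals_t_squared(self):
        rng = np.random.default_rng(2)
        b1, b2 = rng.uniform(0.2, 0.8, 6), rng.uniform(0.2, 0.8, 7)
        f, p_f = anova_blocks([list(b1), list(b2)], transform=True)
        t, p_t = stats.ttest_ind(
            arcsine_transform(b1), arcsine_transform(b2), equal_var=True
        )
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            anova_blocks([[0.5, 0.5], [0.5, 0.5]])

    def test_block_too_small(self):
        with pytest.raises(InputError):
            anova_blocks([[0.5], [0.4, 0.6]])


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(30.95, 1, 31.0), (0.165, 2, 0.17), (-0.175, 2, -0.18), (28.35, 1, 28.4)],
    )
    def test_half_away(self, x, nd, expected):
        assert round_half_away(x, nd) == expected
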