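import numpy as np
import pytest
from scipy import stats

from segmap.errors import ConflictError, InputError, UndefinedStatisticError
from segmap.f2_genetics import (
    F2Individual,
    RecombinantPopulation,
    bp_length,
    fine_map,
    fit_model1,
    marker_trait_association,
    segregation_chi2,
)
from segmap.intervals import Interval


def balanced_f2(means, n_per_class=20, noise=0.0, rng=None):
    inds = []
    k = 0
    for code, mean in zip((1, 2, 3), means):
        for _ in range(n_per_class):
            y = mean + (rng.normal(0, noise) if rng is not None and noise else 0.0)
            inds.append(F2Individual(f"I{k}", {"M": code}, y))
            k += 1
    return inds


class TestSegregationChi2:
    def test_published_counts(self):
        chi2, df, p = segregation_chi2([85, 173, 98], [0.25, 0.5, 0.25])
        assert round(chi2, 2) == 1.23
        assert df == 2
        assert p > 0.05

    def test_exact_expectation(self):
        chi2, _, p = segregation_chi2([89, 178, 89], [0.25, 0.5, 0.25])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computation(self):
        # (30,30,30) vs 1:2:1: 2.5 + 5 + 2.5 = 10
        chi2, _, _ = segregation_chi2([30, 30, 30], [0.25, 0.5, 0.25])
        assert chi2 == pytest.approx(10.0)

    def test_matches_textbook_formula_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            counts = rng.integers(1, 300, size=3)
            ratio = rng.dirichlet([2, 2, 2])
            chi2, df, p = segregation_chi2(list(counts), list(ratio))
            expected = counts.sum() * ratio
            oracle = float(((counts - expected) ** 2 / expected).sum())
            assert chi2 == pytest.approx(oracle)
            assert p == pytest.approx(stats.chi2.sf(oracle, 2))

    def test_zero_expected_class(self):
        with pytest.raises(InputError):
            segregation_chi2([10, 10, 0], [0.5, 0.5, 0.0])

    def test_bad_ratio(self):
        with pytest.raises(InputError):
            segregation_chi2([10, 10], [0.6, 0.6])


class TestModel1:
    def test_balanced_group_means(self):
        # printed class means 52/65/78% -> a = 0.13, d = 0
        fit = fit_model1(balanced_f2([0.52, 0.65, 0.78]), "M")
        assert fit.a == pytest.approx(0.13, abs=1e-10)
        assert fit.d == pytest.approx(0.0, abs=1e-10)
        assert fit.mu == pytest.approx(0.65, abs=1e-10)

    def test_closed_form_contrasts_random_balanced(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            inds = balanced_f2(rng.uniform(0.2, 0.8, 3), n_per_class=15,
                               noise=0.05, rng=rng)
            fit = fit_model1(inds, "M")
            y = {c: np.mean([i.phenotype for i in inds if i.genotypes["M"] == c])
                 for c in (1, 2, 3)}
            assert fit.a == pytest.approx((y[3] - y[1]) / 2, rel=1e-10)
            assert fit.d == pytest.approx(y[2] - (y[1] + y[3]) / 2, rel=1e-10)

    def test_constant_phenotype(self):
        fit = fit_model1(balanced_f2([0.5, 0.5, 0.5]), "M")
        assert fit.a == pytest.approx(0.0)
        assert fit.d == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_pure_additive_truth(self):
        inds = balanced_f2([0.3, 0.5, 0.7])
        fit = fit_model1(inds, "M")
        assert fit.d == pytest.approx(0.0, abs=1e-12)

    def test_single_class_errors(self):
        inds = [F2Individual(f"I{i}", {"M": 2}, 0.5) for i in range(10)]
        with pytest.raises(InputError):
            fit_model1(inds, "M")

    def test_two_classes_flagged(self):
        inds = [F2Individual(f"I{i}", {"M": 1 if i % 2 else 3}, 0.4 + 0.01 * i)
                for i in range(10)]
        fit = fit_model1(inds, "M")
        assert "d" in fit.inestimable
        assert fit.d is None

    def test_missing_dropped(self):
        inds = balanced_f2([0.52, 0.65, 0.78])
        inds.append(F2Individual("X", {"M": None}, 0.9))
        inds.append(F2Individual("Y", {"M": 2}, None))
        fit = fit_model1(inds, "M")
        assert fit.n == 60


class TestAssociation:
    def test_perfect_monotone(self):
        inds = [F2Individual(f"I{i}", {"M": c}, 0.1 * c)
                for i, c in enumerate([1, 1, 2, 2, 3, 3])]
        r, p = marker_trait_association(inds, "M")
        assert r == pytest.approx(1.0)

    def test_null_large_n(self):
        rng = np.random.default_rng(4)
        inds = [
            F2Individual(f"I{i}", {"M": int(rng.integers(1, 4))},
                         float(rng.uniform()))
            for i in range(2000)
        ]
        r, p = marker_trait_association(inds, "M")
        assert abs(r) < 0.08

    def test_monte_carlo_effect(self):
        # a = 0.13, noise SD 0.1, n = 80: median r in [0.5, 0.8] over 200 reps
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(200):
            codes = rng.choice([1, 2, 3], size=80, p=[0.25, 0.5, 0.25])
            y = 0.5 + 0.13 * (codes - 2) + rng.normal(0, 0.1, 80)
            inds = [F2Individual(f"I{i}", {"M": int(c)}, float(v))
                    for i, (c, v) in enumerate(zip(codes, y))]
            rs.append(marker_trait_association(inds, "M")[0])
        assert 0.5 <= np.median(rs) <= 0.8

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        codes = rng.choice([1, 2, 3], size=50)
        y = rng.uniform(0, 1, 50)
        base = [F2Individual(f"I{i}", {"M": int(c)}, float(v))
                for i, (c, v) in enumerate(zip(codes, y))]
        scaled = [F2Individual(f"I{i}", {"M": int(c)}, float(3.5 * v + 1.2))
                  for i, (c, v) in enumerate(zip(codes, y))]
        r1, _ = marker_trait_association(base, "M")
        r2, _ = marker_trait_association(scaled, "M")
        assert r1 == pytest.approx(r2)

    def test_zero_variance(self):
        inds = [F2Individual(f"I{i}", {"M": 2}, float(i)) for i in range(5)]
        with pytest.raises(UndefinedStatisticError):
            marker_trait_association(inds, "M")

    def test_too_few(self):
        inds = [F2Individual("a", {"M": 1}, 0.1), F2Individual("b", {"M": 3}, 0.9)]
        with pytest.raises(InputError):
            marker_trait_association(inds, "M")


def pop(rid, lo, hi, p, marker="P", pos=None):
    return RecombinantPopulation(
        recomb_id=rid, chromosome="3", het_interval=Interval(lo, hi),
        marker_id=marker, marker_pos=pos, r=0.6 if p < 0.01 else 0.05, p=p,
    )


class TestFineMap:
    def test_fixture_332kb(self):
        from segmap import datasets

        intervals = fine_map(datasets.load_recombinants(), alpha=0.01)
        assert len(intervals) == 1
        assert bp_length(intervals[0]) == 332700
        assert intervals[0].start == 3067301
        assert intervals[0].end == 3400000

    def test_single_significant_identity(self):
        out = fine_map([pop("R1", 100, 900, 1e-5)], alpha=0.01)
        assert out == [Interval(100, 900)]

    def test_negative_covers_everything(self):
        with pytest.raises(ConflictError):
            fine_map(
                [pop("R1", 100, 900, 1e-5), pop("R2", 0, 1000, 0.5)], alpha=0.01
            )

    def test_no_significant_population(self):
        with pytest.raises(InputError):
            fine_map([pop("R1", 100, 900, 0.5)], alpha=0.01)

    def test_grid_oracle_small_intervals(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            sig = [pop(f"S{i}", *sorted(rng.integers(0, 5000, 2)), 1e-4)
                   for i in range(rng.integers(1, 3))]
            non = [pop(f"N{i}", *sorted(rng.integers(0, 5000, 2)), 0.5)
                   for i in range(rng.integers(0, 3))]
            try:
                pieces = fine_map(sig + non, alpha=0.01)
            except ConflictError:
                pieces = []
            # 1-bp grid oracle
            points = np.arange(0, 5001)
            ok = np.ones(len(points), dtype=bool)
            for s in sig:
                ok &= (points >= s.het_interval.start) & (points <= s.het_interval.end)
            for n_ in non:
                ok &= ~((points > n_.het_interval.start) & (points < n_.het_interval.end))
            runs = []
            i = 0
            while i < len(points):
                if ok[i]:
                    j = i
                    while j + 1 < len(points) and ok[j + 1]:
                        j += 1
                    runs.append((points[i], points[j]))
                    i = j + 1
                else:
                    i += 1
            assert len(pieces) == len(runs)
            for piece, (lo, hi) in zip(sorted(pieces), runs):
                assert piece.start == lo and piece.end == hi

    def test_marker_outside_interval_rejected(self):
        with pytest.raises(InputError):
            pop("R1", 100, 900, 1e-5, pos=1200)
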