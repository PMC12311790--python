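import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replidyn.binning import BinDistribution
from replidyn.layout import GenomeLayout, Region
from replidyn.rqe import (
    Fragment,
    NullDistribution,
    circular_distance,
    compare_rqe_distributions,
    distance_matrix,
    empirical_null,
    fragment_sigma,
    max_rqe,
    normalized_rqe,
    sample_null_fragments,
    tail_probability,
)


def rqe_bruteforce(p):
    """Independent O(K^2) double-sum oracle for the normalized RQE."""
    k = len(p)
    num = 0.0
    for i in range(k):
        for j in range(k):
            num += circular_distance(i, j, k) * p[i] * p[j]
    u = [1.0 / k] * k
    denom = 0.0
    for i in range(k):
        for j in range(k):
            denom += circular_distance(i, j, k) * u[i] * u[j]
    return num / denom


def simplex_points(rng, n, k=5):
    return rng.dirichlet(np.ones(k), size=n)


class TestCircularDistance:
    @pytest.mark.parametrize(
        "i,j,k,expected",
        [(0, 0, 5, 0), (0, 3, 5, 2), (1, 4, 5, 2), (0, 1, 5, 1), (2, 4, 5, 2)],
    )
    def test_examples(self, i, j, k, expected):
        assert circular_distance(i, j, k) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            circular_distance(0, 5, 5)

    @pytest.mark.parametrize("k", range(2, 9))
    def test_metric_axioms(self, k):
        """Symmetry, identity, and the triangle inequality, exhaustively."""
        for i in range(k):
            assert circular_distance(i, i, k) == 0
            for j in range(k):
                assert circular_distance(i, j, k) == circular_distance(j, i, k)
                for m in range(k):
                    assert circular_distance(i, j, k) <= (
                        circular_distance(i, m, k) + circular_distance(m, j, k)
                    )


class TestNormalizedRqe:
    def test_uniform_is_exactly_one(self):
        assert normalized_rqe([0.2, 0.2, 0.2, 0.2, 0.2]) == 1.0

    @pytest.mark.parametrize("cls", range(5))
    def test_single_fraction_is_exactly_zero(self, cls):
        p = np.zeros(5)
        p[cls] = 1.0
        assert normalized_rqe(p) == 0.0

    def test_two_adjacent_halves(self):
        assert normalized_rqe([0.5, 0.5, 0, 0, 0]) == pytest.approx(5 / 12, abs=1e-12)

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            normalized_rqe([0.5, 0.5, 0.5, 0, 0])
        with pytest.raises(ValueError):
            normalized_rqe([1.2, -0.2, 0, 0, 0])

    def test_matches_bruteforce_double_sum(self, rng):
        for p in simplex_points(rng, 150):
            assert normalized_rqe(p) == pytest.approx(rqe_bruteforce(p), abs=1e-12)

    def test_range_and_symmetries(self, rng):
        """RQE in [0,1]; invariant to cyclic rotation and label reversal."""
        for p in simplex_points(rng, 150):
            v = normalized_rqe(p)
            assert 0.0 <= v <= 1.0
            for shift in range(1, 5):
                assert normalized_rqe(np.roll(p, shift)) == pytest.approx(v, abs=1e-12)
            assert normalized_rqe(p[::-1]) == pytest.approx(v, abs=1e-12)

    @given(st.lists(st.floats(0.01, 10.0), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_unit_interval_property(self, weights):
        p = np.array(weights) / sum(weights)
        assert 0.0 <= normalized_rqe(p) <= 1.0

    def test_uniform_is_unique_grid_maximizer(self):
        """No point of the step-0.05 simplex grid beats the uniform value."""
        from itertools import product

        best, argmax = -1.0, None
        count = 0
        for c in product(range(21), repeat=4):
            if sum(c) <= 20:
                comp = (*c, 20 - sum(c))
                p = np.array(comp) / 20.0
                v = normalized_rqe(p)
                count += 1
                assert v <= 1.0
                if v > best:
                    best, argmax = v, comp
        assert count == 10626
        assert best == 1.0
        assert argmax == (4, 4, 4, 4, 4)


def uniform_dist(n_bins, width=10_000, chrom="chr1"):
    p = np.full((n_bins, 5), 0.2)
    return BinDistribution({chrom: p}, {chrom: np.ones(n_bins, bool)}, width)


class TestFragmentSigma:
    def test_all_uniform_bins(self):
        dist = uniform_dist(160)
        res = fragment_sigma(Fragment("chr1", 0, 1_600_000), dist)
        assert res.sigma == 1.0
        assert res.n_defined == 160

    def test_all_delta_bins(self):
        p = np.tile(np.eye(5)[2], (160, 1))
        dist = BinDistribution({"chr1": p}, {"chr1": np.ones(160, bool)}, 10_000)
        assert fragment_sigma(Fragment("chr1", 0, 1_600_000), dist).sigma == 0.0

    def test_half_and_half_mean(self):
        """80 bins at contribution 1.0 plus 80 at 0.0 average to 0.5."""
        p = np.vstack([np.full((80, 5), 0.2), np.tile(np.eye(5)[0], (80, 1))])
        dist = BinDistribution({"chr1": p}, {"chr1": np.ones(160, bool)}, 10_000)
        assert fragment_sigma(Fragment("chr1", 0, 1_600_000), dist).sigma == pytest.approx(0.5)

    def test_undefined_bins_skipped_and_counted(self):
        dist = uniform_dist(160)
        dist.defined["chr1"][:40] = False
        dist.probs["chr1"][:40] = np.nan
        res = fragment_sigma(Fragment("chr1", 0, 1_600_000), dist)
        assert (res.n_defined, res.n_undefined) == (120, 40)

    def test_all_undefined_is_error(self):
        dist = uniform_dist(160)
        dist.defined["chr1"][:] = False
        with pytest.raises(ValueError, match="no defined bins"):
            fragment_sigma(Fragment("chr1", 0, 1_600_000), dist)

    def test_unaligned_fragment_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            fragment_sigma(Fragment("chr1", 5_000, 1_605_000), uniform_dist(200))


class TestNullSampler:
    def test_30mb_chromosome_two_fragments(self):
        """5 Mb exclusion + 10 Mb start spacing on 30 Mb: starts 5 Mb and 15 Mb
        only (a third start at 25 Mb would end past the 25 Mb bound)."""
        layout = GenomeLayout({"chr1": 30_000_000})
        frags = sample_null_fragments(layout)
        assert [(f.start, f.end) for f in frags] == [
            (5_000_000, 6_600_000),
            (15_000_000, 16_600_000),
        ]

    def test_short_chromosome_yields_nothing(self):
        layout = GenomeLayout({"chr1": 11_000_000, "chr2": 30_000_000})
        frags = sample_null_fragments(layout)
        assert all(f.chrom == "chr2" for f in frags)

    def test_no_room_anywhere_is_error(self):
        layout = GenomeLayout({"chr1": 11_000_000})
        with pytest.raises(ValueError, match="no chromosome"):
            sample_null_fragments(layout)

    def test_bounds_and_spacing_postconditions(self):
        layout = GenomeLayout({"chr1": 87_000_000, "chr2": 33_000_000})
        frags = sample_null_fragments(layout)
        by_chrom = {}
        for f in frags:
            assert f.start >= 5_000_000
            assert f.end <= layout.length(f.chrom) - 5_000_000
            assert f.length == 1_600_000
            by_chrom.setdefault(f.chrom, []).append(f.start)
        for starts in by_chrom.values():
            assert all(b - a >= 10_000_000 for a, b in zip(starts, starts[1:]))

    def test_gap_convention_spaces_start_to_start_by_more(self):
        layout = GenomeLayout({"chr1": 87_000_000})
        gap = sample_null_fragments(layout, convention="gap")
        starts = [f.start for f in gap]
        assert all(b - a == 11_600_000 for a, b in zip(starts, starts[1:]))

    def test_exclude_regions_drops_overlappers(self):
        layout = GenomeLayout({"chr1": 30_000_000})
        frags = sample_null_fragments(
            layout, exclude_regions=[Region("chr1", 6_000_000, 6_100_000)]
        )
        assert [(f.start, f.end) for f in frags] == [(15_000_000, 16_600_000)]

    def test_deterministic(self):
        layout = GenomeLayout({"chr1": 87_000_000})
        assert sample_null_fragments(layout) == sample_null_fragments(layout)


class TestEmpiricalNull:
    def _dist(self):
        dist = uniform_dist(3000, width=10_000)
        return dist

    def test_zero_read_bin_disqualifies_fragment(self):
        dist = self._dist()
        dist.defined["chr1"][50] = False  # inside [0, 1.6 Mb)
        frags = [
            Fragment("chr1", 0, 1_600_000),
            Fragment("chr1", 5_000_000, 6_600_000),
            Fragment("chr1", 10_000_000, 11_600_000),
        ]
        null = empirical_null(frags, dist)
        assert (null.n_sampled, null.n_retained) == (3, 2)

    def test_fully_covered_retains_all(self):
        frags = [Fragment("chr1", 0, 1_600_000), Fragment("chr1", 5_000_000, 6_600_000)]
        null = empirical_null(frags, self._dist())
        assert null.n_retained == null.n_sampled == 2

    def test_sigma_multiset_matches_per_fragment_recomputation(self, rng):
        p = rng.dirichlet(np.ones(5), size=3000)
        dist = BinDistribution({"chr1": p}, {"chr1": np.ones(3000, bool)}, 10_000)
        frags = [Fragment("chr1", s, s + 1_600_000) for s in range(0, 20_000_000, 5_000_000)]
        null = empirical_null(frags, dist)
        expected = [fragment_sigma(f, dist).sigma for f in frags]
        assert np.allclose(sorted(null.sigmas), sorted(expected), atol=1e-12)


class TestTailProbability:
    def _null(self, values):
        return NullDistribution(np.array(values), len(values), len(values))

    def test_above_everything(self):
        assert tail_probability(self._null([0.1, 0.2, 0.3]), 0.9) == 0.0

    def test_below_everything(self):
        assert tail_probability(self._null([0.1, 0.2, 0.3]), 0.05) == 1.0

    def test_counting_with_inclusive_ties(self):
        null = self._null([0.1, 0.2, 0.3, 0.4])
        assert tail_probability(null, 0.25) == 0.5
        assert tail_probability(null, 0.3) == 0.5  # >= is inclusive

    def test_non_increasing_in_observed(self, rng):
        null = self._null(sorted(rng.random(50)))
        obs = np.sort(rng.random(30))
        probs = [tail_probability(null, o) for o in obs]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


def ks_bruteforce(a, b):
    """Max absolute ECDF gap, evaluated by sweeping all pooled points."""
    a, b = np.sort(a), np.sort(b)
    gaps = [
        abs(np.searchsorted(a, x, "right") / len(a) - np.searchsorted(b, x, "right") / len(b))
        for x in np.concatenate([a, b])
    ]
    return max(gaps)


class TestCompareDistributions:
    def test_identical_samples(self):
        d, p = compare_rqe_distributions([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = compare_rqe_distributions([0, 0, 0], [1, 1, 1])
        assert d == 1.0

    def test_statistic_matches_ecdf_sweep(self, rng):
        for _ in range(100):
            a = rng.random(int(rng.integers(2, 15)))
            b = rng.random(int(rng.integers(2, 15)))
            d, _ = compare_rqe_distributions(a, b)
            assert d == pytest.approx(ks_bruteforce(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_rqe_distributions([], [0.1])


def test_max_rqe_closed_form():
    """The normalizer matches (k^2 - 1) / (4k) for odd k (1.2 for k = 5)."""
    for k in (3, 5, 7):
        assert max_rqe(k) == pytest.approx((k * k - 1) / (4 * k), rel=1e-12)
    assert distance_matrix(5).sum() == 30
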