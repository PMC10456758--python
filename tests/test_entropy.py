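"""Distance histograms, H_NDist and its normalized variant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ndentropy as nd
from ndentropy.entropy import entropy_of_sample
from ndentropy.neighbors import DistanceSample


def literal_entropy(counts) -> float:
    """Independent, unoptimized evaluation of -sum p log2 p."""
    import math

    total = sum(counts)
    h = 0.0
    for x in counts:
        if x > 0:
            p = x / total
            h -= p * math.log2(p)
    return h


def sample(values) -> DistanceSample:
    return DistanceSample(values=np.asarray(values, dtype=float))


class TestHistogram:
    def test_right_open_bins(self):
        hist = nd.make_histogram(sample([1.0, 1.0, 2.0, 2.0]), 1.0)
        assert hist.counts.tolist() == [0, 2, 2]
        assert np.allclose(hist.bin_edges, [0, 1, 2, 3])

    def test_wide_bin_single_occupied(self):
        hist = nd.make_histogram(sample([3.0, 5.0, 7.9]), 10.0)
        assert hist.occupied_bins == 1

    def test_single_value(self):
        hist = nd.make_histogram(sample([0.5]), 1.0)
        assert hist.counts.tolist() == [1]

    def test_counts_conserve_sample_size(self, gas_fixture):
        s = nd.neighbor_distances(gas_fixture, nd.build_voronoi_graph(gas_fixture))
        assert nd.make_histogram(s, 2.5).total == s.n

    def test_invalid_inputs(self):
        with pytest.raises(nd.ConfigurationError):
            nd.make_histogram(sample([1.0]), 0.0)
        with pytest.raises(nd.EmptyInputError):
            nd.make_histogram(sample([]), 1.0)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5], 0.0),            # all mass in one bin
            ([3, 3], 1.0),         # two equal bins
            ([1, 1, 2], 1.5),      # closed form
        ],
    )
    def test_closed_forms(self, counts, expected):
        hist = nd.DistanceHistogram(
            bin_edges=np.arange(len(counts) + 1, dtype=float), counts=counts
        )
        assert nd.shannon_entropy(hist) == pytest.approx(expected, abs=1e-12)

    def test_zero_iff_single_occupied_bin(self):
        hist = nd.DistanceHistogram(bin_edges=[0.0, 1.0, 2.0], counts=[0, 7])
        assert nd.shannon_entropy(hist) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=40))
    def test_matches_literal_formula(self, counts):
        if sum(counts) == 0:
            counts = counts + [1]
        hist = nd.DistanceHistogram(
            bin_edges=np.arange(len(counts) + 1, dtype=float), counts=counts
        )
        assert nd.shannon_entropy(hist) == pytest.approx(
            literal_entropy(counts), abs=1e-12
        )
        # bounds and the label-permutation invariance
        h = nd.shannon_entropy(hist)
        occupied = sum(c > 0 for c in counts)
        assert 0.0 <= h <= np.log2(occupied) + 1e-12
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(counts))
        hist_p = nd.DistanceHistogram(
            bin_edges=np.arange(len(counts) + 1, dtype=float),
            counts=np.asarray(counts)[perm],
        )
        assert nd.shannon_entropy(hist_p) == pytest.approx(h, abs=1e-12)
        # uniform duplication of all counts leaves probabilities unchanged
        hist_2x = nd.DistanceHistogram(
            bin_edges=np.arange(len(counts) + 1, dtype=float),
            counts=2 * np.asarray(counts),
        )
        assert nd.shannon_entropy(hist_2x) == pytest.approx(h, abs=1e-12)


class TestNormalizedEntropy:
    @pytest.mark.parametrize("m,w", [(4, 1.0), (16, 0.5), (7, 3.0)])
    def test_uniform_histogram_normalizes_to_one(self, m, w):
        hist = nd.DistanceHistogram(
            bin_edges=np.arange(m + 1, dtype=float) * w, counts=np.full(m, 5)
        )
        assert nd.normalized_entropy(hist) == pytest.approx(1.0, abs=1e-12)

    def test_two_occupied_of_eight_unit_bins(self):
        hist = nd.DistanceHistogram(
            bin_edges=np.arange(9, dtype=float), counts=[8, 0, 0, 0, 0, 0, 0, 8]
        )
        assert nd.normalized_entropy(hist) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_short_span_rejected(self):
        hist = nd.DistanceHistogram(bin_edges=[0.0, 0.5], counts=[3])
        with pytest.raises(nd.DomainError, match="length unit"):
            nd.normalized_entropy(hist)

    def test_stable_across_bin_sizes_on_structureless_sample(self, rng):
        # uniform distances have no structure at any scale: h_norm at w and 2w agree
        s = sample(rng.uniform(0, 200, 20000))
        h1 = entropy_of_sample(s, 1.0).h_norm
        h2 = entropy_of_sample(s, 2.0).h_norm
        assert h1 == pytest.approx(h2, rel=0.02)


class TestEntropyByNeighborDistance:
    def test_hexagonal_lattice_is_zero(self, hex_lattice):
        res = nd.entropy_by_neighbor_distance(hex_lattice, bin_size=1.0)
        assert res.h_ndist == 0.0
        assert res.occupied_bins == 1

    def test_two_points_single_distance(self):
        pts = nd.PointSet([[0.0, 0.0], [4.0, 0.0]])
        res = nd.entropy_by_neighbor_distance(
            pts, bin_size=1.0, neighbor_mode="metric", metric_radius=10.0
        )
        assert res.h_ndist == 0.0
        assert res.n_samples == 2

    def test_gas_exceeds_clusters(self, gas_fixture, clusters_fixture):
        hg = nd.entropy_by_neighbor_distance(gas_fixture, 1.0).h_ndist
        hc = nd.entropy_by_neighbor_distance(clusters_fixture, 1.0).h_ndist
        assert hg > hc

    def test_counting_convention_invariance(self, gas_fixture):
        # per-edge vs per-agent-directed: the factor of 2 cancels in p_i
        g = nd.build_voronoi_graph(gas_fixture)
        directed = nd.neighbor_distances(gas_fixture, g)
        per_edge = DistanceSample(values=g.edge_distances, counting_convention="per_edge")
        h2 = entropy_of_sample(directed, 1.0)
        h1 = entropy_of_sample(per_edge, 1.0)
        assert h1.h_ndist == pytest.approx(h2.h_ndist, abs=1e-12)
        assert h1.h_norm == pytest.approx(h2.h_norm, abs=1e-12)

    def test_metric_mode_requires_radius(self, gas_fixture):
        with pytest.raises(nd.ConfigurationError):
            nd.entropy_by_neighbor_distance(gas_fixture, 1.0, neighbor_mode="metric")


class TestBinSizeSweep:
    def test_nested_merging_is_monotone(self, gas_fixture):
        # merging histogram cells cannot increase Shannon entropy
        sw = nd.bin_size_sweep(gas_fixture, [1.0, 2.0, 4.0, 8.0])
        assert np.all(np.diff(sw["h_ndist"].to_numpy()) <= 1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nested_merging_monotone_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        s = sample(rng.uniform(0, 50, 500))
        h_fine = nd.shannon_entropy(nd.make_histogram(s, 1.0))
        h_coarse = nd.shannon_entropy(nd.make_histogram(s, 2.0))
        assert h_coarse <= h_fine + 1e-12

    def test_single_distance_zero_for_all_widths(self):
        pts = nd.PointSet([[0.0, 0.0], [7.0, 0.0]])
        sw = nd.bin_size_sweep(
            pts, [1.5, 2.0, 3.0], neighbor_mode="metric", metric_radius=10.0
        )
        assert np.all(sw["h_ndist"].to_numpy() == 0.0)
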