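import numpy as np
import pytest

import scktld
from scktld.metrics import (
    BoundaryFrequencyProfile,
    Partition,
    ami,
    boundary_frequency,
    consensus_boundaries,
    enrichment_profile,
    frequency_stratified_fold_change,
    moc,
    mutual_information,
    partition_from_domains,
    shared_boundary_count,
    tad_adj_r2,
)

from _oracles import tad_adj_r2_pairs


def domset(domains, n_bins, resolution=50_000):
    return scktld.DomainSet(chrom="c", resolution=resolution, n_bins=n_bins,
                            domains=domains)


class TestPartitionFromDomains:
    def test_tiling_domains_one_cluster_each(self):
        p = partition_from_domains(domset([(0, 2), (2, 4)], 4))
        assert p.labels.tolist() == [0, 0, 1, 1]
        assert np.allclose(p.fractions(), [0.5, 0.5])

    def test_single_domain_single_cluster(self):
        p = partition_from_domains(domset([(0, 6)], 6))
        assert p.n_clusters == 1

    def test_gap_run_becomes_its_own_cluster(self):
        p = partition_from_domains(domset([(0, 2), (3, 5)], 5))
        assert p.n_clusters == 3
        assert p.labels[2] not in (p.labels[0], p.labels[4])


class TestMutualInformation:
    def test_identity_equals_entropy(self):
        p = Partition(np.array([0, 0, 1, 1, 2, 2]))
        h = -np.sum([1 / 3 * np.log(1 / 3)] * 3)
        assert mutual_information(p, p) == pytest.approx(h)

    def test_constant_partition_zero_information(self):
        p = Partition(np.array([0, 0, 1, 1]))
        q = Partition(np.zeros(4, dtype=int))
        assert mutual_information(p, q) == pytest.approx(0.0)

    def test_product_form_overlap_zero_information(self):
        p = Partition(np.array([0, 0, 1, 1]))
        q = Partition(np.array([0, 1, 0, 1]))
        assert mutual_information(p, q) == pytest.approx(0.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(Partition(np.zeros(3)), Partition(np.zeros(4)))


class TestAMI:
    def test_identity_scores_one(self):
        p = Partition(np.array([0, 0, 1, 1, 2, 2]))
        assert ami(p, p) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        p = Partition(rng.integers(0, 4, size=50))
        q = Partition(rng.integers(0, 3, size=50))
        assert ami(p, q) == pytest.approx(ami(q, p))

    def test_single_cluster_against_structure_scores_zero(self):
        p = Partition(np.array([0, 0, 1, 1, 2, 2]))
        q = Partition(np.zeros(6, dtype=int))
        assert ami(p, q) == pytest.approx(0.0)

    def test_both_single_cluster_degenerate_identity(self):
        p = Partition(np.zeros(5, dtype=int))
        assert ami(p, p) == 1.0

    def test_random_labelings_average_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            p = Partition(rng.integers(0, 5, size=200))
            q = Partition(rng.integers(0, 5, size=200))
            vals.append(ami(p, q))
        assert abs(np.mean(vals)) <= 0.05

    def test_permutation_estimate_tracks_exact(self, rng):
        p = Partition(np.repeat([0, 1, 2], 20))
        labels = np.repeat([0, 1, 2], 20)
        rng.shuffle(labels[15:45])
        q = Partition(labels)
        exact = ami(p, q, method="exact")
        perm = ami(p, q, method="permutation", n_permutations=500, seed=1)
        assert perm == pytest.approx(exact, abs=0.05)


class TestMoC:
    def test_both_single_cluster_defined_as_one(self):
        p = Partition(np.zeros(4, dtype=int))
        assert moc(p, p) == 1.0

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_identity_scores_one_for_any_cluster_count(self, c):
        p = Partition(np.repeat(np.arange(c), 4))
        assert moc(p, p) == pytest.approx(1.0)

    def test_structure_against_single_cluster_scores_zero(self):
        p = Partition(np.array([0, 0, 1, 1]))
        q = Partition(np.zeros(4, dtype=int))
        assert moc(p, q) == pytest.approx(0.0)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            p = Partition(rng.integers(0, 4, size=40))
            q = Partition(rng.integers(0, 6, size=40))
            v = moc(p, q)
            assert v == pytest.approx(moc(q, p))
            assert -1e-12 <= v <= 1 + 1e-12

    def test_printed_normalizer_differs(self):
        p = Partition(np.repeat([0, 1, 2], 3))
        assert moc(p, p, printed_normalizer=True) < moc(p, p)


class TestTadAdjR2:
    def test_blockwise_constant_matrix_perfect_fit(self, contact_matrix_factory):
        # value depends only on (domain/gap class, distance) -> zero residual
        n = 20
        doms = [(0, 8), (12, 20)]
        dom_of = np.full(n, -1)
        for k, (s, e) in enumerate(doms):
            dom_of[s:e] = k
        dense = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                g = abs(i - j)
                same = dom_of[i] == dom_of[j] and dom_of[i] >= 0
                dense[i, j] = (10 + 3 * dom_of[i] if same else 1) + 0.5 * g
        m = contact_matrix_factory(dense)
        vals, mean = tad_adj_r2(m, domset(doms, n), max_distance=4)
        assert np.allclose(vals, 1.0)
        assert mean == pytest.approx(1.0)

    def test_uninformative_domains_give_nonpositive_r2(self, contact_matrix_factory, rng):
        # all class means equal the overall mean but residual is nonzero
        n = 16
        base = rng.uniform(1, 2, size=(n, n))
        dense = (base + base.T) / 2
        m = contact_matrix_factory(dense)
        # classes at distance 1 partition pairs; with means ~equal, the
        # adjusted ratio (b-1)/(b-p-1) > 1 drives R2 below 0
        vals, _ = tad_adj_r2(m, domset([(0, 8), (8, 16)], n), max_distance=1)
        oracle = tad_adj_r2_pairs(dense, [(0, 8), (8, 16)], 1)
        assert vals[0] == pytest.approx(oracle[0], abs=1e-12)
        assert vals[0] <= 1.0

    def test_matches_per_pair_oracle_on_planted_fixture(self, small_cell, small_design):
        doms = scktld.design_domains(small_design).domains
        ds = domset(doms, small_design.n_bins)
        vals, mean = tad_adj_r2(small_cell, ds, max_distance=8)
        oracle = tad_adj_r2_pairs(small_cell.dense(), doms, 8)
        assert np.allclose(vals, oracle, equal_nan=True)
        assert np.all(vals[np.isfinite(vals)] <= 1.0)

    def test_underdetermined_distance_reported_missing(self, contact_matrix_factory):
        n = 5
        m = contact_matrix_factory(np.ones((n, n)))
        # 4 domains of size >= 2 would leave b - p - 1 <= 0 at distance 1
        with pytest.warns(UserWarning, match="skipped"):
            vals, _ = tad_adj_r2(m, domset([(0, 2), (2, 4)], n), max_distance=4)
        assert np.isnan(vals).any()


class TestBoundaryStatistics:
    def test_boundary_frequency_counts_identical_sets(self):
        ds = domset([(0, 4), (4, 7), (7, 10)], 10)
        prof = boundary_frequency([ds, ds, ds])
        assert prof.counts[4] == 3 and prof.counts[7] == 3
        assert prof.counts.sum() == 6

    def test_single_domain_sets_give_zero_profile(self):
        prof = boundary_frequency([domset([(0, 10)], 10)] * 4)
        assert prof.counts.sum() == 0

    def test_disjoint_boundaries_max_count_one(self):
        a = domset([(0, 3), (3, 10)], 10)
        b = domset([(0, 6), (6, 10)], 10)
        prof = boundary_frequency([a, b])
        assert prof.counts.max() == 1

    def test_consensus_single_peak(self):
        prof = BoundaryFrequencyProfile(counts=np.array([0, 0, 5, 0, 0]), n_cells=10)
        assert consensus_boundaries(prof, window=1, min_fraction=0.2) == [2]

    def test_consensus_flat_profile_empty(self):
        prof = BoundaryFrequencyProfile(counts=np.full(6, 3), n_cells=10)
        assert consensus_boundaries(prof, window=1, min_fraction=0.1) == []

    def test_consensus_nearby_peaks_both_kept(self):
        prof = BoundaryFrequencyProfile(counts=np.array([0, 4, 0, 0, 5, 0]), n_cells=10)
        assert consensus_boundaries(prof, window=1, min_fraction=0.2) == [1, 4]

    def test_shared_boundaries_identical_sets(self):
        ds = domset([(0, 4), (4, 7), (7, 10)], 10)
        assert shared_boundary_count(ds, ds, tolerance=0) == 2

    def test_shared_boundaries_disjoint(self):
        a = domset([(0, 3), (3, 10)], 10)
        b = domset([(0, 6), (6, 10)], 10)
        assert shared_boundary_count(a, b, tolerance=0) == 0

    def test_shared_boundaries_with_tolerance(self):
        a = domset([(0, 10), (10, 20)], 20)
        b = domset([(0, 11), (11, 20)], 20)
        assert shared_boundary_count(a, b, tolerance=1) == 1

    def test_each_target_boundary_matched_once(self):
        a = domset([(0, 5), (5, 6), (6, 20)], 20)   # boundaries 5, 6
        b = domset([(0, 5), (5, 20)], 20)           # boundary 5
        assert shared_boundary_count(a, b, tolerance=1) == 1


class TestEnrichment:
    def track(self, values, resolution=50_000):
        return scktld.SignalTrack(chrom="c", resolution=resolution,
                                  values=np.asarray(values, dtype=float))

    def test_constant_track_profile_zero(self):
        t = self.track(np.full(40, 2.5))
        offsets, prof = enrichment_profile(t, [20], flank=500_000)
        assert np.allclose(prof, 0.0)

    def test_delta_track_hand_arithmetic(self):
        vals = np.zeros(41)
        vals[20] = 1.0
        t = self.track(vals)
        offsets, prof = enrichment_profile(t, [20], flank=500_000)
        # background offsets (2..10 bins away) see only zeros
        assert prof[offsets == 0][0] == pytest.approx(1.0)
        off_bg = (np.abs(offsets) >= 2) & (np.abs(offsets) <= 10)
        assert np.allclose(prof[off_bg], 0.0)

    def test_two_boundaries_profile_is_mean_of_singles(self):
        rng = np.random.default_rng(4)
        t = self.track(rng.uniform(0, 1, size=60))
        _, both = enrichment_profile(t, [25, 30], flank=250_000)
        # away from chromosome edges the per-offset means are linear in
        # the boundary set, so the joint profile equals the background-
        # shifted average of the two single-boundary raw profiles
        w = 250_000 // 50_000
        offs = np.arange(-w, w + 1)
        raw = (t.values[25 + offs] + t.values[30 + offs]) / 2
        bp = np.abs(offs) * 50_000
        bg = (bp >= 100_000) & (bp <= 250_000)
        assert np.allclose(both, raw - raw[bg].mean())

    def test_empty_boundaries_rejected(self):
        with pytest.raises(ValueError):
            enrichment_profile(self.track(np.ones(10)), [], flank=100_000)


class TestFrequencyStratifiedFoldChange:
    def test_constant_track_unity_everywhere(self):
        t = scktld.SignalTrack(chrom="c", resolution=1, values=np.full(20, 3.0))
        prof = BoundaryFrequencyProfile(
            counts=np.array([0] * 10 + [1] * 5 + [2] * 5), n_cells=4
        )
        fc = frequency_stratified_fold_change(t, prof)
        assert fc == {1: pytest.approx(1.0), 2: pytest.approx(1.0)}

    def test_boundary_signal_doubling(self):
        counts = np.array([0] * 10 + [1] * 4 + [3] * 4)
        vals = np.where(counts > 0, 2.0, 1.0)
        t = scktld.SignalTrack(chrom="c", resolution=1, values=vals)
        prof = BoundaryFrequencyProfile(counts=counts, n_cells=5)
        fc = frequency_stratified_fold_change(t, prof)
        assert fc == {1: pytest.approx(2.0), 3: pytest.approx(2.0)}

    def test_monotone_signal_gives_monotone_fold_change(self):
        counts = np.array([0] * 8 + [1] * 4 + [2] * 4 + [3] * 4)
        vals = 1.0 + counts.astype(float)
        t = scktld.SignalTrack(chrom="c", resolution=1, values=vals)
        prof = BoundaryFrequencyProfile(counts=counts, n_cells=5)
        fc = frequency_stratified_fold_change(t, prof)
        fs = sorted(fc)
        assert all(fc[a] < fc[b] for a, b in zip(fs, fs[1:]))

    def test_no_zero_frequency_bins_rejected(self):
        t = scktld.SignalTrack(chrom="c", resolution=1, values=np.ones(4))
        prof = BoundaryFrequencyProfile(counts=np.array([1, 1, 2, 1]), n_cells=3)
        with pytest.raises(ValueError, match="zero-frequency"):
            frequency_stratified_fold_change(t, prof)
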