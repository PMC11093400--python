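"""GSS parcellation stages against brute-force oracles, plus end-to-end
determinism, monotonicity and planted-network recovery."""

import numpy as np
import pytest

from gsspipe import (GSSParcellation, NetworkSpec, VolumeGrid, make_phantom,
                     sample_subject_topography)
from gsspipe.gss import (calibrate_cluster_extent, filter_small_parcels,
                         overlap_map, parcel_validation, smooth_probability_map,
                         threshold_overlap, threshold_top_fraction,
                         watershed_parcellate)

from _oracles import (gaussian3d, max_cluster_size_6conn, overlap_bruteforce,
                      steepest_ascent_basins, top_k_bruteforce)

SHAPE = (18, 18, 18)


class TestTopFraction:
    def test_exact_count(self, rng):
        m = rng.normal(size=(10, 10, 10))
        sel = threshold_top_fraction(m, None, 0.05)
        assert sel.sum() == 50  # 5% of 1000

    def test_all_equal_breaks_ties_by_index(self):
        m = np.ones((10, 10, 10))
        sel = threshold_top_fraction(m, None, 0.05)
        assert sel.sum() == 50
        assert set(np.flatnonzero(sel.ravel())) == set(range(50))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=SHAPE)
        mask = rng.uniform(size=SHAPE) < 0.7
        frac = 0.05
        k = int(round(frac * mask.sum()))
        sel = threshold_top_fraction(m, mask, frac)
        assert set(np.flatnonzero(sel.ravel())) == top_k_bruteforce(m, mask, k)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_top_fraction(np.zeros(SHAPE), np.zeros(SHAPE, bool), 0.05)


class TestOverlap:
    def test_simple_counts(self):
        a = np.zeros((4, 4, 4), bool); a[0, 0, 0] = True
        assert overlap_map([a, a, a])[0, 0, 0] == 3

    def test_disjoint_masks_max_one(self, rng):
        masks = []
        for i in range(4):
            m = np.zeros((4, 4, 4), bool)
            m.ravel()[i] = True
            masks.append(m)
        assert overlap_map(masks).max() == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_sum(self, seed):
        rng = np.random.default_rng(seed)
        masks = [rng.uniform(size=(8, 8, 8)) < 0.2 for _ in range(12)]
        assert np.array_equal(overlap_map(masks), overlap_bruteforce(masks))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_map([np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool)])


class TestThresholdOverlap:
    def test_more_than_five_rule(self):
        counts = np.array([[[5, 6]]])
        p = threshold_overlap(counts, 41, min_subjects=6)
        assert p[0, 0, 0] == 0.0          # 5 subjects: excluded
        assert p[0, 0, 1] == pytest.approx(6 / 41)

    def test_min_one_retains_all_nonzero(self, rng):
        counts = rng.integers(0, 10, size=(6, 6, 6))
        p = threshold_overlap(counts, 10, min_subjects=1)
        assert np.array_equal(p > 0, counts > 0)


class TestSmoothing:
    def test_zero_kernel_is_identity(self, rng):
        m = rng.uniform(size=SHAPE)
        assert np.array_equal(smooth_probability_map(m, 0.0), m)

    def test_delta_matches_analytic_gaussian(self):
        m = np.zeros((21, 21, 21))
        m[10, 10, 10] = 1.0
        fwhm, vox = 6.0, (2.0, 2.0, 2.0)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox[0]
        sm = smooth_probability_map(m, fwhm, vox)
        # discrete Gaussian kernel: analytic density sampled then normalised,
        # matching the separable filter's construction
        x = np.arange(21) - 10.0
        k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
        k1 /= np.exp(-(np.arange(-13, 14)) ** 2 / (2 * sigma ** 2)).sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        assert np.abs(sm - expected).max() < 1e-6

    def test_mass_conserved(self, rng):
        m = np.zeros(SHAPE)
        m[6:12, 6:12, 6:12] = rng.uniform(size=(6, 6, 6))
        sm = smooth_probability_map(m, 4.0)
        assert sm.sum() == pytest.approx(m.sum(), abs=1e-6)


class TestWatershed:
    def test_two_bumps_give_two_basins_matching_ascent_oracle(self):
        field = gaussian3d(SHAPE, (5, 9, 9), (1.5, 1.5, 1.5)) \
            + gaussian3d(SHAPE, (13, 9, 9), (1.5, 1.5, 1.5))
        atlas = watershed_parcellate(field)
        assert atlas.n_parcels == 2
        l1 = atlas.labels[5, 9, 9]
        l2 = atlas.labels[13, 9, 9]
        assert {l1, l2} == {1, 2}
        oracle = steepest_ascent_basins(field, field > 0)
        # identical partition up to label naming, away from exact ridges
        agree = 0
        for a, b in ((l1, oracle[5, 9, 9]), (l2, oracle[13, 9, 9])):
            agree += ((atlas.labels == a) == (oracle == b)).mean()
        assert agree / 2 > 0.98

    def test_single_bump_single_parcel(self):
        field = gaussian3d(SHAPE, (9, 9, 9), (2, 2, 2))
        assert watershed_parcellate(field).n_parcels == 1

    def test_all_zero_map_empty_atlas(self):
        atlas = watershed_parcellate(np.zeros(SHAPE))
        assert atlas.n_parcels == 0
        assert not atlas.union_mask().any()

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError):
            watershed_parcellate(-np.ones(SHAPE))


class TestSizeFilter:
    def _atlas_two_parcels(self):
        labels = np.zeros(SHAPE, dtype=np.int32)
        labels[2:6, 2:6, 2:6] = 1      # 64 voxels
        labels[10:14, 10:14, 10:14] = 2
        from gsspipe.gss import ParcelAtlas, _basic_table
        return ParcelAtlas(labels, _basic_table(labels))

    def test_boundary_mean_size_ten_is_retained(self):
        atlas = self._atlas_two_parcels()
        # every subject overlaps parcel 1 in exactly 10 voxels
        subs = []
        for _ in range(3):
            m = np.zeros(SHAPE, bool)
            m.ravel()[np.flatnonzero(atlas.labels.ravel() == 1)[:10]] = True
            subs.append(m)
        out = filter_small_parcels(atlas, subs, min_mean_size=10)
        assert out.n_parcels == 1  # parcel 1 stays (10 is not < 10), parcel 2 empty

    def test_all_empty_subjects_removed(self):
        atlas = self._atlas_two_parcels()
        subs = [np.zeros(SHAPE, bool) for _ in range(3)]
        assert filter_small_parcels(atlas, subs, 10).n_parcels == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_survivors_match_per_parcel_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        atlas = self._atlas_two_parcels()
        subs = [rng.uniform(size=SHAPE) < 0.15 for _ in range(6)]
        out = filter_small_parcels(atlas, subs, min_mean_size=9.0)
        expected = []
        for pid in (1, 2):
            pm = atlas.labels == pid
            mean = np.mean([(s & pm).sum() for s in subs])
            if mean >= 9.0:
                expected.append(pid)
        assert out.n_parcels == len(expected)
        # labels re-compacted, survivors keep their voxels
        for new_id, old_id in enumerate(expected, start=1):
            assert np.array_equal(out.labels == new_id, atlas.labels == old_id)


class TestValidation:
    def _atlas(self):
        labels = np.zeros(SHAPE, dtype=np.int32)
        labels[4:12, 4:12, 4:12] = 1
        from gsspipe.gss import ParcelAtlas, _basic_table
        return ParcelAtlas(labels, _basic_table(labels))

    def test_rate_one_and_zero(self):
        atlas = self._atlas()
        hot = np.zeros(SHAPE); hot[5:9, 5:9, 5:9] = 5.0
        cold = np.zeros(SHAPE)
        assert parcel_validation(atlas, [hot] * 4, 2.0, 3)[0] == 1.0
        assert parcel_validation(atlas, [cold] * 4, 2.0, 3)[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_cluster_search(self, seed):
        rng = np.random.default_rng(seed)
        atlas = self._atlas()
        pm = atlas.labels == 1
        zmaps = [rng.normal(size=SHAPE) for _ in range(8)]
        for mc in (1, 2, 3):
            rate = parcel_validation(atlas, zmaps, 1.5, mc)[0]
            expected = np.mean([max_cluster_size_6conn((z > 1.5) & pm) >= mc
                                for z in zmaps])
            assert rate == pytest.approx(expected)

    def test_calibrated_extent_controls_fwe(self):
        # pure-noise false-validation rate at the calibrated extent is ~5%
        k = calibrate_cluster_extent(100, validation_z=2.0, fwe_rate=0.05,
                                     n_sims=1000, seed=1)
        assert 2 <= k <= 5


def _subject_zmaps(seed, n_subjects=12, shape=(24, 24, 24)):
    """Synthetic subject z-maps: unit noise + strong activation inside a
    jittered copy of each truth network."""
    grid = VolumeGrid(shape)
    specs = [NetworkSpec("netA", (7, 12, 12), 3.2),
             NetworkSpec("netB", (17, 12, 12), 3.2)]
    truths = make_phantom(grid, specs, [f"s{i}" for i in range(n_subjects)],
                          seed=seed, disjoint=True)
    rng = np.random.default_rng(seed)
    zmaps = {"netA": [], "netB": []}
    for i in range(n_subjects):
        for t in truths:
            topo = sample_subject_topography(t, f"s{i}", seed=seed * 1000 + i * 7
                                             + (t.name == "netB"), max_shift_vox=2,
                                             grow_prob=0.3, min_overlap=0.5)
            z = rng.normal(size=shape)
            z[topo.mask] += 6.0
            zmaps[t.name].append(z)
    return truths, zmaps


class TestGSSEndToEnd:
    def test_bitwise_determinism(self):
        _, zmaps = _subject_zmaps(seed=2)
        a = GSSParcellation().fit(zmaps["netA"])
        b = GSSParcellation().fit(zmaps["netA"])
        assert np.array_equal(a.labels_, b.labels_)
        assert a.atlas_.table.equals(b.atlas_.table)

    def test_min_subjects_monotonicity(self):
        _, zmaps = _subject_zmaps(seed=3)
        retained = []
        for ms in (4, 6, 8):
            est = GSSParcellation(min_subjects=ms).fit(zmaps["netA"])
            retained.append(int((est.probability_map_ > 0).sum()))
        assert retained[0] >= retained[1] >= retained[2]

    def test_min_size_monotonicity(self):
        _, zmaps = _subject_zmaps(seed=3)
        counts = []
        for msz in (0.0, 10.0, 40.0):
            est = GSSParcellation(min_mean_parcel_size_vox=msz).fit(zmaps["netA"])
            counts.append(est.atlas_.n_parcels)
        assert counts[0] >= counts[1] >= counts[2]

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_recovers_planted_networks(self, seed):
        truths, zmaps = _subject_zmaps(seed=seed)
        masks = {t.name: t.mask for t in truths}
        atlases = {}
        for net in ("netA", "netB"):
            est = GSSParcellation().fit(zmaps[net])
            atlases[net] = est.atlas_
            union = est.atlas_.union_mask()
            dice = 2 * (union & masks[net]).sum() / (union.sum() + masks[net].sum())
            assert dice >= 0.6, f"{net} seed {seed}: Dice {dice:.2f}"
        for net, atlas in atlases.items():
            for pid in atlas.parcel_ids():
                pm = atlas.parcel_mask(pid)
                assert not ((pm & masks["netA"]).any() and (pm & masks["netB"]).any()), \
                    "a parcel spans both truth networks"
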