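"""MR8 bank construction, responses, texton dictionary, histograms."""

import numpy as np
import pytest
from scipy import ndimage

from otodx.filterbank import (
    FilterBankError,
    TextonDictionary,
    assign_textons,
    assign_vectors,
    build_mr8_bank,
    build_texton_dictionary,
    filterbank_features,
    mr8_responses,
    texton_histogram,
)
from otodx.preprocessing import luminance
from otodx.synthetic import PhantomSpec, generate_phantom, phantom_seed

SMALL = (96, 96)


class TestBankConstruction:
    def test_default_bank_has_38_kernels_and_8_slots(self, bank):
        assert len(bank.kernels) == 38
        assert bank.n_slots == 8
        # 6 anisotropic slots of 6 orientations + 2 isotropic singletons
        assert [len(g) for g in bank.grouping] == [6] * 6 + [1, 1]

    def test_kernels_are_l1_normalized_and_zero_mean(self, bank):
        for i, k in enumerate(bank.kernels):
            assert np.abs(k).sum() == pytest.approx(1.0, abs=1e-12)
            if i != 36:  # all but the isotropic Gaussian are zero-mean
                assert abs(k.sum()) < 1e-10

    def test_rotating_a_bar_kernel_one_step_gives_the_next_orientation(self, bank):
        # bar group at the middle scale: kernels 24..29, step = 30 degrees
        group = bank.grouping[4]
        k0, k1 = bank.kernels[group[0]], bank.kernels[group[1]]
        rotated = ndimage.rotate(k0, -30.0, reshape=False, order=3)
        corr = np.corrcoef(rotated.ravel(), k1.ravel())[0, 1]
        assert corr > 0.95

    def test_invalid_scales_rejected(self):
        with pytest.raises(FilterBankError):
            build_mr8_bank(scales=((0.0, 3.0),))
        with pytest.raises(FilterBankError):
            build_mr8_bank(orientations=1)


class TestResponses:
    def test_constant_image_gives_near_zero_planes(self, bank):
        resp = mr8_responses(np.full((64, 64), 99.0), bank)
        assert np.abs(resp.planes).max() < 1e-9

    def test_plane_count_and_shape(self, bank, small_phantoms):
        img = small_phantoms["normal"][0].pixels
        resp = mr8_responses(img, bank)
        assert resp.planes.shape == (8, img.shape[0], img.shape[1])

    def test_image_smaller_than_support_rejected(self, bank):
        with pytest.raises(FilterBankError):
            mr8_responses(np.zeros((40, 40)), bank)

    def test_oriented_lines_give_matching_bar_response_magnitudes(self, bank):
        # a bright line at 30 deg and at 60 deg must excite some bar slot equally
        def line_image(theta_deg):
            yy, xx = np.mgrid[0:96, 0:96]
            t = np.deg2rad(theta_deg)
            d = np.abs((xx - 48) * np.sin(t) - (yy - 48) * np.cos(t))
            return np.where(d < 1.2, 255.0, 0.0)

        maxima = []
        for theta in (30.0, 60.0):
            resp = mr8_responses(line_image(theta), bank, contrast_normalize=False)
            maxima.append(max(abs(resp.planes[s]).max() for s in range(3, 6)))
        assert maxima[0] == pytest.approx(maxima[1], rel=0.05)

    def test_rot90_preserves_response_value_distribution(self, bank, small_phantoms):
        img = luminance(small_phantoms["earwax"][0].pixels)
        r_orig = mr8_responses(img, bank).planes
        r_rot = mr8_responses(np.rot90(img), bank).planes
        trim = 25  # ignore border where padding differs between orientations
        for p_orig, p_rot in zip(r_orig, r_rot):
            a = np.sort(p_orig[trim:-trim, trim:-trim].ravel())
            b = np.sort(np.rot90(p_rot, -1)[trim:-trim, trim:-trim].ravel())
            assert np.allclose(a, b, rtol=1e-6, atol=1e-8)


class TestDictionary:
    def test_four_classes_k10_yield_40_ordered_centroids(self, bank, small_phantoms):
        images_by_class = {c: [im.pixels for im in ims[:2]] for c, ims in small_phantoms.items()}
        d = build_texton_dictionary(images_by_class, k=10, seed=0, bank=bank, max_samples_per_class=2000)
        assert d.n_textons == 40
        assert d.centroids.shape == (40, 8)
        assert d.class_of == [c for c in images_by_class for _ in range(10)]

    def test_dictionary_build_is_deterministic(self, bank, small_phantoms):
        images_by_class = {c: [ims[0].pixels] for c, ims in small_phantoms.items()}
        d1 = build_texton_dictionary(images_by_class, k=4, seed=3, bank=bank, max_samples_per_class=1000)
        d2 = build_texton_dictionary(images_by_class, k=4, seed=3, bank=bank, max_samples_per_class=1000)
        assert np.array_equal(d1.centroids, d2.centroids)

    def test_k1_on_identical_images_returns_the_mean_response(self, bank, small_phantoms):
        img = small_phantoms["normal"][0].pixels
        d = build_texton_dictionary({"normal": [img, img]}, k=1, seed=0, bank=bank, max_samples_per_class=10**9)
        expected = mr8_responses(img, bank).vectors.mean(axis=0)
        assert np.allclose(d.centroids[0], expected, rtol=1e-8)

    def test_fewer_vectors_than_k_rejected(self, bank):
        with pytest.raises(FilterBankError):
            build_texton_dictionary({"normal": []}, k=10, seed=0, bank=bank)

    def test_save_load_roundtrip_preserves_bin_order(self, tmp_path):
        d = TextonDictionary(centroids=np.arange(24.0).reshape(6, 4), class_of=["a"] * 3 + ["b"] * 3, k_per_class=3)
        d.save(tmp_path / "dict.txt")
        back = TextonDictionary.load(tmp_path / "dict.txt")
        assert np.array_equal(back.centroids, d.centroids)
        assert back.class_of == d.class_of and back.k_per_class == 3


class TestAssignment:
    def test_exact_centroid_match_and_tie_breaks_to_lowest_index(self):
        centroids = np.zeros((8, 8))
        centroids[3] = 0.0
        centroids[7] = 2.0
        d = TextonDictionary(centroids=centroids, class_of=["x"] * 8, k_per_class=8)
        vectors = np.vstack([centroids[7], np.full(8, 1.0)])  # exact match; equidistant 3 vs 7
        labels = assign_vectors(vectors, d)
        assert labels[0] == 7
        assert labels[1] == 0  # rows 0,1,2,3.. all zero -> ties collapse to lowest index

    def test_labels_agree_with_exhaustive_loop(self, rng):
        centroids = rng.normal(size=(12, 8))
        d = TextonDictionary(centroids=centroids, class_of=["x"] * 12, k_per_class=12)
        vectors = rng.normal(size=(16 * 16, 8))
        labels = assign_vectors(vectors, d)
        for v, lab in zip(vectors, labels):
            dists = [((v - c) ** 2).sum() for c in centroids]
            assert lab == int(np.argmin(dists))

    def test_dimension_mismatch_rejected(self):
        d = TextonDictionary(centroids=np.zeros((4, 8)), class_of=["x"] * 4, k_per_class=4)
        with pytest.raises(FilterBankError):
            assign_vectors(np.zeros((5, 7)), d)


class TestHistogram:
    def test_single_label_is_one_hot(self):
        h = texton_histogram(np.zeros((10, 10), dtype=int), n_bins=40)
        expected = np.zeros(40)
        expected[0] = 1.0
        assert np.array_equal(h.counts, expected)

    def test_normalized_histogram_sums_to_one(self, rng):
        labels = rng.integers(0, 40, size=(32, 32))
        h = texton_histogram(labels, n_bins=40)
        assert h.counts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_counts_match_brute_force_tally(self, rng):
        labels = rng.integers(0, 13, size=(32, 32))
        h = texton_histogram(labels, n_bins=13, normalize=False)
        for b in range(13):
            assert h.counts[b] == (labels == b).sum()

    def test_out_of_range_label_rejected(self):
        with pytest.raises(FilterBankError):
            texton_histogram(np.array([[0, 5]]), n_bins=4)


def test_same_class_pairs_are_closer_in_chi2_than_cross_class(bank, small_phantoms):
    """Histogram features cluster by phantom class."""
    images_by_class = {c: [im.pixels for im in ims[:2]] for c, ims in small_phantoms.items()}
    d = build_texton_dictionary(images_by_class, k=5, seed=1, bank=bank, max_samples_per_class=2000)

    def chi2(p, q):
        denom = p + q
        mask = denom > 0
        return 0.5 * ((p[mask] - q[mask]) ** 2 / denom[mask]).sum()

    feats = {
        c: [
            filterbank_features(
                generate_phantom(PhantomSpec(c, roi_size=SMALL, seed=phantom_seed(77, c, i))).pixels,
                d,
                bank=bank,
            )
            for i in range(3)
        ]
        for c in images_by_class
    }
    same = [chi2(f[i], f[j]) for f in feats.values() for i in range(3) for j in range(i + 1, 3)]
    classes = list(feats)
    cross = [
        chi2(feats[a][i], feats[b][i])
        for ai, a in enumerate(classes)
        for b in classes[ai + 1 :]
        for i in range(3)
    ]
    assert np.mean(same) < np.mean(cross)
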