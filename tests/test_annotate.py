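"""Graph-cut skin annotation, label propagation and consensus rules."""

import itertools

import numpy as np
import pytest

from neovitals.annotate import (
    ColorModel,
    ConsensusRule,
    GscParams,
    SeedSet,
    agreement_score,
    combine_annotations,
    fit_color_models,
    gsc_segment,
    propose_seeds,
    star_convexity_violations,
)


@pytest.fixture()
def disk_seeds():
    return SeedSet(skin=[[20, 20], [18, 22], [23, 19]],
                   non_skin=[[2, 2], [2, 37], [37, 2], [37, 37]])


class TestSeedSet:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            SeedSet(skin=[[1, 1]], non_skin=[[1, 1]])

    def test_star_centers_default_to_skin_seeds(self):
        s = SeedSet(skin=[[1, 1], [2, 2]], non_skin=[[5, 5]])
        assert np.array_equal(s.star_centers, s.skin)

    def test_star_centers_must_be_skin_seeds(self):
        with pytest.raises(ValueError):
            SeedSet(skin=[[1, 1]], non_skin=[[5, 5]], star_centers=[[3, 3]])


class TestGscSegment:
    def test_recovers_two_tone_disk(self, two_tone_image, disk_seeds):
        img, disk = two_tone_image
        label = gsc_segment(img, disk_seeds)
        assert (label != disk).mean() <= 0.01

    def test_seeds_keep_their_class(self, two_tone_image, disk_seeds):
        img, _ = two_tone_image
        label = gsc_segment(img, disk_seeds)
        for r, c in disk_seeds.skin:
            assert label[r, c]
        for r, c in disk_seeds.non_skin:
            assert not label[r, c]

    def test_full_seeding_is_exact(self, two_tone_image):
        img, disk = two_tone_image
        seeds = SeedSet(skin=np.argwhere(disk), non_skin=np.argwhere(~disk))
        assert np.array_equal(gsc_segment(img, seeds), disk)

    def test_output_is_star_convex(self, two_tone_image, disk_seeds):
        img, _ = two_tone_image
        label = gsc_segment(img, disk_seeds)
        assert star_convexity_violations(label, img, disk_seeds) == 0

    def test_unary_only_equals_per_pixel_likelihood(self, two_tone_image, disk_seeds):
        # with no boundary term and no shape prior the cut degenerates to
        # independent per-pixel maximum likelihood
        img, _ = two_tone_image
        small = img[12:28, 12:28]
        seeds = SeedSet(skin=[[8, 8], [7, 9]], non_skin=[[0, 0], [15, 15]])
        params = GscParams(lambda_pairwise=0.0, star_convexity=False, k_components=1)
        label = gsc_segment(small, seeds, params)
        from neovitals.annotate import _fit_gmm
        pix = small.reshape(-1, 3).astype(float)
        sk = _fit_gmm(pix[[8 * 16 + 8, 7 * 16 + 9]], 1, seed=0)
        ns = _fit_gmm(pix[[0, 15 * 16 + 15]], 1, seed=1)
        oracle = (sk.score_samples(pix) > ns.score_samples(pix)).reshape(16, 16)
        interior = np.ones((16, 16), bool)
        interior[[8, 7], [8, 9]] = interior[[0, 15], [0, 15]] = False
        assert (label == oracle)[interior].mean() >= 0.99

    def test_empty_seed_class_rejected(self, two_tone_image):
        img, _ = two_tone_image
        with pytest.raises(ValueError):
            gsc_segment(img, SeedSet(skin=np.empty((0, 2), int), non_skin=[[0, 0]]))


class TestColorModels:
    def test_flat_color_component_means(self, two_tone_image):
        img, disk = two_tone_image
        model = fit_color_models(img, disk, k_components=1)
        assert np.allclose(model.skin.means_[0], (200, 150, 130), atol=3)
        assert np.allclose(model.non_skin.means_[0], (40, 50, 60), atol=3)

    def test_skin_color_high_probability(self, two_tone_image):
        img, disk = two_tone_image
        model = fit_color_models(img, disk, k_components=1)
        p = model.skin_probability(np.array([[[200, 150, 130]]], float))
        assert p[0, 0] > 0.99

    def test_too_many_components_rejected(self):
        img = np.zeros((3, 3, 3), np.uint8)
        label = np.zeros((3, 3), bool)
        label[0, 0] = True
        with pytest.raises(ValueError):
            fit_color_models(img, label, k_components=5)

    def test_single_class_label_rejected(self, two_tone_image):
        img, _ = two_tone_image
        with pytest.raises(ValueError):
            fit_color_models(img, np.ones(img.shape[:2], bool))


class TestProposeSeeds:
    @pytest.fixture()
    def model(self, two_tone_image):
        img, disk = two_tone_image
        return fit_color_models(img, disk, k_components=2)

    def test_propagation_on_identical_frame(self, two_tone_image, model):
        img, disk = two_tone_image
        first = gsc_segment(img, SeedSet(skin=[[20, 20], [18, 22]],
                                         non_skin=[[2, 2], [37, 37]]))
        seeds = propose_seeds(img, model, n_seeds=10, rng_seed=4)
        second = gsc_segment(img, seeds)
        assert (first != second).mean() <= 0.02

    def test_single_seed_per_class(self, two_tone_image, model):
        img, disk = two_tone_image
        s = propose_seeds(img, model, n_seeds=1, rng_seed=0)
        assert len(s.skin) == 1 and len(s.non_skin) == 1
        assert disk[tuple(s.skin[0])]
        assert not disk[tuple(s.non_skin[0])]

    def test_reproducible_by_seed(self, two_tone_image, model):
        img, _ = two_tone_image
        a = propose_seeds(img, model, n_seeds=6, rng_seed=9)
        b = propose_seeds(img, model, n_seeds=6, rng_seed=9)
        assert np.array_equal(a.skin, b.skin)
        assert np.array_equal(a.non_skin, b.non_skin)

    def test_best_candidate_spreads_more_than_uniform(self, two_tone_image, model):
        img, disk = two_tone_image
        rng = np.random.default_rng(0)
        coords = np.argwhere(disk)

        def min_pairwise(pts):
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            return d[np.triu_indices(len(pts), 1)].min()

        bc, uni = [], []
        for trial in range(100):
            s = propose_seeds(img, model, n_seeds=6, rng_seed=trial)
            bc.append(min_pairwise(s.skin.astype(float)))
            pick = coords[rng.integers(len(coords), size=6)]
            uni.append(min_pairwise(pick.astype(float)))
        assert np.mean(bc) > np.mean(uni)

    def test_no_confident_region_errors(self, two_tone_image, model):
        img, _ = two_tone_image
        flat = np.full_like(img, 128)
        with pytest.raises(ValueError):
            propose_seeds(flat, model, n_seeds=3, rng_seed=0)


class TestConsensus:
    def test_three_identical_labels(self):
        m = np.random.default_rng(0).random((6, 6)) < 0.4
        assert np.array_equal(combine_annotations([m, m, m]), m)

    def test_pixel_quorum_enumeration(self):
        # every 2^3 vote pattern against brute-force counting
        for votes in itertools.product([0, 1], repeat=3):
            labels = [np.array([[bool(v)]]) for v in votes]
            out = combine_annotations(labels)
            assert out[0, 0] == (sum(votes) >= 2)

    def test_two_skips_image_negative(self):
        m = np.ones((3, 3), bool)
        assert combine_annotations([m, None, None]) is None

    def test_one_skip_still_positive(self):
        m = np.ones((3, 3), bool)
        out = combine_annotations([m, m, None])
        assert out.all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labels = [rng.random((5, 5)) < 0.5 for _ in range(3)]
        ref = combine_annotations(labels)
        for perm in itertools.permutations(labels):
            assert np.array_equal(combine_annotations(list(perm)), ref)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            combine_annotations([np.ones((2, 2), bool), np.ones((3, 3), bool)])

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ConsensusRule(pixel_quorum=4)


class TestAgreement:
    def test_identical_labels(self):
        m = np.random.default_rng(0).random((4, 4)) < 0.5
        assert agreement_score([m, m, m]) == 1.0

    def test_set_arithmetic_example(self):
        # A = B = {p1, p2}, C = {p2, p3} -> 2/3
        a = np.zeros((2, 2), bool); a[0, 0] = a[0, 1] = True
        c = np.zeros((2, 2), bool); c[0, 1] = c[1, 0] = True
        assert agreement_score([a, a.copy(), c]) == pytest.approx(2 / 3)

    def test_disjoint_singletons(self):
        labels = []
        for i in range(3):
            m = np.zeros((3, 3), bool)
            m[i, i] = True
            labels.append(m)
        assert agreement_score(labels) == 0.0

    def test_empty_union_defined_as_one(self):
        z = np.zeros((2, 2), bool)
        assert agreement_score([z, z, z]) == 1.0

    def test_monotone_under_similarity(self):
        rng = np.random.default_rng(2)
        base = rng.random((8, 8)) < 0.5
        noisy = base ^ (rng.random((8, 8)) < 0.3)
        closer = base ^ (rng.random((8, 8)) < 0.05)
        assert agreement_score([base, base, closer]) >= agreement_score(
            [base, base, noisy])
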