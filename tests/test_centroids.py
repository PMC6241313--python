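import numpy as np
import pytest

from diffcentroid.centroids import ic1_centroid, ic2_centroid, pw_centroid
from diffcentroid.currents import current_sqdist, to_current
from diffcentroid.kernels import KernelConfig
from diffcentroid.matching import MatchConfig
from diffcentroid.mesh_io import TriangleMesh
from diffcentroid.testing import EuclideanMatcher

KV = KernelConfig("cauchy", 10.0)
CFG = MatchConfig(kernel_V=KV, kernel_W=KernelConfig("cauchy", 5.0), max_iter=60)


def point_shape(p, scale=1e-3) -> TriangleMesh:
    """A tiny triangle whose barycenter is p: a 'single point' shape."""
    offsets = scale * np.array([[1, 0, 0], [-0.5, 0.8, 0], [-0.5, -0.8, 0]])
    return TriangleMesh(np.asarray(p, dtype=float) + offsets, np.array([[0, 1, 2]]))


@pytest.mark.parametrize("estimator", [ic1_centroid, ic2_centroid, pw_centroid])
def test_single_subject_returns_it(estimator, sphere12):
    kwargs = {} if estimator is pw_centroid else {"ordering": None}
    res = estimator([sphere12], CFG, **kwargs)
    assert res.n_matchings == 0
    (mesh, w), = res.as_collection()
    assert w == 1.0
    np.testing.assert_array_equal(mesh.vertices, sphere12.vertices)


class TestEuclideanMeanRecovery:
    """With an exact flat-space matcher, all estimators return the arithmetic mean."""

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    @pytest.mark.parametrize("estimator", [ic1_centroid, ic2_centroid, pw_centroid])
    def test_exact_mean(self, n, estimator, rng):
        pts = rng.normal(size=(n, 3)) * 5
        shapes = [point_shape(p) for p in pts]
        kwargs = {} if estimator is pw_centroid else {"ordering": None}
        res = estimator(shapes, CFG, matcher=EuclideanMatcher(), **kwargs)
        mean = pts.mean(axis=0)
        if res.is_collection:
            bary = np.mean(
                [m.vertices.mean(axis=0) for m, _ in res.as_collection()], axis=0
            )
        else:
            bary = res.centre.vertices.mean(axis=0)
        np.testing.assert_allclose(bary, mean, atol=1e-12)

    def test_matching_count_is_n_minus_one(self, rng):
        pts = rng.normal(size=(7, 3))
        shapes = [point_shape(p) for p in pts]
        for estimator in (ic1_centroid, ic2_centroid, pw_centroid):
            matcher = EuclideanMatcher()
            kwargs = {} if estimator is pw_centroid else {"ordering": None}
            res = estimator(shapes, CFG, matcher=matcher, **kwargs)
            assert res.n_matchings == 6
            assert matcher.n_calls == 6

    def test_pw_group_sizes_give_one_third_step(self, rng):
        shapes = [point_shape(p) for p in rng.normal(size=(3, 3))]
        res = pw_centroid(shapes, CFG, matcher=EuclideanMatcher())
        # subtrees of sizes 2 and 1 combine at t = 1/3
        assert res.step_log[-1]["t"] == pytest.approx(1 / 3)
        assert res.step_log[-1]["group_sizes"] == (2, 1)


class TestIC2Weights:
    def test_equal_weights_after_each_step(self, rng):
        for n in (2, 4, 5):
            shapes = [point_shape(p) for p in rng.normal(size=(n, 3))]
            res = ic2_centroid(shapes, CFG, matcher=EuclideanMatcher())
            weights = [w for _, w in res.as_collection()]
            np.testing.assert_allclose(weights, np.full(n, 1 / n))

    def test_collection_grows_linearly(self, rng):
        shapes = [point_shape(p) for p in rng.normal(size=(5, 3))]
        res = ic2_centroid(shapes, CFG, matcher=EuclideanMatcher())
        assert len(res.as_collection()) == 5


class TestOrdering:
    def test_default_is_input_order(self, rng):
        shapes = [point_shape(p) for p in rng.normal(size=(4, 3))]
        res = ic1_centroid(shapes, CFG, matcher=EuclideanMatcher())
        assert res.ordering == [0, 1, 2, 3]

    def test_seeded_shuffle_recorded_and_reproducible(self, rng):
        shapes = [point_shape(p) for p in rng.normal(size=(6, 3))]
        r1 = ic1_centroid(shapes, CFG, ordering=3, matcher=EuclideanMatcher())
        r2 = ic1_centroid(shapes, CFG, ordering=3, matcher=EuclideanMatcher())
        assert r1.ordering == r2.ordering
        assert sorted(r1.ordering) == [0, 1, 2, 3, 4, 5]

    def test_bad_permutation_rejected(self, rng):
        shapes = [point_shape(p) for p in rng.normal(size=(3, 3))]
        with pytest.raises(ValueError):
            ic1_centroid(shapes, CFG, ordering=[0, 0, 2], matcher=EuclideanMatcher())


@pytest.fixture(scope="module")
def pair(tiny_population):
    return tiny_population.shapes[:2]


class TestLDDMMCentroids:
    """Real-matcher behavior on a small shot pair (slow path, small meshes)."""

    def test_ic1_midpoint_property(self, pair, match_cfg):
        from dataclasses import replace

        from diffcentroid.matching import match

        cfg = replace(match_cfg, max_iter=60)
        res = ic1_centroid(pair, cfg)
        d1 = np.sqrt(match(res.centre, pair[0], cfg).energy)
        d2 = np.sqrt(match(res.centre, pair[1], cfg).energy)
        assert d1 == pytest.approx(d2, rel=0.15, abs=0.05 * cfg.kernel_V.sigma)

    def test_pw_two_subjects_equals_half_step(self, pair, match_cfg):
        from dataclasses import replace

        cfg = replace(match_cfg, max_iter=60)
        res_pw = pw_centroid(pair, cfg)
        res_ic1 = ic1_centroid(pair, cfg)
        kw = cfg.kernel_W_at(cfg.schedule[-1])
        d = current_sqdist(to_current(res_pw.centre), to_current(res_ic1.centre), kw)
        norm = current_sqdist(to_current(pair[0]), to_current(pair[1]), kw)
        assert d < 1e-6 * max(norm, 1.0)

    def test_connectivity_inherited_from_first_subject(self, pair, match_cfg):
        from dataclasses import replace

        res = ic1_centroid(pair, replace(match_cfg, max_iter=20))
        np.testing.assert_array_equal(res.centre.faces, pair[0].faces)


def test_ordering_robustness_small_population(tiny_population, small_match_cfg):
    """Different orderings land on nearby centroids (W* distance well below
    the subject-to-centre scale)."""
    shapes = tiny_population.shapes
    centres = []
    for seed in (0, 1, 2):
        res = ic1_centroid(shapes, small_match_cfg, ordering=seed)
        centres.append(res.centre)
    kw = small_match_cfg.kernel_W_at(small_match_cfg.schedule[-1])
    subject_scale = np.mean(
        [
            current_sqdist(to_current(s), to_current(centres[0]), kw)
            for s in shapes
        ]
    )
    pair_d = [
        current_sqdist(to_current(a), to_current(b), kw)
        for i, a in enumerate(centres)
        for b in centres[i + 1 :]
    ]
    assert max(pair_d) < 0.10 * subject_scale
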