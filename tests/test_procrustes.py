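"""Superimposition: centroid size, OPA, GPA, mirroring, sliding,
symmetrization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geckomorph as gm
from geckomorph.core import Curve, LandmarkScheme
from geckomorph.procrustes import (
    DegenerateConfigurationError,
    _centre_scale,
    slide_to_reference,
)

from conftest import random_rotation


def rotz(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestCentroidSize:
    def test_square_is_sqrt8(self):
        x = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert gm.centroid_size(x) == pytest.approx(np.sqrt(8), abs=1e-12)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        assert gm.centroid_size(c * x) == pytest.approx(
            c * gm.centroid_size(x), rel=1e-12)

    def test_rigid_invariance(self, base_shape):
        rng = np.random.default_rng(5)
        moved = base_shape @ random_rotation(rng) + rng.normal(size=3)
        assert gm.centroid_size(moved) == pytest.approx(
            gm.centroid_size(base_shape), rel=1e-12)

    def test_matches_brute_force_summation(self, base_shape):
        # direct Σ-of-squares oracle on the 55-landmark fixture
        centroid = base_shape.mean(axis=0)
        total = 0.0
        for row in base_shape:
            for a, b in zip(row, centroid):
                total += (a - b) ** 2
        assert gm.centroid_size(base_shape) == pytest.approx(np.sqrt(total), rel=1e-12)

    def test_degenerate_error(self):
        with pytest.raises(DegenerateConfigurationError):
            gm.centroid_size(np.ones((4, 3)))


def _rotation_grid_best_residual(moving, target, levels=3):
    """Independent oracle: hierarchical grid search over Euler angles for the
    minimal full-Procrustes residual (unit shapes)."""
    mu, _ = _centre_scale(moving)
    tu, _ = _centre_scale(target)

    def residual(angles):
        a, b, c = angles
        rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
        r = rx @ ry @ rotz(c)
        aligned = mu @ r
        # optimal nonnegative scale at this rotation (scale must be positive)
        beta = max((aligned * tu).sum(), 0.0)
        return np.linalg.norm(beta * aligned - tu)

    centre = np.zeros(3)
    width = np.pi
    best = np.inf
    for _ in range(levels):
        axes = [np.linspace(c0 - width, c0 + width, 21) for c0 in centre]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    r = residual((a, b, c))
                    if r < best:
                        best, centre = r, np.array([a, b, c])
        width /= 10.0
    return best


class TestOpa:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(0)
        target = rng.normal(size=(8, 3))
        moving = target @ rotz(np.pi / 2)
        aligned, rot, scale, resid = gm.opa_align(moving, target)
        assert resid < 1e-12
        np.testing.assert_allclose(aligned, target, atol=1e-12)
        np.testing.assert_allclose(rot, rotz(np.pi / 2).T, atol=1e-12)

    def test_reflection_flag(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=(9, 3))
        moving = target.copy()
        moving[:, 0] *= -1
        _, _, _, resid_proper = gm.opa_align(moving, target, allow_reflection=False)
        _, rot, _, resid_refl = gm.opa_align(moving, target, allow_reflection=True)
        assert resid_proper > 1e-3
        assert resid_refl < 1e-12
        assert np.linalg.det(rot) < 0

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        _, rot, _, _ = gm.opa_align(rng.normal(size=(6, 3)), rng.normal(size=(6, 3)))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_residual_matches_rotation_grid_search(self):
        rng = np.random.default_rng(3)
        moving, target = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        _, _, _, resid = gm.opa_align(moving, target)
        mu, _ = _centre_scale(moving)
        tu, _ = _centre_scale(target)
        r = mu @ gm.opa_align(moving, target)[1]
        beta = (r * tu).sum()
        analytic_unit = np.linalg.norm(beta * r - tu)
        oracle = _rotation_grid_best_residual(moving, target)
        assert analytic_unit == pytest.approx(oracle, abs=1e-3)
        assert analytic_unit <= oracle + 1e-9  # SVD optimum can't be beaten

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            gm.opa_align(np.zeros((4, 3)), np.zeros((5, 3)))


class TestGpa:
    def test_identical_shapes_collapse(self, base_shape):
        rng = np.random.default_rng(4)
        configs = []
        for i in range(4):
            x = 3.0 ** i * base_shape @ random_rotation(rng) + rng.normal(size=3)
            configs.append(gm.Configuration(specimen_id=f"s{i}", coords=x))
        ds = gm.gpa(configs)
        for i in range(1, 4):
            np.testing.assert_allclose(ds.shapes[i], ds.shapes[0], atol=1e-9)
        np.testing.assert_allclose(ds.consensus, ds.shapes[0], atol=1e-9)

    def test_unit_size_and_centred(self, aligned):
        for s in aligned.shapes:
            assert abs(np.sqrt((s**2).sum()) - 1.0) < 1e-9
            assert np.abs(s.mean(axis=0)).max() < 1e-9

    def test_consensus_is_fixed_point(self, aligned):
        # re-superimposing the aligned shapes moves the consensus only within
        # the convergence tolerance (up to the arbitrary global rotation)
        est = gm.GeneralizedProcrustes().fit(aligned.shapes)
        assert gm.procrustes_distance(est.consensus_, aligned.consensus) < 1e-5

    def test_equivariance_under_prerotation(self, base_shape):
        rng = np.random.default_rng(6)
        X = base_shape[None] + rng.normal(0, 0.01, size=(5, *base_shape.shape))
        ds1 = gm.GeneralizedProcrustes().fit(X)
        q = random_rotation(np.random.default_rng(9))
        ds2 = gm.GeneralizedProcrustes().fit(X @ q + rng.normal(size=3))
        # shapes agree up to one global rotation: align consensus to consensus
        r = gm.opa_align(ds2.consensus_, ds1.consensus_)[1]
        np.testing.assert_allclose(ds2.shapes_ @ r, ds1.shapes_, atol=1e-9)

    def test_consensus_local_optimality(self, base_shape):
        rng = np.random.default_rng(8)
        X = base_shape[None] + rng.normal(0, 0.02, size=(5, *base_shape.shape))
        est = gm.GeneralizedProcrustes().fit(X)

        def total_ss(candidate):
            ss = 0.0
            for x in est.shapes_:
                u, _ = _centre_scale(x)
                r = gm.opa_align(u, candidate)[1]
                cu, _ = _centre_scale(candidate)
                ss += np.linalg.norm(u @ r - cu) ** 2
            return ss

        base_ss = total_ss(est.consensus_)
        for k in range(10):
            probe = est.consensus_ + np.random.default_rng(k).normal(
                0, 1e-3, size=est.consensus_.shape)
            assert total_ss(probe) >= base_ss - 1e-12

    def test_centroid_sizes_recorded(self, base_shape):
        configs = [
            gm.Configuration(specimen_id="a", coords=2.0 * base_shape),
            gm.Configuration(specimen_id="b", coords=5.0 * base_shape),
        ]
        ds = gm.gpa(configs)
        np.testing.assert_allclose(ds.centroid_sizes, [2.0, 5.0], rtol=1e-12)


class TestMirror:
    def _cfg(self, base_shape, side="left"):
        return gm.Configuration(specimen_id="m", coords=base_shape.copy(), side=side)

    def test_involution(self, base_shape):
        c = self._cfg(base_shape)
        once = gm.mirror_configuration(c)
        with pytest.warns(UserWarning):  # second application is off-label
            twice = gm.mirror_configuration(once)
        np.testing.assert_array_equal(twice.coords, c.coords)

    def test_cs_unchanged(self, base_shape):
        c = self._cfg(base_shape)
        assert gm.centroid_size(gm.mirror_configuration(c)) == pytest.approx(
            gm.centroid_size(c), rel=1e-12)

    def test_symmetric_individual_distance_zero(self, base_shape):
        rng = np.random.default_rng(11)
        right = base_shape @ random_rotation(rng) + rng.normal(size=3)
        left = base_shape.copy()
        left[:, 0] *= -1
        left = left @ random_rotation(rng) + rng.normal(size=3)
        mirrored = gm.mirror_configuration(
            gm.Configuration(specimen_id="x", coords=left, side="left"))
        assert gm.procrustes_distance(mirrored.coords, right) < 1e-9

    def test_right_side_warns(self, base_shape):
        with pytest.warns(UserWarning):
            gm.mirror_configuration(self._cfg(base_shape, side="right"))


class TestSliding:
    def test_zero_displacement_at_consensus(self, aligned, scheme):
        X = np.stack([aligned.consensus] * 3)
        ds = gm.AlignedDataset(
            shapes=X, centroid_sizes=np.ones(3), consensus=aligned.consensus,
            metadata=[gm.Configuration(specimen_id=f"c{i}", coords=X[i]) for i in range(3)],
            scheme=scheme)
        slid = gm.slide_semilandmarks(ds, scheme)
        np.testing.assert_allclose(slid.shapes, X, atol=1e-12)

    def test_descent_property(self, sim_data, scheme):
        modern, _, _ = sim_data
        prepared = [gm.mirror_configuration(c) if c.side == "left" else c
                    for c in modern[:20]]
        ds = gm.gpa(prepared, scheme)
        totals = []
        current = ds
        for _ in range(4):
            current = gm.slide_semilandmarks(current, scheme, max_cycles=1)
            totals.append(sum(np.linalg.norm(s - current.consensus)
                              for s in current.shapes))
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_fixed_landmarks_never_move(self, aligned, scheme):
        rng = np.random.default_rng(12)
        X = aligned.shapes[:5].copy()
        ds = gm.AlignedDataset(
            shapes=X.copy(), centroid_sizes=np.ones(5), consensus=aligned.consensus,
            metadata=[gm.Configuration(specimen_id=f"c{i}", coords=X[i]) for i in range(5)],
            scheme=scheme)
        slid = gm.slide_semilandmarks(ds, scheme, max_cycles=1)
        # fixed block may rotate with re-GPA but not deform: Procrustes
        # distance restricted to fixed landmarks vs original is tiny
        for before, after in zip(X, slid.shapes):
            d = gm.procrustes_distance(before[:scheme.n_fixed], after[:scheme.n_fixed])
            assert d < 5e-3

    def test_matches_1d_grid_oracle(self):
        # single curve of 3 semilandmarks on a line; target shifted along the
        # line: sliding each point is a 1-D minimization checked by dense grid
        scheme = LandmarkScheme(
            n_fixed=5, curves=(Curve(start=0, semilandmarks=(5, 6, 7), end=1),))
        ref = np.zeros((8, 3))
        ref[0] = [0, 0, 0]
        ref[1] = [4, 0, 0]
        ref[2] = [0, 3, 0]
        ref[3] = [4, 3, 1]
        ref[4] = [2, 5, 2]
        ref[5:8, 0] = [1.0, 2.0, 3.0]
        shape = ref.copy()
        shape[5:8, 0] = [0.8, 1.7, 3.3]  # semis displaced along the curve
        neighbours = scheme.neighbours()
        from geckomorph.procrustes import _slide_one

        slid = _slide_one(shape, ref, neighbours)
        for j in (5, 6, 7):
            prev, nxt = neighbours[j]
            t = shape[nxt] - shape[prev]
            t = t / np.linalg.norm(t)
            bound = 0.5 * min(np.linalg.norm(shape[j] - shape[prev]),
                              np.linalg.norm(shape[nxt] - shape[j]))
            grid = np.linspace(-bound, bound, 200001)
            cand = shape[j][None] + grid[:, None] * t[None]
            best = cand[np.argmin(((cand - ref[j]) ** 2).sum(1))]
            np.testing.assert_allclose(slid[j], best, atol=1e-5)
            # and the slid point is no worse than every grid candidate
            assert np.linalg.norm(slid[j] - ref[j]) <= np.min(
                np.linalg.norm(cand - ref[j], axis=1)) + 1e-9


class TestSymmetrize:
    def test_pair_counts(self, aligned, sim_data):
        modern, _, _ = sim_data
        assert aligned.n_specimens == len({c.specimen_id for c in modern})
        assert aligned.symmetrized
        assert not aligned.unpaired.any()

    def test_exact_mirror_pair_equals_either_side(self, base_shape, scheme):
        right = gm.Configuration(specimen_id="i1", coords=base_shape.copy(), side="right")
        left_coords = base_shape.copy()
        left_coords[:, 0] *= -1
        left = gm.Configuration(specimen_id="i1", coords=left_coords, side="left")
        filler = [
            gm.Configuration(specimen_id=f"f{i}",
                             coords=base_shape + np.random.default_rng(i).normal(0, 0.01, base_shape.shape))
            for i in range(2)
        ]
        ds = gm.gpa([gm.mirror_configuration(left), right] + filler, scheme)
        sym = gm.symmetrize_pairs(ds)
        i1 = [i for i, m in enumerate(sym.metadata) if m.specimen_id == "i1"][0]
        d = gm.procrustes_distance(sym.shapes[i1], right.coords)
        assert d < 1e-9

    def test_constructed_asymmetry_midpoint(self, base_shape, scheme):
        rng = np.random.default_rng(13)
        d = rng.normal(0, 0.002, size=base_shape.shape)
        plus = gm.Configuration(specimen_id="p", coords=base_shape + d, side="right")
        minus = gm.Configuration(specimen_id="p", coords=base_shape - d, side="right")
        other = gm.Configuration(
            specimen_id="q", coords=base_shape + rng.normal(0, 0.01, base_shape.shape))
        ds = gm.gpa([plus, minus, other], scheme)
        sym = gm.symmetrize_pairs(ds)
        ip = [i for i, m in enumerate(sym.metadata) if m.specimen_id == "p"][0]
        # midpoint of +d/−d is the base shape, coordinate-wise after alignment
        # exact to second order in the asymmetry magnitude
        u = base_shape / np.sqrt((base_shape**2).sum())
        r = gm.opa_align(sym.shapes[ip], u)[1]
        np.testing.assert_allclose(sym.shapes[ip] @ r, u, atol=1e-4)
        # and far closer to the base than either side is
        assert gm.procrustes_distance(sym.shapes[ip], u) < 0.05 * gm.procrustes_distance(
            base_shape + d, u)

    def test_single_side_passes_through_flagged(self, base_shape, scheme):
        rng = np.random.default_rng(14)
        configs = [
            gm.Configuration(specimen_id="solo", coords=base_shape.copy(), side="right"),
            gm.Configuration(specimen_id="pair", coords=base_shape + rng.normal(0, 0.01, base_shape.shape), side="right"),
            gm.Configuration(specimen_id="pair", coords=base_shape + rng.normal(0, 0.01, base_shape.shape), side="right"),
        ]
        sym = gm.symmetrize_pairs(gm.gpa(configs, scheme))
        flags = {m.specimen_id: u for m, u in zip(sym.metadata, sym.unpaired)}
        assert flags == {"solo": True, "pair": False}
        assert sym.n_specimens == 2

    def test_three_elements_is_error(self, base_shape, scheme):
        configs = [
            gm.Configuration(specimen_id="x", coords=base_shape + 0.01 * i)
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="3 elements"):
            gm.symmetrize_pairs(gm.gpa(configs, scheme))

    def test_centroid_size_is_side_mean(self, base_shape, scheme):
        a = gm.Configuration(specimen_id="z", coords=2.0 * base_shape, side="right")
        b = gm.Configuration(specimen_id="z", coords=4.0 * base_shape, side="right")
        c = gm.Configuration(specimen_id="w", coords=3.0 * base_shape, side="right")
        sym = gm.symmetrize_pairs(gm.gpa([a, b, c], scheme))
        cs = {m.specimen_id: s for m, s in zip(sym.metadata, sym.centroid_sizes)}
        assert cs["z"] == pytest.approx(3.0, rel=1e-9)


class TestProcrustesDistanceMetric:
    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(15)
        a, b, c = rng.normal(size=(3, 10, 3))
        dab = gm.procrustes_distance(a, b)
        dba = gm.procrustes_distance(b, a)
        dac = gm.procrustes_distance(a, c)
        dcb = gm.procrustes_distance(c, b)
        assert dab == pytest.approx(dba, abs=1e-9)
        assert dab <= dac + dcb + 1e-9

    def test_rigid_motion_invariance(self, base_shape):
        rng = np.random.default_rng(16)
        other = base_shape + rng.normal(0, 0.05, size=base_shape.shape)
        d0 = gm.procrustes_distance(base_shape, other)
        moved = 2.5 * base_shape @ random_rotation(rng) + rng.normal(size=3)
        assert gm.procrustes_distance(moved, other) == pytest.approx(d0, abs=1e-9)
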