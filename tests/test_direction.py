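"""Blocked-direction cones, icosphere sampling and the binding direction."""

import numpy as np
import pytest

from ppisect.direction import (
    BlockedCone, FullyBlockedError, accumulate_counts, binding_direction,
    blocked_cone, group_free_points, interface_atoms, sample_unit_sphere,
    surface_distance,
)
from ppisect.fixtures import FixtureSpec, make_fixture
from ppisect.structures import Molecule, SphereAtom


def atom(x, y, z, r=1.0):
    return SphereAtom((float(x), float(y), float(z)), float(r))


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


class TestSurfaceDistance:
    @pytest.mark.parametrize("d, expected", [(4.0, 2.0), (0.0, -2.0), (2.0, 0.0)])
    def test_gap_between_unit_spheres(self, d, expected):
        assert surface_distance(atom(0, 0, 0), atom(d, 0, 0)) == pytest.approx(expected)


class TestBlockedCone:
    def test_separated_pair_half_angle(self):
        cone = blocked_cone(atom(4, 0, 0), atom(0, 0, 0))
        assert cone.half_angle == pytest.approx(np.pi / 6)
        assert cone.axis == pytest.approx((1.0, 0.0, 0.0))

    def test_interpenetrating_pair_is_half_space(self):
        cone = blocked_cone(atom(1.5, 0, 0), atom(0, 0, 0))
        assert cone.half_angle == pytest.approx(np.pi / 2)

    def test_tangent_pair_is_half_space(self):
        cone = blocked_cone(atom(2.0, 0, 0), atom(0, 0, 0))
        assert cone.half_angle == pytest.approx(np.pi / 2)

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            blocked_cone(atom(0, 0, 0), atom(0, 0, 0))

    def test_axis_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            BlockedCone((2.0, 0.0, 0.0), 0.5)

    def test_membership_matches_swept_ray_oracle(self, rng):
        """Cone membership ⟺ the infinite ray from b along u passes within
        r_a + r_b of a's centre (closed-form point-to-ray distance)."""
        mismatches = 0
        for _ in range(500):
            ca = rng.uniform(-5, 5, 3)
            cb = rng.uniform(-5, 5, 3)
            ra, rb = rng.uniform(0.8, 2.0, 2)
            a, b = SphereAtom(tuple(ca), ra), SphereAtom(tuple(cb), rb)
            if surface_distance(a, b) <= 0.01:
                continue
            cone = blocked_cone(a, b)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            w = ca - cb
            s = max(float(w @ u), 0.0)
            ray_hits = np.linalg.norm(w - s * u) < ra + rb
            if bool(cone.contains(u)) != bool(ray_hits):
                mismatches += 1
        assert mismatches == 0


class TestInterfaceAtoms:
    def test_close_pair_selected(self):
        ma = Molecule("A", [atom(0, 0, 0)])
        mb = Molecule("B", [atom(4, 0, 0)])  # surface distance 2 Å
        sub_a, sub_b = interface_atoms(ma, mb, delta=5.0)
        assert len(sub_a) == 1 and len(sub_b) == 1

    def test_distant_pair_raises(self):
        ma = Molecule("A", [atom(0, 0, 0)])
        mb = Molecule("B", [atom(9, 0, 0)])  # surface distance 7 Å
        with pytest.raises(ValueError, match="no interface"):
            interface_atoms(ma, mb, delta=5.0)

    def test_slab_selection_matches_all_pairs_brute_force(self, slab_pair):
        ma, mb, _ = slab_pair  # 5×5 vs 5×5, gap 3 Å
        sub_a, sub_b = interface_atoms(ma, mb, delta=5.0)
        gaps = (np.linalg.norm(ma.centers[:, None] - mb.centers[None], axis=-1)
                - ma.radii[:, None] - mb.radii[None])
        assert len(sub_a) == int((gaps.min(axis=1) <= 5.0).sum()) == 25
        assert len(sub_b) == int((gaps.min(axis=0) <= 5.0).sum()) == 25


class TestSampleUnitSphere:
    def test_icosahedron_level0(self):
        s = sample_unit_sphere(0)
        assert len(s) == 12
        assert all(len(nb) == 5 for nb in s.neighbors)

    def test_point_count_formula(self):
        assert len(sample_unit_sphere(3)) == 10 * 4 ** 3 + 2

    def test_points_are_unit_and_adjacency_symmetric(self, sampling_level3):
        s = sampling_level3
        np.testing.assert_allclose(np.linalg.norm(s.points, axis=1), 1.0,
                                   atol=1e-9)
        for p, nbs in enumerate(s.neighbors):
            for q in nbs:
                assert p in s.neighbors[q]

    def test_angular_resolution_improves_with_level(self):
        def max_neighbor_gap(level):
            s = sample_unit_sphere(level)
            worst = 0.0
            for p, nbs in enumerate(s.neighbors):
                cosines = s.points[nbs] @ s.points[p]
                worst = max(worst, float(np.arccos(np.clip(cosines.min(), -1, 1))))
            return worst

        gaps = [max_neighbor_gap(level) for level in range(4)]
        assert all(b < a for a, b in zip(gaps, gaps[1:]))


class TestAccumulateCounts:
    def test_axis_point_counted_antipode_not(self, sampling_level3):
        cone = BlockedCone((0.0, 0.0, 1.0), np.pi / 6)
        s = accumulate_counts(sampling_level3, [cone])
        i_top = int(np.argmax(s.points @ np.array([0, 0, 1.0])))
        i_bot = int(np.argmin(s.points @ np.array([0, 0, 1.0])))
        assert s.counts[i_top] == 1
        assert s.counts[i_bot] == 0

    def test_matches_per_point_double_loop(self, sampling_level3, rng):
        axes = rng.normal(size=(20, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        halves = rng.uniform(0.05, np.pi / 2, 20)
        cones = [BlockedCone(tuple(a), h) for a, h in zip(axes, halves)]
        s = accumulate_counts(sampling_level3, cones)
        brute = np.zeros(len(s), dtype=int)
        for i, p in enumerate(s.points):
            for c in cones:
                if np.dot(p, c.axis) >= np.cos(c.half_angle):
                    brute[i] += 1
        np.testing.assert_array_equal(s.counts, brute)

    def test_counts_invariant_under_cone_permutation(self, sampling_level3, rng):
        axes = rng.normal(size=(10, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        cones = [BlockedCone(tuple(a), h)
                 for a, h in zip(axes, rng.uniform(0.1, 1.5, 10))]
        c1 = accumulate_counts(sampling_level3, cones).counts.copy()
        rng.shuffle(cones)
        c2 = accumulate_counts(sampling_level3, cones).counts.copy()
        np.testing.assert_array_equal(c1, c2)


class TestGroupFreePoints:
    def test_all_free_is_one_group(self, sampling_level3):
        s = accumulate_counts(sampling_level3, [])
        s = group_free_points(s, count_threshold=1)
        assert set(s.group) == {0}

    def test_antipodal_caps_form_two_groups(self, sampling_level3):
        s = sampling_level3
        z = s.points[:, 2]
        # block the equatorial band, freeing two antipodal caps
        s.counts = np.where(np.abs(z) < 0.5, 1, 0)
        s = group_free_points(s, count_threshold=1)
        labels = s.group[s.group >= 0]
        assert len(np.unique(labels)) == 2

    def test_no_free_points_raises(self, sampling_level3):
        s = sampling_level3
        s.counts = np.ones(len(s), dtype=np.int64)
        with pytest.raises(FullyBlockedError):
            group_free_points(s, count_threshold=1)


class TestBindingDirection:
    def test_single_pair_along_x(self):
        ma = Molecule("A", [atom(0, 0, 0)])
        mb = Molecule("B", [atom(3, 0, 0)])
        res = binding_direction(ma, mb, delta=5.0, level=3)
        assert angle_deg(res.separating_direction, [1, 0, 0]) < 5.0
        assert angle_deg(res.binding_direction, [-1, 0, 0]) < 5.0
        np.testing.assert_allclose(res.binding_direction,
                                   -res.separating_direction, atol=1e-12)

    def test_role_swap_negates_direction(self):
        ma = Molecule("A", [atom(0, 0, 0)])
        mb = Molecule("B", [atom(3, 0, 0)])
        fwd = binding_direction(ma, mb, delta=5.0, level=3)
        rev = binding_direction(mb, ma, delta=5.0, level=3)
        assert angle_deg(fwd.binding_direction, -rev.binding_direction) < 5.0

    def test_slab_fixture_recovers_axis(self, slab_pair, sampling_level4):
        ma, mb, gt = slab_pair
        res = binding_direction(ma, mb, delta=5.0, sampling=sampling_level4)
        assert angle_deg(res.separating_direction,
                         gt["separating_direction"]) < 5.0

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation
        ma, mb, _ = make_fixture(FixtureSpec("slab_pair", n=3, gap=2.0))
        base = binding_direction(ma, mb, delta=5.0, level=4)
        rot = Rotation.random(random_state=7).as_matrix()
        res = binding_direction(ma.transformed(rotation=rot),
                                mb.transformed(rotation=rot),
                                delta=5.0, level=4)
        assert angle_deg(res.separating_direction,
                         rot @ base.separating_direction) < 5.0

    def test_groups_sorted_by_size_and_free_fraction_consistent(self, slab_pair):
        ma, mb, _ = slab_pair
        res = binding_direction(ma, mb, delta=5.0, level=3)
        sizes = [s for s, _ in res.groups]
        assert sizes == sorted(sizes, reverse=True)
        n = 10 * 4 ** 3 + 2
        assert res.free_fraction == pytest.approx(sum(sizes) / n)

    def test_fully_blocked_relaxes_threshold_with_warning(self):
        ma = Molecule("A", [atom(0, 0, 0)])
        mb = Molecule("B", [atom(0, 0, 0)])  # coincident: blocks everything
        with pytest.warns(RuntimeWarning):
            res = binding_direction(ma, mb, delta=5.0, level=1)
        assert res.relaxed
        assert res.count_threshold == 2
        assert res.free_fraction == pytest.approx(1.0)

    def test_separation_along_returned_direction_is_collision_free(self):
        from ppisect.fixtures import oracle_swept_collision
        for kind, kw in [("two_atom", {}), ("slab_pair", {"n": 5, "gap": 3.0})]:
            ma, mb, _ = make_fixture(FixtureSpec(kind, **kw))
            res = binding_direction(ma, mb, delta=5.0, level=4)
            d = res.separating_direction / np.linalg.norm(res.separating_direction)
            assert not oracle_swept_collision(mb, ma, d, res.delta)
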