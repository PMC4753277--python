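"""Tests for SWC handling, density maps, Sholl profiles, convex hulls,
layer-resolved lengths and basket-cell subtype clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ampakit import morphometry as mo
from ampakit import synthetic_data as sd


def simple_morph(rows):
    return mo.Morphology(
        nodes=pd.DataFrame(
            rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]
        )
    )


def random_tree(rng, n=40, spread=120.0):
    """Random connected tree rooted at a soma node at the origin."""
    rows = [(1, mo.SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    for i in range(2, n + 2):
        parent = int(rng.integers(1, i))
        stype = mo.AXON if rng.random() < 0.6 else mo.DENDRITE
        rows.append(
            (i, stype, rng.normal(0, spread), rng.normal(0, spread),
             rng.normal(0, 5.0), 0.5, parent)
        )
    return simple_morph(rows)


BOUNDS = mo.LayerBoundaries(l1_l23=100.0, l23_l4=350.0, l4_l5=450.0,
                            l5_l6=700.0)


class TestSWC:
    def test_three_node_cable_total_length(self):
        m = simple_morph(
            [
                (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
                (2, 2, 0.0, 30.0, 0.0, 0.5, 1),
                (3, 2, 0.0, 70.0, 0.0, 0.5, 2),
            ]
        )
        assert m.total_length(mo.AXON) == pytest.approx(70.0)

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        m = random_tree(rng)
        p = tmp_path / "cell.swc"
        mo.write_swc(m, p)
        back = mo.read_swc(p)
        for col in ("x", "y", "z", "radius"):
            assert np.allclose(back.nodes[col], m.nodes[col])
        assert (back.nodes["parent"] == m.nodes["parent"]).all()

    def test_dangling_parent_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 2 0 1 0 1 99\n")
        with pytest.raises(mo.SWCError, match="dangling"):
            mo.read_swc(p)

    def test_cycle_rejected(self):
        with pytest.raises(mo.SWCError, match="cycle"):
            simple_morph(
                [
                    (1, 1, 0, 0, 0, 5, 2),
                    (2, 2, 0, 1, 0, 1, 1),
                ]
            )

    def test_malformed_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5\n")
        with pytest.raises(mo.SWCError, match="7 columns"):
            mo.read_swc(p)


class TestSholl:
    def test_straight_cable_crosses_every_circle_once(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        ys = np.linspace(2.0, 100.0, 25)
        for i, y in enumerate(ys, start=2):
            rows.append((i, 2, 0.0, float(y), 0.0, 0.5, i - 1))
        prof = mo.sholl_profile(simple_morph(rows), step=6.5)
        inside = prof.radii < 100.0
        assert np.all(prof.crossings["axon"][inside] == 1)
        assert np.all(prof.crossings["axon"][~inside] == 0)

    def test_y_branch_doubles_crossings_past_the_fork(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        nid = 2
        trunk_end = None
        for y in np.linspace(5.0, 50.0, 10):
            rows.append((nid, 2, 0.0, float(y), 0.0, 0.5, nid - 1))
            trunk_end = nid
            nid += 1
        for dx in (-1.0, 1.0):
            parent = trunk_end
            for k, y in enumerate(np.linspace(55.0, 120.0, 12), 1):
                rows.append((nid, 2, dx * 2.0 * k, float(y), 0.0, 0.5, parent))
                parent = nid
                nid += 1
        prof = mo.sholl_profile(simple_morph(rows), step=6.5)
        below = prof.radii < 50.0
        assert np.all(prof.crossings["axon"][below] == 1)
        assert np.all(prof.crossings["axon"][prof.radii == 52.0] <= 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_geometric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_tree(rng)
        prof = mo.sholl_profile(m, step=6.5)
        sx, sy = m.soma_position
        for stype, name in ((mo.AXON, "axon"), (mo.DENDRITE, "dendrite")):
            seg = m.segments(stype)
            for ri, r in enumerate(prof.radii):
                count = 0
                for row in seg.itertuples(index=False):
                    d0 = np.hypot(row.x0 - sx, row.y0 - sy)
                    d1 = np.hypot(row.x1 - sx, row.y1 - sy)
                    if min(d0, d1) <= r < max(d0, d1):
                        count += 1
                assert prof.crossings[name][ri] == count


class TestConvexHull:
    def test_square_with_interior_point(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        hull = mo.convex_hull(pts)
        assert len(hull) == 4
        assert mo.hull_area(hull) == pytest.approx(1.0)

    def test_counter_clockwise_order(self):
        hull = mo.convex_hull(np.array([[0, 0], [2, 0], [2, 2], [0, 2]]))
        x, y = hull[:, 0], hull[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(mo.DegenerateHullError):
            mo.convex_hull(pts)

    def test_matches_scipy_oracle_on_random_points(self, rng):
        from scipy.spatial import ConvexHull

        for _ in range(20):
            pts = rng.normal(0, 10, (100, 2))
            ours = {tuple(np.round(v, 9)) for v in mo.convex_hull(pts)}
            ref = {tuple(np.round(v, 9)) for v in pts[ConvexHull(pts).vertices]}
            assert ours == ref

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        dx=st.floats(-100.0, 100.0),
        dy=st.floats(-100.0, 100.0),
    )
    def test_area_invariant_under_rigid_motion(self, angle, dx, dy):
        rng = np.random.default_rng(99)
        pts = rng.normal(0, 5, (40, 2))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + [dx, dy]
        a0 = mo.hull_area(mo.convex_hull(pts))
        a1 = mo.hull_area(mo.convex_hull(moved))
        assert a1 == pytest.approx(a0, rel=1e-6)


class TestHullFraction:
    def test_bisected_square(self):
        hull = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert mo.hull_fraction_above(hull, 0.5) == pytest.approx(0.5)

    def test_boundary_above_hull_gives_zero(self):
        hull = np.array([[0.0, 5.0], [1.0, 5.0], [1.0, 6.0], [0.0, 6.0]])
        assert mo.hull_fraction_above(hull, 2.0) == 0.0
        assert mo.hull_fraction_above(hull, 10.0) == 1.0

    def test_matches_monte_carlo_oracle(self, rng):
        from shapely.geometry import Polygon
        from shapely import contains_xy

        pts = rng.normal(0, 10, (30, 2))
        hull = mo.convex_hull(pts)
        boundary = float(np.median(pts[:, 1]))
        frac = mo.hull_fraction_above(hull, boundary)
        poly = Polygon(hull)
        minx, miny, maxx, maxy = poly.bounds
        n = 200_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        inside = contains_xy(poly, xs, ys)
        above = inside & (ys < boundary)
        mc = above.sum() / inside.sum()
        assert frac == pytest.approx(mc, abs=0.01)


class TestPerLayerLengths:
    def test_compartment_inside_one_layer(self):
        m = simple_morph(
            [
                (1, 1, 0.0, 500.0, 0.0, 5.0, -1),
                (2, 2, 0.0, 550.0, 0.0, 0.5, 1),
            ]
        )
        tab = mo.per_layer_lengths(m, BOUNDS).set_index("layer")
        assert tab.loc["L5", "axon_um"] == pytest.approx(50.0)
        assert tab.drop("L5")["axon_um"].sum() == 0.0

    def test_compartment_split_across_boundary(self):
        m = simple_morph(
            [
                (1, 1, 0.0, 430.0, 0.0, 5.0, -1),
                (2, 2, 0.0, 470.0, 0.0, 0.5, 1),  # spans the L4/L5 line
            ]
        )
        tab = mo.per_layer_lengths(m, BOUNDS).set_index("layer")
        assert tab.loc["L4", "axon_um"] == pytest.approx(20.0)
        assert tab.loc["L5", "axon_um"] == pytest.approx(20.0)

    def test_generated_classes_have_expected_laminar_footprint(self):
        mc, _ = sd.gen_morphology("MC", BOUNDS, seed=1)
        tab = mo.per_layer_lengths(mc, BOUNDS).set_index("layer")
        assert tab.loc["L1", "axon_um"] > 0
        bc2, _ = sd.gen_morphology("BC2", BOUNDS, seed=1)
        tab2 = mo.per_layer_lengths(bc2, BOUNDS).set_index("layer")
        supra = tab2.loc[["L1", "L2/3"], "axon_um"].sum()
        assert supra / tab2["axon_um"].sum() < 0.05


class TestDensityMap:
    def test_mass_proportional_to_length(self):
        m = simple_morph(
            [
                (1, 1, 0.0, 500.0, 0.0, 5.0, -1),
                (2, 2, 10.0, 520.0, 0.0, 0.5, 1),
            ]
        )
        dm = mo.density_map([m], BOUNDS, structure=mo.AXON, mirror=False,
                            normalize=False)
        # unit-mass Gaussian blur of a length-weighted impulse
        assert dm.grid.sum() == pytest.approx(m.total_length(mo.AXON), rel=1e-6)

    def test_mass_scales_linearly_with_arbor_length(self, rng):
        m = random_tree(rng, n=30)
        m.nodes["y"] += 400.0
        dm1 = mo.density_map([m], BOUNDS, structure=mo.AXON, mirror=False,
                             normalize=False, extent=1500.0)
        m2 = m.nodes.copy()
        m2[["x", "y", "z"]] = (m2[["x", "y", "z"]] - [0, 400, 0]) * 2 + [0, 400, 0]
        dm2 = mo.density_map([mo.Morphology(nodes=m2)], BOUNDS,
                             structure=mo.AXON, mirror=False, normalize=False,
                             extent=1500.0)
        assert dm2.grid.sum() == pytest.approx(2 * dm1.grid.sum(), rel=1e-3)

    def test_mirrored_map_is_symmetric(self, rng):
        m = random_tree(rng, n=30)
        m.nodes["y"] += 400.0
        dm = mo.density_map([m], BOUNDS, structure=mo.AXON, mirror=True)
        assert np.allclose(dm.grid, dm.grid[:, ::-1], atol=1e-10)

    def test_maximum_position_matches_brute_force(self):
        # two compartments at known offsets; compare peak locations with a
        # direct sum-of-Gaussians evaluation on the same grid
        m = simple_morph(
            [
                (1, 1, 0.0, 450.0, 0.0, 5.0, -1),
                (2, 2, -60.0, 400.0, 0.0, 0.5, 1),
                (3, 2, -60.0, 300.0, 0.0, 0.5, 2),
            ]
        )
        dm = mo.density_map([m], BOUNDS, structure=mo.AXON, mirror=False,
                            normalize=False, bin_um=5.0)
        seg = m.segments(mo.AXON)
        mx = 0.5 * (seg.x0 + seg.x1).to_numpy()
        my = 0.5 * (seg.y0 + seg.y1).to_numpy() - BOUNDS.l4_l5
        w = seg.length.to_numpy()
        X, Y = np.meshgrid(dm.lateral, dm.depth)
        brute = sum(
            wi * np.exp(-((X - xi) ** 2 + (Y - yi) ** 2) / (2 * 25.0**2))
            for xi, yi, wi in zip(mx, my, w)
        )
        ours = np.unravel_index(np.argmax(dm.grid), dm.grid.shape)
        ref = np.unravel_index(np.argmax(brute), brute.shape)
        assert abs(ours[0] - ref[0]) <= 1 and abs(ours[1] - ref[1]) <= 1

    def test_gamma_is_display_only(self, rng):
        m = random_tree(rng, n=20)
        m.nodes["y"] += 400.0
        dm = mo.density_map([m], BOUNDS, structure=mo.AXON, gamma=0.5)
        assert np.allclose(dm.display, np.sqrt(dm.grid))


class TestClustering:
    def test_hand_computed_single_linkage_partition(self):
        # merges: 0.01-0.02 (1e-4), 0.02-0.03 (1e-4), 0.60-0.62 (4e-4),
        # bridge (0.60-0.03)^2 = 0.3249; 25% cut = 0.0812 -> {3, 2}
        res = mo.cluster_interneurons([0.01, 0.02, 0.03, 0.60, 0.62])
        assert res.n_clusters == 2
        sizes = sorted(np.bincount(res.labels)[1:].tolist())
        assert sizes == [2, 3]

    def test_identical_features_single_cluster(self):
        res = mo.cluster_interneurons([0.4] * 6)
        assert res.n_clusters == 1

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            mo.cluster_interneurons([0.5])

    def test_fcm_agrees_on_well_separated_features(self):
        feats = [0.02, 0.03, 0.05, 0.55, 0.60, 0.62]
        res = mo.cluster_interneurons(feats)
        assert res.n_clusters == 2
        assert res.agreement == 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
        perm_seed=st.integers(0, 1000),
    )
    def test_labels_invariant_to_order_and_affine_transform(
        self, scale, offset, perm_seed
    ):
        feats = np.array([0.01, 0.02, 0.03, 0.60, 0.62])
        base = mo.cluster_interneurons(feats).labels
        perm = np.random.default_rng(perm_seed).permutation(len(feats))
        res = mo.cluster_interneurons(scale * feats[perm] + offset)
        # partition equality irrespective of label names
        a = base[perm]
        b = res.labels
        pairs_a = (a[:, None] == a[None, :])
        pairs_b = (b[:, None] == b[None, :])
        assert np.array_equal(pairs_a, pairs_b)


class TestEnsembleHull:
    def test_union_of_hulls_and_mirrors(self):
        h1 = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        ens = mo.ensemble_hull([h1], mirror_axis=0.0)
        # mirror image spans [-2, 0] x [0, 2]
        assert mo.hull_area(ens) == pytest.approx(8.0)
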