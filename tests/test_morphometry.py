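"""Arbor metrics: lengths, branch points, polygon territories, extent."""

import numpy as np
import pytest

from arbormetry import (
    ArborSimParams,
    NeuronReconstruction,
    arbor_density,
    assign_sections,
    branch_density,
    compute_metrics,
    convex_polygon_area,
    count_branch_points,
    generate_arbor,
    mediolateral_summary,
    territory_volume,
    topographic_correlation,
    total_length,
)


def hull_area_bruteforce(pts: np.ndarray) -> float:
    """O(n^3) extreme-edge convex hull oracle: a directed edge (i, j) is
    on the hull iff every other point lies on its left; hull edges sorted
    by direction give the polygon, whose area is the shoelace sum."""
    pts = np.asarray(pts, float)
    n = len(pts)
    scale = np.abs(pts).max() or 1.0
    eps = 1e-9 * scale * scale
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross >= -eps):
                edges.append((i, j))
    if len(edges) < 3:
        return 0.0
    edges.sort(key=lambda e: np.arctan2(*(pts[e[1]] - pts[e[0]])[::-1]))
    v = np.array([pts[i] for i, _ in edges])
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestLengthsAndBranches:
    def test_345_edge(self):
        rec = NeuronReconstruction(
            ids=[1, 2],
            type_codes=[1, 2],
            xyz=np.array([[0.0, 0, 0], [3.0, 4.0, 0]]),
            radius=[1, 1],
            parent_ids=[-1, 1],
        )
        assert total_length(rec, "axon") == pytest.approx(5.0)

    def test_y_arbor_three_unit_edges(self, y_arbor):
        assert total_length(y_arbor, "axon") == pytest.approx(3.0)
        assert count_branch_points(y_arbor, "axon") == 1

    def test_unbranched_path(self, straight_axon):
        assert count_branch_points(straight_axon(n_nodes=10), "axon") == 0

    def test_empty_selection_warns_and_returns_zero(self, straight_axon):
        with pytest.warns(UserWarning):
            assert total_length(straight_axon(), "dendrite") == 0.0

    def test_generator_bookkeeping_oracle(self):
        # every generated edge has exactly the step length
        p = ArborSimParams(target_length=100_000.0, step_length=10.0, seed=3)
        rec = generate_arbor(p)
        n_axon = int(np.sum(rec.type_codes == 2))
        assert total_length(rec, "axon") == pytest.approx(n_axon * 10.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_branch_points_equal_bruteforce_recount(self, seed):
        rec = generate_arbor(ArborSimParams(target_length=20_000, seed=seed))
        # independent adjacency scan over the raw SWC table
        from collections import Counter

        kids = Counter()
        for nid, code, pid in zip(rec.ids, rec.type_codes, rec.parent_ids):
            if pid != -1 and code == 2:
                kids[int(pid)] += 1
        axon_ids = {int(i) for i, c in zip(rec.ids, rec.type_codes) if c == 2}
        expect = sum(1 for nid, k in kids.items() if k >= 2 and nid in axon_ids)
        assert count_branch_points(rec, "axon") == expect

    def test_trifurcation_counts_once(self):
        xyz = np.array([[0.0, 0, 0], [0, 0, 1], [1, 0, 2], [0, 1, 2], [-1, 0, 2]])
        rec = NeuronReconstruction(
            ids=[1, 2, 3, 4, 5],
            type_codes=[1, 2, 2, 2, 2],
            xyz=xyz,
            radius=np.ones(5),
            parent_ids=[-1, 1, 2, 2, 2],
        )
        assert count_branch_points(rec, "axon") == 1

    def test_branch_density_arithmetic(self):
        # 1000 branch points on 250 mm of cable -> 4.0 per mm; checked via
        # a synthetic arbor is overkill, so check the division contract on
        # a tiny arbor instead
        rec = NeuronReconstruction(
            ids=[1, 2, 3, 4],
            type_codes=[1, 2, 2, 2],
            xyz=np.array([[0.0, 0, 0], [0, 0, 500], [400, 0, 800], [-400, 0, 800]]),
            radius=np.ones(4),
            parent_ids=[-1, 1, 2, 2],
        )
        length_mm = total_length(rec, "axon") / 1e3
        assert branch_density(rec, "axon") == pytest.approx(1.0 / length_mm)

    def test_zero_length_density_errors(self, y_arbor):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                branch_density(y_arbor, "dendrite")


class TestConvexPolygon:
    def test_unit_square(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert convex_polygon_area(pts) == pytest.approx(1.0)

    def test_collinear_points_zero_area(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        assert convex_polygon_area(pts) == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            convex_polygon_area(np.empty((0, 2)))

    @pytest.mark.parametrize("seed,n", [(0, 20), (1, 50), (2, 200)])
    def test_matches_bruteforce_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-100, 100, size=(n, 2))
        assert convex_polygon_area(pts) == pytest.approx(
            hull_area_bruteforce(pts), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_in_plane_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 500, size=(40, 2))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert convex_polygon_area(pts @ rot.T) == pytest.approx(
            convex_polygon_area(pts), rel=1e-6
        )

    def test_monotone_under_added_points(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, size=(10, 2))
        area = convex_polygon_area(pts)
        grown = np.vstack([pts, rng.uniform(-5, 15, size=(5, 2))])
        assert convex_polygon_area(grown) >= area - 1e-12


class TestTerritory:
    def _square_slab_rec(self, x0: float, side: float = 1000.0):
        # a closed square of axon in the section plane at x = x0 + 10
        corners = np.array(
            [
                [x0 + 10, 0, 0],
                [x0 + 10, side, 0],
                [x0 + 10, side, side],
                [x0 + 10, 0, side],
                [x0 + 10, 0, 0],
            ]
        )
        n = len(corners)
        return NeuronReconstruction(
            ids=np.arange(1, n + 1),
            type_codes=[1] + [2] * (n - 1),
            xyz=corners,
            radius=np.ones(n),
            parent_ids=[-1] + list(range(1, n)),
        )

    def test_single_slab_volume(self):
        rec = self._square_slab_rec(0.0)
        d = assign_sections(rec, thickness=300.0)
        # 1000 µm square hull x 300 µm thickness = 0.3 mm³
        assert territory_volume(d) == pytest.approx(0.3)

    def test_two_slabs_add(self):
        a = self._square_slab_rec(0.0)
        d = assign_sections(a, thickness=300.0)
        # duplicate the same square into slab 1
        d.slabs[1] = d.slabs[0].__class__(
            index=1, segments=list(d.slabs[0].segments), excluded=False
        )
        assert territory_volume(d) == pytest.approx(0.6)

    def test_excluded_slab_contributes_zero(self):
        a = self._square_slab_rec(0.0)
        d = assign_sections(a, thickness=300.0)
        d.slabs[1] = d.slabs[0].__class__(
            index=1, segments=list(d.slabs[0].segments), excluded=False
        )
        d.mark_excluded([1])
        assert territory_volume(d) == pytest.approx(0.3)

    def test_arbor_density_arithmetic(self):
        assert arbor_density(100_000.0, 1.0) == pytest.approx(100.0)
        # population means: 310 mm of axon in 1.35 mm³ -> 229.6 mm/mm³
        assert arbor_density(310_000.0, 1.35) == pytest.approx(229.6, abs=0.05)
        with pytest.raises(ValueError):
            arbor_density(1.0, 0.0)

    def test_compact_vs_sprawling_density(self):
        # same cable length, bounding boxes differing 10x in volume ->
        # several-fold difference in arbor density, approaching 10x as the
        # cable saturates both boxes (slab-aligned extents avoid the
        # section-quantization bias of partially spanned slabs)
        small = (600.0, 600.0, 600.0)
        yz = (10 * 600.0**3 / 1200.0) ** 0.5
        big = (1200.0, yz, yz)
        dens = []
        for box in (small, big):
            rec = generate_arbor(
                ArborSimParams(target_length=100_000.0, bounding_box=box, seed=6)
            )
            dens.append(compute_metrics(rec).arbor_density_mm_per_mm3)
        ratio = dens[0] / dens[1]
        assert 3.0 < ratio < 15.0


class TestMediolateral:
    def test_extent_from_slab_span(self, straight_axon):
        # arbor spanning slabs 3..9 -> extent 2.1 mm
        rec = straight_axon(length_um=2000.0, n_nodes=30, axis=0, start=950.0)
        d = assign_sections(rec, axis="x", thickness=300.0)
        ml = mediolateral_summary(d, rec.soma_position())
        assert min(d.slabs) == 3 and max(d.slabs) == 9
        assert ml.extent_mm == pytest.approx(2.1)
        assert ml.interval_mm == (pytest.approx(0.9), pytest.approx(3.0))
        assert ml.soma_position_mm == pytest.approx(0.95)

    def test_single_slab_extent(self, straight_axon):
        rec = straight_axon(length_um=50.0, n_nodes=5, axis=1)  # along y
        d = assign_sections(rec, axis="x", thickness=300.0)
        ml = mediolateral_summary(d, rec.soma_position())
        assert ml.extent_mm == pytest.approx(0.3)

    def test_no_axon_content_errors(self, straight_axon):
        rec = straight_axon()
        d = assign_sections(rec)
        with pytest.raises(ValueError):
            mediolateral_summary(d, rec.soma_position(), type_filter="dendrite")


class TestTopography:
    def test_perfectly_ordered(self):
        somas = np.arange(10.0)
        assert topographic_correlation(somas, somas * 3 + 1) == pytest.approx(1.0)

    def test_reversed(self):
        somas = np.arange(10.0)
        assert topographic_correlation(somas, -somas) == pytest.approx(-1.0)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            topographic_correlation([1, 2, 3], [1, 2])

    def test_null_distribution_centered_on_zero(self):
        rng = np.random.default_rng(0)
        vals = [
            topographic_correlation(rng.normal(size=50), rng.normal(size=50))
            for _ in range(100)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-12
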