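"""Edatopic grids: combination, ellipse assignment, transformation,
point classification and the center-distance diagnostic."""

import itertools

import numpy as np
import pytest

from ecositemap import (
    EcositeEllipse,
    EcositeRectangle,
    EdatopicGrid,
    GridError,
    classify_point,
    combine_ecosites,
    ellipse_assign,
    grid_centers,
    load_default_grid,
    load_grid,
    transform_to_rectangles,
)


class TestCombine:
    def test_acadian_17_originals_combine_to_10(self, acadian_grid):
        combined, relabel = combine_ecosites(
            range(1, 18), acadian_grid.combination_rules
        )
        assert combined == tuple(range(1, 11))
        assert len(relabel) == 17

    def test_maritime_boreal_11_originals_combine_to_10(self, mb_grid):
        combined, relabel = combine_ecosites(range(1, 12), mb_grid.combination_rules)
        assert combined == tuple(range(1, 11))
        assert relabel[8] == 8 and relabel[9] == 8 and relabel[11] == 10

    def test_acadian_4_and_8_merge(self, acadian_grid):
        combined, relabel = combine_ecosites([4, 8], acadian_grid.combination_rules)
        assert combined == (4,)

    def test_identity_rules(self):
        rules = {i: (i, None) for i in range(1, 6)}
        combined, relabel = combine_ecosites(range(1, 6), rules)
        assert combined == (1, 2, 3, 4, 5)
        assert all(relabel[i] == i for i in range(1, 6))

    def test_unmapped_id_rejected(self, acadian_grid):
        with pytest.raises(GridError, match="99"):
            combine_ecosites([1, 99], acadian_grid.combination_rules)


class TestEllipseAssign:
    circles = [
        EcositeEllipse(1, (1.0, 1.0), (1.0, 1.0)),
        EcositeEllipse(2, (2.2, 1.0), (1.0, 1.0)),
    ]

    def test_point_at_center(self):
        assert ellipse_assign(self.circles, 1.0, 1.0) == 1

    def test_outside_all_is_none(self):
        assert ellipse_assign(self.circles, 4.5, 4.5) is None

    def test_overlap_resolved_by_normalized_distance(self):
        # point in both unit circles, nearer to center 1
        assert ellipse_assign(self.circles, 1.5, 1.0) == 1
        assert ellipse_assign(self.circles, 1.8, 1.0) == 2

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(11)
        ellipses = [
            EcositeEllipse(i + 1, tuple(rng.uniform(0.5, 4.5, 2)), tuple(rng.uniform(0.5, 1.5, 2)))
            for i in range(5)
        ]
        for _ in range(200):
            x, y = rng.uniform(0, 5), rng.uniform(0, 7)
            inside = [
                (e.normalized_distance(x, y), e.ecosite_id)
                for e in ellipses
                if e.normalized_distance(x, y) <= 1.0
            ]
            expected = min(inside)[1] if inside else None
            assert ellipse_assign(ellipses, x, y) == expected

    def test_nan_rejected(self):
        with pytest.raises(GridError, match="NaN"):
            ellipse_assign(self.circles, float("nan"), 1.0)


def brute_force_best(own, other, snr_cuts, smr_cuts, fixed, lam, domain):
    """Independent exhaustive search over all lattice rectangles."""
    best_score, best = -np.inf, None
    for xlo, xhi in itertools.combinations(snr_cuts, 2):
        for ylo, yhi in itertools.combinations(smr_cuts, 2):
            rect = EcositeRectangle(0, (xlo, xhi), (ylo, yhi))
            if any(rect.overlaps(f) for f in fixed):
                continue
            score = sum(
                rect.contains(x, y, domain=domain) for x, y in own
            ) - lam * sum(rect.contains(x, y, domain=domain) for x, y in other)
            if score > best_score:
                best_score, best = score, rect
    return best_score, best


class TestTransform:
    domain = ((0.0, 5.0), (0.0, 7.0))

    def test_separated_clusters_fully_captured(self):
        ellipses = [
            EcositeEllipse(1, (1.0, 1.5), (1.0, 1.5)),
            EcositeEllipse(2, (4.0, 5.5), (1.0, 1.5)),
        ]
        rng = np.random.default_rng(0)
        plots = [(x, y, 1) for x, y in rng.uniform((0.5, 0.5), (1.5, 2.5), (20, 2))]
        plots += [(x, y, 2) for x, y in rng.uniform((3.5, 4.5), (4.5, 6.5), (20, 2))]
        rects = transform_to_rectangles(ellipses, plots, 0.25, domain=self.domain)
        by_id = {r.ecosite_id: r for r in rects}
        for x, y, c in plots:
            assert by_id[c].contains(x, y, domain=self.domain)
            other = by_id[3 - c]
            assert not other.contains(x, y, domain=self.domain)

    def test_lambda_zero_single_ecosite_is_outward_rounded_bbox(self):
        ellipses = [EcositeEllipse(1, (2.0, 3.0), (1.0, 1.0))]
        plots = [(1.1, 2.1, 1), (2.9, 3.4, 1), (2.0, 4.1, 1)]
        rects = transform_to_rectangles(
            ellipses, plots, 0.25, lam=0.0, domain=self.domain, expand=False
        )
        (r,) = rects
        assert all(r.contains(x, y, domain=self.domain) for x, y, _ in plots)
        # tie-break picks the smallest such rectangle: the bbox rounded
        # outward to the 0.25 lattice
        assert r.snr_interval == (1.0, 3.0)
        assert r.smr_interval == (2.0, 4.25)

    @pytest.mark.parametrize("trial", range(20))
    def test_greedy_matches_exhaustive_objective_on_small_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_eco = rng.integers(2, 4)
        snr_cuts = np.sort(rng.choice(np.arange(0, 5.25, 0.25), 5, replace=False))
        smr_cuts = np.sort(rng.choice(np.arange(0, 7.25, 0.25), 5, replace=False))
        ellipses = [
            EcositeEllipse(i + 1, (rng.uniform(1, 4), rng.uniform(1, 6)), (1.0, 1.0))
            for i in range(n_eco)
        ]
        n_plots = int(rng.integers(4, 13))
        plots = [
            (rng.uniform(0, 5), rng.uniform(0, 7), int(rng.integers(1, n_eco + 1)))
            for _ in range(n_plots)
        ]
        lam = 1.0
        rects = transform_to_rectangles(
            ellipses, plots, (snr_cuts, smr_cuts), lam=lam,
            domain=self.domain, expand=False,
        )
        # replay the greedy order and compare each chosen rectangle's
        # objective with the brute-force optimum given the fixed prefix
        counts = {e.ecosite_id: sum(1 for *_, c in plots if c == e.ecosite_id)
                  for e in ellipses}
        order = sorted(counts, key=lambda eid: (-counts[eid], eid))
        by_id = {r.ecosite_id: r for r in rects}
        fixed = []
        for eid in order:
            own = [(x, y) for x, y, c in plots if c == eid]
            other = [(x, y) for x, y, c in plots if c != eid]
            best_score, _ = brute_force_best(
                own, other, snr_cuts, smr_cuts, fixed, lam, self.domain
            )
            chosen = by_id[eid]
            if own:
                got = sum(
                    chosen.contains(x, y, domain=self.domain) for x, y in own
                ) - lam * sum(
                    chosen.contains(x, y, domain=self.domain) for x, y in other
                )
                assert got == best_score
            fixed.append(chosen)

    def test_zero_plot_ecosite_seeded_from_ellipse_bbox(self):
        ellipses = [
            EcositeEllipse(1, (1.0, 1.0), (0.6, 0.6)),
            EcositeEllipse(2, (4.0, 6.0), (0.6, 0.6)),
        ]
        plots = [(1.0, 1.0, 1)]
        rects = transform_to_rectangles(
            ellipses, plots, 0.25, domain=self.domain, expand=False
        )
        r2 = next(r for r in rects if r.ecosite_id == 2)
        assert r2.contains(4.0, 6.0, domain=self.domain)

    def test_expansion_partitions_domain(self):
        ellipses = [
            EcositeEllipse(1, (1.0, 1.5), (1.0, 1.5)),
            EcositeEllipse(2, (4.0, 5.5), (1.0, 1.5)),
        ]
        plots = [(1.0, 1.5, 1), (4.0, 5.5, 2)]
        rects = transform_to_rectangles(ellipses, plots, 0.5, domain=self.domain)
        for r1, r2 in itertools.combinations(rects, 2):
            assert not r1.overlaps(r2)
        xs = np.linspace(0, 5, 41)
        ys = np.linspace(0, 7, 57)
        for x in xs:
            for y in ys:
                hits = [r for r in rects if r.contains(x, y, domain=self.domain)]
                assert len(hits) == 1


class TestClassifyPoint:
    def test_published_worked_example(self, acadian_grid):
        assert classify_point(acadian_grid, 0.5, 3.6) == (2, True)
        assert classify_point(acadian_grid, 0.5, 3.4) == (3, True)

    def test_boundary_between_2_and_3_at_smr_3p5(self, acadian_grid):
        eco_above, _ = classify_point(acadian_grid, 0.5, 3.5 + 1e-9)
        eco_below, _ = classify_point(acadian_grid, 0.5, 3.5 - 1e-9)
        assert (eco_above, eco_below) == (2, 3)

    @pytest.mark.parametrize("region", ["acadian", "maritime_boreal"])
    def test_rectangle_centroids_classify_inside(self, region):
        grid = load_default_grid(region)
        for rect in grid.rectangles:
            cx = sum(rect.snr_interval) / 2
            cy = sum(rect.smr_interval) / 2
            assert classify_point(grid, cx, cy) == (rect.ecosite_id, True)

    @pytest.mark.parametrize("region", ["acadian", "maritime_boreal"])
    def test_default_grids_partition_domain(self, region):
        grid = load_default_grid(region)
        xs = np.linspace(0, 5, 51)
        ys = np.linspace(0, 7, 71)
        for x in xs:
            for y in ys:
                hits = [
                    r for r in grid.rectangles if r.contains(x, y, domain=grid.domain)
                ]
                assert len(hits) == 1, (x, y)

    def test_out_of_domain_clamps_to_boundary_behaviour(self, acadian_grid):
        assert classify_point(acadian_grid, -1.0, 8.5) == classify_point(
            acadian_grid, 0.0, 7.0
        )

    def test_nearest_rectangle_fallback(self):
        grid = EdatopicGrid(
            region="toy",
            rectangles=(
                EcositeRectangle(1, (0.0, 1.0), (0.0, 1.0)),
                EcositeRectangle(2, (4.0, 5.0), (6.0, 7.0)),
            ),
        )
        eid, inside = grid.classify(2.0, 1.5)
        assert (eid, inside) == (1, False)

    def test_nan_rejected(self, acadian_grid):
        with pytest.raises(GridError, match="NaN"):
            classify_point(acadian_grid, float("nan"), 3.0)


class TestGridCenters:
    def test_perfect_predictions_have_zero_distance(self, acadian_grid):
        plots = [(0.5, 3.6, 2), (0.5, 3.4, 3), (2.0, 3.0, 5)]
        preds = [(x, y) for x, y, _ in plots]
        centers = grid_centers(acadian_grid, plots, preds)
        assert all(v["distance"] == pytest.approx(0.0) for v in centers.values())

    def test_3_4_5_triangle(self, acadian_grid):
        plots = [(1.0, 1.0, 4)]
        preds = [(1.3, 1.4)]
        centers = grid_centers(acadian_grid, plots, preds)
        assert centers[4]["distance"] == pytest.approx(0.5)

    def test_ecosite_without_plots_omitted(self, acadian_grid):
        centers = grid_centers(acadian_grid, [(0.5, 3.6, 2)], [(0.5, 3.6)])
        assert set(centers) == {2}


class TestGridConfig:
    def test_default_grids_load_with_expected_structure(self, acadian_grid, mb_grid):
        assert len(acadian_grid.rectangles) == 10
        assert len(acadian_grid.ellipses) == 17
        assert len(mb_grid.rectangles) == 10
        assert len(mb_grid.ellipses) == 11

    def test_overlapping_rectangles_rejected(self):
        bad = """
region: toy
domain: {snr: [0, 5], smr: [0, 7]}
rectangles:
  - {id: 1, snr: [0, 3], smr: [0, 3]}
  - {id: 2, snr: [2, 5], smr: [2, 5]}
"""
        with pytest.raises(GridError, match="overlap"):
            load_grid(bad)

    def test_missing_keys_rejected(self):
        with pytest.raises(GridError, match="region"):
            load_grid("domain: {snr: [0, 5], smr: [0, 7]}\nrectangles: []")

    def test_malformed_rectangle_rejected(self):
        bad = """
region: toy
domain: {snr: [0, 5], smr: [0, 7]}
rectangles:
  - {id: 1, snr: [0, 3]}
"""
        with pytest.raises(GridError, match="malformed rectangle"):
            load_grid(bad)
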