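"""Normalization, range clustering, envelope distances and suitability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichebox as nb
from nichebox.envelope import (
    objective_value,
    scopes_from_labels,
    _distances_to_scopes,
)


def brute_force_E(points, labels, k):
    """Independent evaluation of the clustering objective for a partition."""
    total = 0.0
    for i in range(k):
        members = points[labels == i]
        lo, hi = members.min(axis=0), members.max(axis=0)
        for p in members:
            comp = [0.0 if lo[j] <= p[j] <= hi[j]
                    else min(abs(p[j] - lo[j]), abs(p[j] - hi[j]))
                    for j in range(points.shape[1])]
            total += sum(c * c for c in comp)
    return total


def best_two_partition_E(points):
    """Exhaustive minimum of the objective over all 2-partitions."""
    n = points.shape[0]
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        best = min(best, brute_force_E(points, labels, 2))
    return best


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        p = nb.NormalizationParams(("v",), np.array([10.0]), np.array([30.0]))
        assert p.normalize(10.0, "v") == 0.0
        assert p.normalize(30.0, "v") == 100.0
        assert p.normalize(20.0, "v") == 50.0

    def test_out_of_range_extrapolates_not_clips(self):
        p = nb.NormalizationParams(("v",), np.array([0.0]), np.array([10.0]))
        assert p.normalize(-1.0, "v") == -10.0
        assert p.normalize(12.0, "v") == 120.0

    def test_constant_layer_rejected_at_fit_time(self):
        with pytest.raises(ValueError, match="constant"):
            nb.NormalizationParams(("v",), np.array([5.0]), np.array([5.0]))

    def test_fit_uses_layer_valid_cells_not_occurrences(self, scene):
        params = nb.fit_normalization(scene.stack)
        for j, v in enumerate(scene.stack.variables):
            g = scene.stack.grids[v]
            vals = g.data[g.valid_mask()]
            assert params.min_a[j] == vals.min()
            assert params.max_a[j] == vals.max()

    def test_denormalize_inverts(self):
        p = nb.NormalizationParams(("a", "b"), np.array([0.0, -5.0]),
                                   np.array([10.0, 5.0]))
        x = np.array([[3.0, -1.0], [9.9, 4.2]])
        assert np.allclose(p.denormalize(p.normalize(x)), x)


class TestPointDistance:
    def test_inside_scope_is_zero(self):
        assert nb.point_distance([50.0, 50.0], [40.0, 0.0], [60.0, 100.0]) == 0.0

    def test_one_dimensional_gap(self):
        assert nb.point_distance([20.0], [30.0], [70.0]) == 10.0

    def test_euclidean_aggregation(self):
        # gaps (3, 4) across two variables -> 5
        d = nb.point_distance([27.0, 74.0], [30.0, 0.0], [70.0, 70.0])
        assert d == pytest.approx(5.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            nb.point_distance([1.0, 2.0], [0.0], [1.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-200, 300), min_size=1, max_size=6).flatmap(
        lambda p: st.tuples(
            st.just(p),
            st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                     min_size=len(p), max_size=len(p)),
        )))
    def test_matches_scalar_oracle(self, case):
        p, ranges = case
        lo = np.minimum([a for a, _ in ranges], [b for _, b in ranges])
        hi = np.maximum([a for a, _ in ranges], [b for _, b in ranges])
        expect = np.sqrt(sum(
            (0.0 if lo[j] <= v <= hi[j]
             else min(abs(v - lo[j]), abs(v - hi[j]))) ** 2
            for j, v in enumerate(p)))
        assert nb.point_distance(p, lo, hi) == pytest.approx(expect, abs=1e-12)


class TestFitClusters:
    def test_k1_scope_is_global_min_max_and_E_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(30, 4))
        cs = nb.fit_clusters(pts, k=1, seed=0)
        assert np.array_equal(cs.scopes_lo[0], pts.min(axis=0))
        assert np.array_equal(cs.scopes_hi[0], pts.max(axis=0))
        assert cs.objective == 0.0

    def test_k_equals_n_degenerate_scopes(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 0.0]])
        cs = nb.fit_clusters(pts, k=3, seed=1)
        assert np.array_equal(cs.scopes_lo, cs.scopes_hi)
        assert cs.objective == 0.0

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            nb.fit_clusters(np.zeros((2, 2)), k=3)

    def test_two_blobs_partition_matches_enumeration(self):
        pts = np.array([[1.0, 1.0], [2.0, 1.5], [1.5, 2.0], [2.5, 2.5],
                        [80.0, 80.0], [81.0, 82.0], [82.5, 80.5], [83.0, 83.0]])
        cs = nb.fit_clusters(pts, k=2, seed=0, restarts=10)
        # the converged objective equals the enumerated optimum; note that
        # because scopes are recomputed as member min/max, every partition
        # converges to E = 0, so the optimum is attained by construction
        assert cs.objective == pytest.approx(best_two_partition_E(pts), abs=1e-9)
        assert set(cs.labels) == {0, 1}

    def test_reported_E_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            pts = rng.uniform(0, 100, size=(12, 3))
            cs = nb.fit_clusters(pts, k=3, seed=trial)
            assert cs.objective == pytest.approx(
                brute_force_E(pts, cs.labels, 3), abs=1e-9)

    def test_objective_never_increases_between_iterations(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(40, 2))
        cs = nb.fit_clusters(pts, k=4, seed=2, restarts=1)
        diffs = np.diff(cs.history)
        assert (diffs <= 1e-12).all()

    def test_clusters_partition_points(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, size=(25, 3))
        cs = nb.fit_clusters(pts, k=4, seed=0)
        assert sorted(np.concatenate([cs.member_indices(i) for i in range(4)])) \
            == list(range(25))


class TestProfile:
    def test_ranges_are_min_max_in_native_units(self, profile, scene_data):
        clim = scene_data["climates"]
        assert np.array_equal(profile.range_lo, clim.min(axis=0))
        assert np.array_equal(profile.range_hi, clim.max(axis=0))

    def test_single_occurrence_degenerate_profile(self, scene_data):
        params = scene_data["params"]
        clim = scene_data["climates"][:1]
        prof = nb.build_profile(clim, scene_data["soils"][:1], "one", params)
        assert np.array_equal(prof.range_lo, prof.range_hi)
        assert len(prof.soil_classes) == 1

    def test_soil_set_is_distinct_observed_classes(self, profile, scene_data):
        assert profile.soil_classes == frozenset(
            int(s) for s in scene_data["soils"])

    def test_zero_valid_occurrences_rejected(self, scene_data):
        with pytest.raises(ValueError, match="no valid occurrences"):
            nb.build_profile(np.full((3, 6), np.nan), [0, 0, 0], "x",
                             scene_data["params"])

    def test_cluster_scopes_nest_inside_profile_box(self, scene_data):
        prof = nb.build_profile(scene_data["climates"], scene_data["soils"],
                                "v", scene_data["params"], k=3, seed=1)
        lo_n = prof.params.normalize(prof.range_lo)
        hi_n = prof.params.normalize(prof.range_hi)
        assert (prof.clusters.scopes_lo >= lo_n - 1e-9).all()
        assert (prof.clusters.scopes_hi <= hi_n + 1e-9).all()

    def test_json_roundtrip(self, tmp_path, profile):
        p = tmp_path / "prof.json"
        profile.save(p)
        back = nb.EnvelopeProfile.load(p)
        assert back.species == profile.species
        assert np.allclose(back.range_lo, profile.range_lo)
        assert back.soil_classes == profile.soil_classes
        assert np.allclose(back.clusters.scopes_lo, profile.clusters.scopes_lo)


class TestSurfaces:
    def test_distance_zero_iff_inside_some_scope(self, scene, profile, surface):
        dist = surface.distance
        valid = dist.valid_mask()
        cells = scene.stack.cell_matrix(valid)
        norm = profile.params.normalize(cells)
        inside = np.zeros(cells.shape[0], bool)
        for lo, hi in zip(profile.clusters.scopes_lo, profile.clusters.scopes_hi):
            inside |= ((norm >= lo) & (norm <= hi)).all(axis=1)
        assert np.array_equal(dist.data[valid] == 0.0, inside)

    def test_exhaustive_per_cell_oracle_small_grid(self, truth):
        scene = nb.generate_scene(nb.SceneConfig(rows=15, cols=15, seed=2,
                                                 n_occurrences=60), truth)
        params = nb.fit_normalization(scene.stack)
        ext = nb.extract_at_points(scene.stack, scene.occurrences)
        r, c = scene.stack.reference.index_of(
            scene.occurrences["longitude"].to_numpy(),
            scene.occurrences["latitude"].to_numpy())
        soils = scene.soil.data[r, c].astype(int)
        prof = nb.build_profile(ext[list(scene.stack.variables)].to_numpy(),
                                soils, "v", params, k=2, seed=0)
        surf = nb.distance_surface(scene.stack, prof)
        for row in range(15):
            for col in range(15):
                vec = params.normalize(
                    [scene.stack.grids[v].data[row, col]
                     for v in scene.stack.variables])
                expect = min(
                    nb.point_distance(vec, lo, hi)
                    for lo, hi in zip(prof.clusters.scopes_lo,
                                      prof.clusters.scopes_hi))
                assert surf.distance.data[row, col] == pytest.approx(expect)

    def test_distance_invariant_to_cluster_order(self, scene, profile):
        surf = nb.distance_surface(scene.stack, profile)
        flipped = nb.EnvelopeProfile(
            species=profile.species, variables=profile.variables,
            range_lo=profile.range_lo, range_hi=profile.range_hi,
            soil_classes=profile.soil_classes,
            clusters=nb.ClusterSet(
                k=profile.clusters.k,
                labels=profile.clusters.labels,
                scopes_lo=profile.clusters.scopes_lo[::-1].copy(),
                scopes_hi=profile.clusters.scopes_hi[::-1].copy(),
                objective=profile.clusters.objective),
            params=profile.params)
        surf2 = nb.distance_surface(scene.stack, flipped)
        assert np.array_equal(surf.distance.data, surf2.distance.data)

    def test_variable_mismatch_rejected(self, scene, profile):
        sub = nb.VariableStack({"T-aver": scene.stack.grids["T-aver"]})
        with pytest.raises(ValueError, match="mismatch"):
            nb.distance_surface(sub, profile)

    def test_suitability_endpoints_and_soil_rule(self, surface):
        s = surface.suitability.data
        d = surface.distance.data
        valid = surface.distance.valid_mask()
        assert np.all(s[surface.mask] == 0.999)
        # strictly decreasing in distance where soil is allowed
        allowed_pos = valid & (d > 0) & (s > 0)
        if allowed_pos.any():
            order = np.argsort(d[allowed_pos])
            assert (np.diff(s[allowed_pos][order]) <= 1e-12).all()
        # mask is exactly D == 0 and soil allowed and suitability 0.999
        assert np.array_equal(surface.mask, valid & (d == 0) & (s == 0.999))

    def test_soil_disallowed_forces_zero(self, scene, profile):
        surf = nb.distance_surface(scene.stack, profile)
        bad_soil = scene.soil.with_data(np.full(scene.soil.shape, 99.0))
        done = nb.suitability_transform(surf, bad_soil, profile)
        valid = done.distance.valid_mask()
        assert (done.suitability.data[valid] == 0.0).all()
        assert not done.mask.any()

    def test_k1_mask_equals_bioclim_inclusion_oracle(self, scene, profile, surface):
        """With one cluster the mask must match the classic rectangular-
        envelope test: every variable within the occurrence min/max."""
        inside = np.ones(scene.soil.shape, bool)
        for j, v in enumerate(scene.stack.variables):
            g = scene.stack.grids[v].data
            inside &= (g >= profile.range_lo[j]) & (g <= profile.range_hi[j])
        soil_ok = np.isin(scene.soil.data.astype(int),
                          sorted(profile.soil_classes))
        assert np.array_equal(surface.mask, inside & soil_ok)

    def test_mask_covers_occurrences_and_stays_inside_truth(
            self, scene, surface):
        r, c = scene.stack.reference.index_of(
            scene.occurrences["longitude"].to_numpy(),
            scene.occurrences["latitude"].to_numpy())
        assert surface.mask[r, c].all()
        assert not (surface.mask & ~scene.true_mask()).any()

    def test_envelope_recovery_gap_shrinks_with_n(self, truth):
        gaps = []
        for n in (20, 600):
            sc = nb.generate_scene(
                nb.SceneConfig(seed=31, n_occurrences=n), truth)
            params = nb.fit_normalization(sc.stack)
            ext = nb.extract_at_points(sc.stack, sc.occurrences)
            clim = ext[list(sc.stack.variables)].to_numpy()
            prof = nb.build_profile(clim, np.zeros(n), "v", params)
            cells = sc.stack.cell_matrix(np.ones(sc.soil.shape, bool))
            true_cells = sc.truth.climate_inside(cells, sc.stack.variables).sum()
            inside = np.ones(sc.soil.shape, bool)
            for j, v in enumerate(sc.stack.variables):
                g = sc.stack.grids[v].data
                inside &= (g >= prof.range_lo[j]) & (g <= prof.range_hi[j])
            fit_cells = inside.sum()
            gaps.append(true_cells - fit_cells)
        assert gaps[1] <= gaps[0]
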