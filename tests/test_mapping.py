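"""Vertex-wise maps, cluster-extent correction, conjunction, concordance."""

import numpy as np
import pytest

import twinmap as tm
from twinmap.mapping import VertexMap
from twinmap.mesh import relabel_mesh


def _manual_map(n, sig_vertices, stat_sign=None, p_sig=0.01, p_null=0.8):
    """VertexMap with chosen significant vertices (both components equal)."""
    p = np.full(n, p_null)
    p[list(sig_vertices)] = p_sig
    stat = np.full(n, 0.1)
    if stat_sign is not None:
        stat = np.asarray(stat_sign, dtype=float)
    return VertexMap(stat, stat.copy(), p, p.copy(), np.ones(n, dtype=bool))


class TestExtractClusters:
    def test_nothing_significant_gives_empty_table(self, grid_mesh):
        vmap = _manual_map(grid_mesh.n_vertices, [])
        table = tm.extract_clusters(vmap, grid_mesh)
        assert len(table) == 0
        assert table.to_frame().shape[0] == 0

    def test_patches_joined_by_nonsignificant_vertex_stay_separate(self):
        mesh = tm.make_mesh("grid", n_vertices=100, scale_mm=10.0)
        # two runs in grid row 0 separated by vertex 4 (non-significant)
        vmap = _manual_map(100, [0, 1, 2, 3, 5, 6, 7, 8])
        table = tm.extract_clusters(vmap, mesh, extent_threshold_mm=20.0)
        assert len(table) == 2
        sets = sorted(tuple(c.vertices) for c in table.clusters)
        assert sets == [(0, 1, 2, 3), (5, 6, 7, 8)]

    def test_extent_threshold_discards_small_components(self):
        mesh = tm.make_mesh("grid", n_vertices=100, scale_mm=10.0)
        vmap = _manual_map(100, [0, 1])  # extent 10 mm < 20 mm
        assert len(tm.extract_clusters(vmap, mesh, extent_threshold_mm=20.0)) == 0
        assert len(tm.extract_clusters(vmap, mesh, extent_threshold_mm=10.0)) == 1

    def test_sign_split_before_extent(self):
        mesh = tm.make_mesh("grid", n_vertices=100, scale_mm=10.0)
        stat = np.full(100, 1.0)
        stat[[5, 6, 7, 8]] = -1.0
        vmap = _manual_map(100, [0, 1, 2, 3, 4, 5, 6, 7, 8], stat_sign=stat)
        table = tm.extract_clusters(vmap, mesh, extent_threshold_mm=20.0)
        signs = sorted(c.sign for c in table.clusters)
        assert signs == ["negative", "positive"]

    def test_area_mode(self):
        mesh = tm.make_mesh("grid", n_vertices=100, scale_mm=10.0)
        vmap = _manual_map(100, [44, 45, 54, 55])
        by_area = tm.extract_clusters(vmap, mesh, extent_threshold_mm=150.0,
                                      extent_mode="area")
        assert len(by_area) == 1  # 4 interior vertices ~ 400 mm^2

    def test_lower_alpha_never_adds_vertices(self, grid_mesh):
        rng = np.random.default_rng(3)
        p = rng.random(grid_mesh.n_vertices)
        vmap = VertexMap(np.ones_like(p), np.ones_like(p), p, p.copy(),
                         np.ones_like(p, dtype=bool))
        counts = []
        for alpha in (0.2, 0.1, 0.05, 0.01):
            t = tm.extract_clusters(vmap, grid_mesh, alpha=alpha,
                                    extent_threshold_mm=0.0)
            counts.append(sum(c.n_vertices for c in t.clusters))
        assert counts == sorted(counts, reverse=True)

    def test_invariant_to_vertex_relabeling(self, grid_mesh):
        rng = np.random.default_rng(7)
        perm = rng.permutation(grid_mesh.n_vertices)
        vmap = _manual_map(grid_mesh.n_vertices, [0, 1, 2, 3, 10, 11, 12, 13])
        base = tm.extract_clusters(vmap, grid_mesh, extent_threshold_mm=10.0)
        # rebuild fields under the permutation: new_index = perm[old_index]
        inv = np.argsort(perm)
        relabeled_map = VertexMap(
            vmap.bivariate_heritability[inv], vmap.bivariate_environmentality[inv],
            vmap.p_genetic[inv], vmap.p_environmental[inv], vmap.valid[inv])
        other = tm.extract_clusters(relabeled_map, relabel_mesh(grid_mesh, perm),
                                    extent_threshold_mm=10.0)
        base_sets = sorted(tuple(sorted(perm[c.vertices])) for c in base.clusters)
        other_sets = sorted(tuple(sorted(c.vertices)) for c in other.clusters)
        assert base_sets == other_sets


class TestClusterCog:
    def test_single_vertex(self, grid_mesh):
        assert np.allclose(tm.cluster_cog([7], grid_mesh),
                           grid_mesh.vertex_coords[7])

    def test_midpoint(self):
        mesh = tm.SurfaceMesh(np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 1, 0]]),
                              np.array([[0, 1, 2]]))
        assert np.allclose(tm.cluster_cog([0, 1], mesh), [1.0, 0.0, 0.0])

    def test_patch_cog_near_center(self, sphere_mesh):
        ball = sphere_mesh.geodesic_ball(10, 15.0)
        cog = tm.cluster_cog(ball, sphere_mesh)
        center = sphere_mesh.vertex_coords[10]
        # COG of a spherical cap sits slightly inside the sphere
        assert np.linalg.norm(cog - center) < 5.0


class TestConjunction:
    def _table(self, mesh, vertex_sets, signs=None):
        vmap = _manual_map(mesh.n_vertices,
                           [v for s in vertex_sets for v in s])
        if signs:
            stat = np.full(mesh.n_vertices, 1.0)
            for s, sg in zip(vertex_sets, signs):
                stat[list(s)] = sg
            vmap = _manual_map(mesh.n_vertices,
                               [v for s in vertex_sets for v in s], stat_sign=stat)
        return tm.extract_clusters(vmap, mesh, extent_threshold_mm=0.0)

    def test_disjoint_sets_give_empty_overlay(self, grid_mesh):
        ta = self._table(grid_mesh, [[0, 1, 2]])
        tb = self._table(grid_mesh, [[50, 51, 52]])
        assert len(tm.conjunction_overlay(ta, tb, grid_mesh)) == 0

    def test_identical_sets_are_idempotent(self, grid_mesh):
        ta = self._table(grid_mesh, [[0, 1, 2, 10, 11]])
        overlay = tm.conjunction_overlay(ta, ta, grid_mesh)
        assert sorted(overlay.clusters[0].vertices) == [0, 1, 2, 10, 11]

    def test_planted_overlap_recovered_exactly(self):
        mesh = tm.make_mesh("grid", n_vertices=400, scale_mm=5.0)
        set_a = set(range(40, 70))
        set_b = set(range(45, 90))
        ta = self._table(mesh, [sorted(set_a)])
        tb = self._table(mesh, [sorted(set_b)])
        overlay = tm.conjunction_overlay(ta, tb, mesh)
        got = set(int(v) for c in overlay.clusters for v in c.vertices)
        assert got == (set_a & set_b)

    def test_discordant_signs_flagged(self, grid_mesh):
        ta = self._table(grid_mesh, [[0, 1, 2]], signs=[1.0])
        tb = self._table(grid_mesh, [[0, 1, 2]], signs=[-1.0])
        overlay = tm.conjunction_overlay(ta, tb, grid_mesh)
        assert len(overlay) == 1 and overlay.clusters[0].discordant

    def test_mesh_mismatch_rejected(self, grid_mesh, sphere_mesh):
        ta = self._table(grid_mesh, [[0, 1]])
        tb = self._table(grid_mesh, [[0, 1]])
        with pytest.raises(ValueError):
            tm.conjunction_overlay(ta, tb, sphere_mesh)


class TestSignConcordance:
    def test_identical_maps_fully_concordant(self, grid_mesh):
        vmap = _manual_map(grid_mesh.n_vertices, [0, 1, 2, 3])
        table = tm.extract_clusters(vmap, grid_mesh, extent_threshold_mm=0.0)
        rep = tm.sign_concordance(vmap, vmap, table)
        assert (rep["concordance"] == 1.0).all()
        assert rep["same_direction"].all()

    def test_negated_maps_discordant(self, grid_mesh):
        vmap = _manual_map(grid_mesh.n_vertices, [0, 1, 2, 3])
        table = tm.extract_clusters(vmap, grid_mesh, extent_threshold_mm=0.0)
        neg = VertexMap(vmap.bivariate_heritability,
                        -vmap.bivariate_environmentality,
                        vmap.p_genetic, vmap.p_environmental, vmap.valid)
        rep = tm.sign_concordance(vmap, neg, table)
        assert (rep["concordance"] == 0.0).all()

    def test_random_signs_near_half(self):
        mesh = tm.make_mesh("grid", n_vertices=2500, scale_mm=1.0)
        rng = np.random.default_rng(0)
        verts = list(range(mesh.n_vertices))
        vmap = _manual_map(mesh.n_vertices, verts)
        rand = VertexMap(vmap.bivariate_heritability,
                         rng.choice([-1.0, 1.0], mesh.n_vertices),
                         vmap.p_genetic, vmap.p_environmental, vmap.valid)
        table = tm.extract_clusters(vmap, mesh, extent_threshold_mm=0.0)
        rep = tm.sign_concordance(vmap, rand, table)
        assert rep["concordance"].iloc[0] == pytest.approx(0.5, abs=0.05)


class TestFitVertexwise:
    def test_self_association_recovers_trait_heritability(self, reported_paths):
        A, E = reported_paths
        co = tm.simulate_bivariate_cohort(A[:1, :1], E[:1, :1],
                                          n_mz=800, n_dz=800, seed=9)
        beh = co.values[:, :, 0]
        rng = np.random.default_rng(9)
        indep = rng.standard_normal(beh.shape)
        thickness = np.stack([beh, indep], axis=2)
        vmap = tm.fit_vertexwise(thickness, beh, co.zygosity, seed=0)
        # vertex 0 IS the trait: genetic covariance = genetic variance
        assert vmap.valid[0]
        assert vmap.p_genetic[0] < 1e-6
        assert vmap.bivariate_heritability[0] == pytest.approx(0.45, abs=0.07)
        # vertex 1 is unrelated noise
        assert vmap.p_genetic[1] > 1e-4 or abs(vmap.bivariate_heritability[1]) < 0.1

    def test_planted_cluster_has_lower_p_than_null_vertices(self):
        mesh = tm.make_mesh("grid", n_vertices=64, scale_mm=8.0)
        truth = tm.planted_cluster_truth(mesh, [27], radius_mm=12.0,
                                         cross_path=0.35)
        cohort, thickness, truth = tm.simulate_twin_cohort(
            mesh, truth, n_mz=250, n_dz=250, seed=21)
        vmap = tm.fit_vertexwise(thickness, cohort.values[:, :, 0],
                                 cohort.zygosity, seed=0,
                                 components=("genetic",))
        inside = truth.cluster_vertices[0]
        outside = np.setdiff1d(np.arange(64), inside)
        assert np.median(vmap.p_genetic[inside]) < np.median(vmap.p_genetic[outside])

    def test_constant_vertex_marked_invalid(self):
        rng = np.random.default_rng(0)
        n = 60
        beh = rng.standard_normal((n, 2))
        thickness = np.stack([np.ones((n, 2)), rng.standard_normal((n, 2))], axis=2)
        zyg = np.array(["MZ"] * 30 + ["DZ"] * 30, dtype=object)
        vmap = tm.fit_vertexwise(thickness, beh, zyg, seed=0,
                                 components=("genetic",))
        assert not vmap.valid[0]
        assert np.isnan(vmap.bivariate_heritability[0])
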