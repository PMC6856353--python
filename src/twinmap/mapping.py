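"""Vertex-wise genetic/environmental association maps and cluster extraction.

At every vertex a bivariate Cholesky model is fitted with the vertex's
(residualized) thickness as the first variable and the behavioral score as
the second.  Shared environment is allowed on the vertex only: the C cross
path and the behavioral C loading are fixed at zero (behavioral traits showed
no C).  The signed bivariate heritability (standardized a11 * a21) and the
chi-square difference test of the genetic cross path give the genetic map;
the analogous E quantities give the environmental map.

Significant vertices (p < alpha) are partitioned into sign-homogeneous
connected components on the mesh and filtered by spatial extent
(cluster-extent correction, default 20 mm geodesic diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy import sparse
from sklearn.base import clone

from .cholesky import CholeskyTwinModel, ConvergenceError, lr_test, pattern_statistics
from .mesh import SurfaceMesh, component_extent_mm


def vertexwise_spec(**kwargs) -> CholeskyTwinModel:
    """The per-vertex bivariate model: A and E fully free, C free on the
    vertex only (c21 = c22 = 0)."""
    free_c = np.array([[True, False], [False, False]])
    return CholeskyTwinModel(components="ACE", free_c=free_c, **kwargs)


@dataclass
class VertexMap:
    """Per-vertex association statistics over a mesh."""

    bivariate_heritability: np.ndarray
    bivariate_environmentality: np.ndarray
    p_genetic: np.ndarray
    p_environmental: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bivariate_heritability)
        for name in ("bivariate_environmentality", "p_genetic",
                     "p_environmental", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("vertex map fields must share one length")
        for p in (self.p_genetic, self.p_environmental):
            ok = self.valid & np.isfinite(p)
            if np.any((p[ok] < 0) | (p[ok] > 1)):
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.bivariate_heritability)

    def field_for(self, component: str):
        if component == "genetic":
            return self.bivariate_heritability, self.p_genetic
        if component == "environmental":
            return self.bivariate_environmentality, self.p_environmental
        raise ValueError("component must be 'genetic' or 'environmental'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex": np.arange(self.n_vertices),
            "bivariate_heritability": self.bivariate_heritability,
            "bivariate_environmentality": self.bivariate_environmentality,
            "p_genetic": self.p_genetic,
            "p_environmental": self.p_environmental,
            "valid": self.valid,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VertexMap":
        return cls(
            df["bivariate_heritability"].to_numpy(float),
            df["bivariate_environmentality"].to_numpy(float),
            df["p_genetic"].to_numpy(float),
            df["p_environmental"].to_numpy(float),
            df["valid"].to_numpy(bool),
        )


def _pack_start(model: CholeskyTwinModel, masks) -> np.ndarray:
    mats = (model.a_, model._c_mat, model.e_)
    return np.concatenate([M[m] for M, m in zip(mats, masks)] + [model.means_])


def fit_vertexwise(thickness: np.ndarray, behavior: np.ndarray,
                   zygosity: np.ndarray, spec: CholeskyTwinModel | None = None,
                   seed=None, n_starts: int = 1,
                   components=("genetic", "environmental")) -> VertexMap:
    """Fit the bivariate model at every vertex and assemble a VertexMap.

    Parameters
    ----------
    thickness : (n_pairs, 2, n_vertices) residualized thickness, NaN missing.
    behavior : (n_pairs, 2) residualized behavioral score.
    zygosity : (n_pairs,) "MZ"/"DZ" labels.
    spec : unfitted model carrying the free/fixed pattern (default: the
        C-constrained bivariate model from :func:`vertexwise_spec`).
    n_starts : optimizer starts per vertex (1 = moment start only; the
        reduced fits warm-start from the full fit).

    Vertices where any fit fails, or with (near) zero variance, are flagged
    invalid rather than silently set to zero.
    """
    thickness = np.asarray(thickness, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n_pairs, _, n_vertices = thickness.shape
    if behavior.shape != (n_pairs, 2):
        raise ValueError("behavior must be (n_pairs, 2)")
    spec = spec if spec is not None else vertexwise_spec()
    spec = clone(spec)
    spec.set_params(n_starts=n_starts, random_state=seed)

    masks_full = spec._masks(2)
    # reduced specs: genetic cross path a21 = 0; environmental cross e21 = 0
    red_a = clone(spec)
    fa = masks_full[0].copy(); fa[1, 0] = False
    red_a.set_params(free_a=fa)
    red_e = clone(spec)
    fe = masks_full[2].copy(); fe[1, 0] = False
    red_e.set_params(free_e=fe)
    masks_ra = (fa, masks_full[1], masks_full[2])
    masks_re = (masks_full[0], masks_full[1], fe)

    bivh = np.full(n_vertices, np.nan)
    bive = np.full(n_vertices, np.nan)
    p_g = np.full(n_vertices, np.nan)
    p_e = np.full(n_vertices, np.nan)
    valid = np.zeros(n_vertices, dtype=bool)

    do_g = "genetic" in components
    do_e = "environmental" in components

    for v in range(n_vertices):
        X = np.column_stack([thickness[:, 0, v], behavior[:, 0],
                             thickness[:, 1, v], behavior[:, 1]])
        col = np.concatenate([X[:, 0], X[:, 2]])
        if np.nanvar(col) < 1e-12:
            continue
        try:
            full = clone(spec).fit(X, zygosity)
            if not full.converged_:
                continue
            stats_list = full._stats
            if do_g:
                x0 = _pack_start(full, masks_ra)
                ra = clone(red_a)
                ra.set_params(n_starts=n_starts, random_state=seed)
                ra._fit_from_stats(stats_list, 2, X=X, zygosity=zygosity, x0=x0)
                p_g[v] = lr_test(full, ra)[2]
            if do_e:
                x0 = _pack_start(full, masks_re)
                re_ = clone(red_e)
                re_.set_params(n_starts=n_starts, random_state=seed)
                re_._fit_from_stats(stats_list, 2, X=X, zygosity=zygosity, x0=x0)
                p_e[v] = lr_test(full, re_)[2]
        except (ConvergenceError, ValueError):
            continue
        bivh[v] = full.bivariate_heritability_
        bive[v] = full.bivariate_environmentality_
        valid[v] = True
    return VertexMap(bivh, bive, p_g, p_e, valid)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A sign-homogeneous, mesh-contiguous set of significant vertices."""

    vertices: np.ndarray
    sign: str                       # "positive" | "negative"
    cog_xyz: np.ndarray
    n_vertices: int
    extent_mm: float
    replicated: bool | None = None
    discordant: bool = False

    def vertex_set(self) -> set[int]:
        return set(int(v) for v in self.vertices)


@dataclass
class ClusterTable:
    """Clusters for one trait/component, pairwise disjoint."""

    clusters: list[Cluster] = field(default_factory=list)
    trait: str = ""
    component: str = "A"
    n_mesh_vertices: int | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            s = c.vertex_set()
            if seen & s:
                raise ValueError("clusters must be pairwise disjoint")
            seen |= s

    def __len__(self) -> int:
        return len(self.clusters)

    def union_vertices(self) -> np.ndarray:
        if not self.clusters:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([c.vertices for c in self.clusters]))

    def sign_lookup(self) -> dict[int, str]:
        return {int(v): c.sign for c in self.clusters for v in c.vertices}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters, start=1):
            rows.append({
                "Cluster": i,
                "COG X": c.cog_xyz[0], "COG Y": c.cog_xyz[1],
                "COG Z": c.cog_xyz[2],
                "Number of vertices": c.n_vertices,
                "sign": c.sign,
                "replicated": c.replicated,
            })
        return pd.DataFrame(
            rows, columns=["Cluster", "COG X", "COG Y", "COG Z",
                           "Number of vertices", "sign", "replicated"],
        )


def cluster_cog(vertices, mesh: SurfaceMesh) -> np.ndarray:
    """Center of gravity: unweighted mean coordinate of the member vertices."""
    vertices = np.atleast_1d(np.asarray(vertices))
    if vertices.size == 0:
        raise ValueError("cluster has no vertices")
    return mesh.vertex_coords[vertices].mean(axis=0)


def _components_of(vertex_ids: np.ndarray, adjacency) -> list[np.ndarray]:
    if vertex_ids.size == 0:
        return []
    sub = adjacency[vertex_ids][:, vertex_ids]
    ncomp, labels = connected_components(sub, directed=False)
    return [vertex_ids[labels == k] for k in range(ncomp)]


def extract_clusters(vmap: VertexMap, mesh: SurfaceMesh, alpha: float = 0.05,
                     extent_threshold_mm: float = 20.0,
                     component: str = "genetic", trait: str = "",
                     extent_mode: str = "diameter") -> ClusterTable:
    """Cluster-extent-corrected significant clusters of a vertex map.

    Vertices with ``p < alpha`` are split by the sign of the association,
    partitioned into mesh-connected components, and components whose spatial
    extent falls below ``extent_threshold_mm`` are discarded.  Extent is the
    geodesic diameter in mm (``extent_mode="diameter"``) or total vertex
    surface area in mm^2 (``extent_mode="area"``).
    """
    if vmap.n_vertices != mesh.n_vertices:
        raise ValueError("map and mesh vertex counts differ")
    stat, p = vmap.field_for(component)
    adjacency = mesh.adjacency()
    areas = mesh.vertex_areas() if extent_mode == "area" else None
    if extent_mode not in ("diameter", "area"):
        raise ValueError("extent_mode must be 'diameter' or 'area'")
    sig = vmap.valid & np.isfinite(p) & (p < alpha)
    clusters: list[Cluster] = []
    for sign_label, mask in (("positive", sig & (stat > 0)),
                             ("negative", sig & (stat <= 0))):
        for comp_vertices in _components_of(np.flatnonzero(mask), adjacency):
            if extent_mode == "diameter":
                extent = component_extent_mm(mesh, comp_vertices, adjacency)
            else:
                extent = float(areas[comp_vertices].sum())
            if extent < extent_threshold_mm:
                continue
            clusters.append(Cluster(
                vertices=np.sort(comp_vertices), sign=sign_label,
                cog_xyz=cluster_cog(comp_vertices, mesh),
                n_vertices=int(comp_vertices.size), extent_mm=extent,
            ))
    comp_label = "A" if component == "genetic" else "E"
    return ClusterTable(clusters, trait=trait, component=comp_label,
                        n_mesh_vertices=mesh.n_vertices)


def conjunction_overlay(clusters_a: ClusterTable, clusters_b: ClusterTable,
                        mesh: SurfaceMesh) -> ClusterTable:
    """Conjunction of two traits' surviving clusters.

    The vertex-level intersection of the two tables' cluster unions is
    re-partitioned into mesh-connected components.  Components where the two
    traits' association signs disagree are reported separately and flagged
    ``discordant``.
    """
    for t in (clusters_a, clusters_b):
        if t.n_mesh_vertices is not None and t.n_mesh_vertices != mesh.n_vertices:
            raise ValueError("cluster table does not match the mesh")
    inter = np.intersect1d(clusters_a.union_vertices(),
                           clusters_b.union_vertices())
    sign_a = clusters_a.sign_lookup()
    sign_b = clusters_b.sign_lookup()
    adjacency = mesh.adjacency()
    out: list[Cluster] = []
    concord = np.array([v for v in inter if sign_a[v] == sign_b[v]], dtype=int)
    discord = np.setdiff1d(inter, concord)
    for verts, disc in ((concord, False), (discord, True)):
        for sign_label in ("positive", "negative"):
            src = sign_a
            sel = np.array([v for v in verts if src[v] == sign_label], dtype=int)
            for comp_vertices in _components_of(sel, adjacency):
                out.append(Cluster(
                    vertices=np.sort(comp_vertices), sign=sign_label,
                    cog_xyz=cluster_cog(comp_vertices, mesh),
                    n_vertices=int(comp_vertices.size),
                    extent_mm=component_extent_mm(mesh, comp_vertices, adjacency),
                    discordant=disc,
                ))
    trait = f"{clusters_a.trait}&{clusters_b.trait}"
    return ClusterTable(out, trait=trait, component=clusters_a.component,
                        n_mesh_vertices=mesh.n_vertices)


def sign_concordance(genetic: VertexMap, environmental: VertexMap,
                     clusters: ClusterTable, threshold: float = 0.5) -> pd.DataFrame:
    """Per-cluster agreement between genetic and environmental directions.

    Same-direction genetic and environmental association is consistent with
    (though not sufficient for) a causal brain-behavior interpretation.
    Returns one row per cluster with the fraction of member vertices whose
    two signs agree and a same-direction verdict at ``threshold``.
    """
    if genetic.n_vertices != environmental.n_vertices:
        raise ValueError("maps have different vertex counts")
    rows = []
    g = genetic.bivariate_heritability
    e = environmental.bivariate_environmentality
    for i, c in enumerate(clusters.clusters, start=1):
        v = c.vertices
        agree = np.sign(g[v]) == np.sign(e[v])
        frac = float(np.mean(agree)) if v.size else float("nan")
        rows.append({"Cluster": i, "concordance": frac,
                     "same_direction": bool(frac >= threshold)})
    return pd.DataFrame(rows, columns=["Cluster", "concordance", "same_direction"])
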