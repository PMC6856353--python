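"""Synthetic twin cohorts, surface meshes and expression matrices with known
ground truth.

The generative model mirrors the fitted one: latent additive-genetic factors
correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins, shared
environment is identical within a family, non-shared environment is
independent, and phenotypes are assembled through lower-triangular Cholesky
paths.  Singletons arise by deleting a co-twin completely at random, matching
the missing-at-random assumption under which FIML is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .cohort import TwinCohort
from .expression import ExpressionMatrix
from .mesh import SurfaceMesh

_ICO_COUNTS = [12, 42, 162, 642, 2562, 10242, 40962]


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def make_mesh(kind: str = "sphere", n_vertices: int = 642,
              scale_mm: float = 50.0, seed=None) -> SurfaceMesh:
    """Synthetic triangulated surface in mm coordinates.

    ``kind="sphere"`` subdivides an icosahedron to the smallest level with at
    least ``n_vertices`` vertices (counts 12, 42, 162, 642, 2562, ...), with
    radius ``scale_mm``.  ``kind="grid"`` builds a regular k x k planar
    triangulation with k = round(sqrt(n_vertices)) and ``scale_mm`` spacing.
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    if n_vertices < 4:
        raise ValueError("need at least 4 vertices")
    if kind == "sphere":
        level = next(i for i, c in enumerate(_ICO_COUNTS) if c >= n_vertices)
        tm = trimesh.creation.icosphere(subdivisions=level, radius=scale_mm)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "lh")
    if kind == "grid":
        k = int(round(np.sqrt(n_vertices)))
        xs, ys = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        coords = np.column_stack([
            xs.ravel() * scale_mm, ys.ravel() * scale_mm, np.zeros(k * k)
        ])
        tris = []
        for i in range(k - 1):
            for j in range(k - 1):
                a = i * k + j
                tris.append([a, a + 1, a + k])
                tris.append([a + 1, a + k + 1, a + k])
        return SurfaceMesh(coords, np.asarray(tris), "lh")
    raise ValueError("kind must be 'sphere' or 'grid'")


# ---------------------------------------------------------------------------
# twin cohorts
# ---------------------------------------------------------------------------

def _latent_a(rng, n: int, is_mz: np.ndarray, extra: tuple = ()) -> np.ndarray:
    """Additive-genetic latents, shape (n, 2, *extra): co-twin correlation 1
    for MZ pairs and 0.5 for DZ pairs."""
    fam = rng.standard_normal((n, 1) + extra)
    ind = rng.standard_normal((n, 2) + extra)
    out = np.empty((n, 2) + extra)
    mz = is_mz[(slice(None), None) + (None,) * len(extra)]
    out[:] = np.where(mz, fam, np.sqrt(0.5) * fam + np.sqrt(0.5) * ind)
    return out


def simulate_bivariate_cohort(a_paths, e_paths, c_paths=None, means=None,
                              n_mz: int = 120, n_dz: int = 115,
                              singleton_fraction: float = 0.0,
                              seed=None, variable_names=None) -> TwinCohort:
    """Twin cohort drawn from an explicit p-variate Cholesky ACE/AE model.

    Path matrices are lower triangular (p x p); ``c_paths=None`` gives an AE
    model.  Reproducible given ``seed``.
    """
    A = np.atleast_2d(np.asarray(a_paths, dtype=float))
    E = np.atleast_2d(np.asarray(e_paths, dtype=float))
    C = np.zeros_like(A) if c_paths is None else np.atleast_2d(np.asarray(c_paths, float))
    p = A.shape[0]
    if A.shape != (p, p) or E.shape != (p, p) or C.shape != (p, p):
        raise ValueError("path matrices must be square and equally sized")
    mu = np.zeros(p) if means is None else np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    n = n_mz + n_dz
    is_mz = np.zeros(n, dtype=bool)
    is_mz[:n_mz] = True

    za = _latent_a(rng, n, is_mz, (p,))
    zc = np.repeat(rng.standard_normal((n, 1, p)), 2, axis=1)
    ze = rng.standard_normal((n, 2, p))
    values = mu + za @ A.T + zc @ C.T + ze @ E.T

    if singleton_fraction > 0:
        drop = rng.random(n) < singleton_fraction
        which = rng.integers(0, 2, size=n)
        values[drop, which[drop], :] = np.nan
    zyg = np.where(is_mz, "MZ", "DZ").astype(object)
    return TwinCohort(values, zyg, list(variable_names or []),
                      np.arange(n))


@dataclass
class VertexTruth:
    """Generating per-vertex paths for a simulated thickness + behavior set."""

    vertex_a: np.ndarray          # additive genetic loading per vertex
    vertex_c: np.ndarray          # shared environment loading per vertex
    vertex_e: np.ndarray          # non-shared environment loading per vertex
    cross_path: np.ndarray        # loading of the behavior's genetic factor
    behavior_a: float
    behavior_e: float
    cluster_vertices: list[np.ndarray] = field(default_factory=list)


def planted_cluster_truth(mesh: SurfaceMesh, centers, radius_mm: float,
                          cross_path: float = 0.3, vertex_a: float = 0.6,
                          vertex_c: float = 0.3, behavior_h2: float = 0.45,
                          ) -> VertexTruth:
    """Truth record with genetic brain-behavior covariance planted in geodesic
    patches of radius ``radius_mm`` around ``centers`` and null elsewhere.
    Vertex total variance is kept at 1 by absorbing the planted cross path
    into the residual E loading."""
    V = mesh.n_vertices
    w = np.zeros(V)
    clusters = []
    for c in np.atleast_1d(centers):
        ball = mesh.geodesic_ball(int(c), radius_mm)
        clusters.append(ball)
        w[ball] = cross_path
    a = np.full(V, vertex_a)
    cc = np.full(V, vertex_c)
    e2 = 1.0 - a ** 2 - cc ** 2 - w ** 2
    if np.any(e2 <= 0):
        raise ValueError("paths imply non-positive residual vertex variance")
    return VertexTruth(a, cc, np.sqrt(e2), w,
                       float(np.sqrt(behavior_h2)), float(np.sqrt(1 - behavior_h2)),
                       clusters)


def simulate_twin_cohort(mesh: SurfaceMesh, truth: VertexTruth,
                         n_mz: int = 120, n_dz: int = 115,
                         singleton_fraction: float = 0.0, seed=None):
    """Simulate thickness (per vertex) and one behavioral trait for a cohort.

    The behavioral trait is AE; each vertex carries its own A/C/E loadings
    plus a cross loading on the behavior's genetic factor (nonzero inside
    planted clusters), so the vertex-behavior covariance is purely genetic.

    Returns ``(cohort, thickness, truth)``: a behavioral :class:`TwinCohort`
    (one variable), a ``(n_pairs, 2, n_vertices)`` thickness array, and the
    truth record.  Bit-reproducible given ``seed``.
    """
    V = mesh.n_vertices
    for arr in (truth.vertex_a, truth.vertex_c, truth.vertex_e, truth.cross_path):
        if np.asarray(arr).shape != (V,):
            raise ValueError("truth arrays must have one entry per vertex")
    rng = np.random.default_rng(seed)
    n = n_mz + n_dz
    is_mz = np.zeros(n, dtype=bool)
    is_mz[:n_mz] = True

    g_beh = _latent_a(rng, n, is_mz)                     # (n, 2)
    e_beh = rng.standard_normal((n, 2))
    behavior = truth.behavior_a * g_beh + truth.behavior_e * e_beh

    g_v = _latent_a(rng, n, is_mz, (V,))                 # (n, 2, V)
    c_v = np.repeat(rng.standard_normal((n, 1, V)), 2, axis=1)
    e_v = rng.standard_normal((n, 2, V))
    thickness = (truth.vertex_a * g_v + truth.vertex_c * c_v
                 + truth.vertex_e * e_v
                 + truth.cross_path * g_beh[:, :, None])

    if singleton_fraction > 0:
        drop = rng.random(n) < singleton_fraction
        which = rng.integers(0, 2, size=n)
        behavior[drop, which[drop]] = np.nan
        thickness[drop, which[drop], :] = np.nan

    zyg = np.where(is_mz, "MZ", "DZ").astype(object)
    cohort = TwinCohort(behavior[:, :, None], zyg, ["behavior"], np.arange(n))
    return cohort, thickness, truth


def correlated_ae_paths(rg: float = 0.40, re: float = 0.04,
                        h2_1: float = 0.45, h2_2: float = 0.45):
    """Bivariate AE Cholesky paths with unit trait variances and the given
    genetic and non-shared-environmental correlations.

    With unit variances the standardized paths equal the raw paths:
    ``a21 = rg * sqrt(h2_2)`` and ``a22`` absorbs the rest of trait 2's
    genetic variance (analogously for E).  Defaults reproduce the behavioral
    depression-CU model's reported correlations (rG = 0.40, rE = 0.04) with
    heritability 0.45 for both traits.  Returns ``(A, E)``.
    """
    a11 = np.sqrt(h2_1)
    a21 = rg * np.sqrt(h2_2)
    a22 = np.sqrt(h2_2 - a21 ** 2)
    e11 = np.sqrt(1.0 - h2_1)
    e21 = re * np.sqrt(1.0 - h2_2)
    e22 = np.sqrt(1.0 - h2_2 - e21 ** 2)
    A = np.array([[a11, 0.0], [a21, a22]])
    E = np.array([[e11, 0.0], [e21, e22]])
    return A, E


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(n_genes: int = 100, n_regions: int = 10,
                        k_true: int = 3, separation: float = 3.0,
                        noise_sd: float = 0.5, seed=None):
    """Gene x region matrix with ``k_true`` planted mean profiles.

    Returns ``(ExpressionMatrix, labels)`` with the true cluster label per
    gene.  Profiles are drawn N(0, separation^2) per region, rows add
    N(0, noise_sd^2) noise.
    """
    if k_true > n_genes:
        raise ValueError("k_true cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    profiles = rng.normal(0.0, separation, size=(k_true, n_regions))
    labels = np.repeat(np.arange(k_true), int(np.ceil(n_genes / k_true)))[:n_genes]
    values = profiles[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_regions))
    mat = ExpressionMatrix(values,
                           [f"GENE{i:04d}" for i in range(n_genes)],
                           [f"region{j}" for j in range(n_regions)])
    return mat, labels
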