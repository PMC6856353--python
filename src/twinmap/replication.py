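"""Family-preserving split-half replication and the triple-conjunction rule.

Families (twin pairs) are randomly partitioned into two halves so co-twins
never straddle the split; the full analysis is repeated in each half, and a
full-sample cluster counts as replicated only if it spatially overlaps a
same-sign surviving cluster in *both* halves.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cohort import TwinCohort
from .mapping import Cluster, ClusterTable
from .mesh import SurfaceMesh


def split_by_family(cohort: TwinCohort, seed=None, mode: str = "balanced"):
    """Random family-preserving split into two sub-cohorts.

    ``mode="balanced"`` (default) partitions families into halves whose sizes
    differ by at most one; ``mode="bernoulli"`` assigns each family by an
    independent fair coin, allowing unequal halves.  Deterministic given
    ``seed``.  Returns ``(cohort1, cohort2, assignment)`` where assignment is
    0/1 per family.
    """
    n = cohort.n_pairs
    if n < 2:
        raise ValueError("need at least two families to split")
    rng = np.random.default_rng(seed)
    if mode == "balanced":
        order = rng.permutation(n)
        assign = np.zeros(n, dtype=int)
        assign[order[n // 2 + n % 2:]] = 1
    elif mode == "bernoulli":
        assign = rng.integers(0, 2, size=n)
        # a degenerate draw that empties a half is redrawn deterministically
        while assign.min() == assign.max():
            assign = rng.integers(0, 2, size=n)
    else:
        raise ValueError("mode must be 'balanced' or 'bernoulli'")
    return cohort.subset(assign == 0), cohort.subset(assign == 1), assign


def _overlaps_same_sign(cluster: Cluster, table: ClusterTable) -> bool:
    mine = cluster.vertex_set()
    for other in table.clusters:
        if other.sign == cluster.sign and mine & other.vertex_set():
            return True
    return False


def triple_conjunction(full: ClusterTable, half1: ClusterTable,
                       half2: ClusterTable, mesh: SurfaceMesh) -> ClusterTable:
    """Confidence criterion: keep full-sample clusters that spatially
    intersect a same-sign surviving cluster in both half-sample analyses.

    All clusters of the full table are returned with their ``replicated``
    flag set; the replicated subset is always a subset of the full table.
    """
    for t in (full, half1, half2):
        if t.n_mesh_vertices is not None and t.n_mesh_vertices != mesh.n_vertices:
            raise ValueError("cluster table does not match the mesh")
    out = []
    for c in full.clusters:
        rep = _overlaps_same_sign(c, half1) and _overlaps_same_sign(c, half2)
        out.append(replace(c, replicated=rep))
    return ClusterTable(out, trait=full.trait, component=full.component,
                        n_mesh_vertices=full.n_mesh_vertices)
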