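"""Phylogenetic profiling: presence/absence matrices and profile clustering.

A phylogenetic profile records, for each species, whether a homolog of a
given complex component is detectable.  Components that co-occur across
species (correlated profiles) are candidates for functional coupling or
subcomplex membership.  Profiles are clustered hierarchically with the
correlation distance (1 - Pearson r) and average linkage (UPGMA), and the
dendrogram is exported in newick form with merge heights as node depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ProfileMatrix",
    "ClusterResult",
    "ConstantColumnError",
    "build_profile",
    "correlation_distance",
    "cluster_profiles",
    "export_heatmap_data",
    "linkage_to_newick",
]


class ConstantColumnError(ValueError):
    """Pearson correlation is undefined for an all-0 or all-1 profile."""


@dataclass
class ProfileMatrix:
    """Species x component binary matrix (rows species, columns components)."""

    data: pd.DataFrame
    taxon_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate species labels")
        if df.columns.duplicated().any():
            raise ValueError("duplicate component labels")
        if df.shape[1] < 2:
            raise ValueError("need at least 2 components")
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")
        self.data = df.astype(np.int8)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def components(self) -> list[str]:
        return list(self.data.columns)


def build_profile(
    homolog_table: pd.DataFrame | str | Path,
    components: list[str] | None = None,
) -> ProfileMatrix:
    """Presence/absence matrix from a (species, component[, present]) table.

    An entry is 1 iff the table records at least one homolog for that
    (species, component); duplicates are OR-ed.  Species keep first-seen
    order.  ``components`` may declare the full column set (so components
    never observed still appear as all-zero columns).
    """
    if not isinstance(homolog_table, pd.DataFrame):
        homolog_table = pd.read_csv(homolog_table, sep="\t", dtype=str)
    df = homolog_table.copy()
    if "present" in df.columns:
        present = df["present"].astype(float) > 0
    else:
        present = pd.Series(True, index=df.index)
    df = df[present]
    species_order = list(dict.fromkeys(df["species"]))
    comp_order = components or sorted(set(df["component"]))
    mat = pd.DataFrame(0, index=species_order, columns=comp_order, dtype=np.int8)
    for sp, comp in zip(df["species"], df["component"]):
        if comp in mat.columns:
            mat.loc[sp, comp] = 1
    return ProfileMatrix(data=mat)


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation of two equal-length binary profiles, in [0, 2].

    Raises :class:`ConstantColumnError` for a constant vector (undefined
    correlation) rather than returning NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("u and v must be equal-length vectors of length >=2")
    du = u - u.mean()
    dv = v - v.mean()
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0.0 or nv == 0.0:
        raise ConstantColumnError("correlation undefined for a constant profile")
    return float(np.clip(1.0 - (du @ dv) / (nu * nv), 0.0, 2.0))


@dataclass
class ClusterResult:
    components: list[str]  # lexicographic order used for the linkage
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    flat_clusters: dict[str, int]
    cophenetic: np.ndarray  # condensed cophenetic distances
    distances: np.ndarray  # condensed input distances


def cluster_profiles(
    matrix: ProfileMatrix,
    k: int | None = None,
    height: float | None = None,
    metric: str = "correlation",
) -> ClusterResult:
    """UPGMA clustering of component profiles.

    Components are ordered lexicographically before distance computation
    (deterministic tie-breaking).  ``metric`` is "correlation" (the
    default; constant columns raise, naming the offending components —
    pass ``metric="jaccard"`` as a fallback for matrices with
    always-present components) or any scipy pdist metric.  Flat clusters
    come from ``k`` (maxclust) or a ``height`` cut; with neither given,
    every component is its own cluster at height 0.
    """
    comps = sorted(matrix.components)
    X = matrix.data[comps].to_numpy(dtype=float).T  # components x species
    if X.shape[1] < 2:
        raise ValueError("need at least 2 species")
    if metric == "correlation":
        constant = [c for c, row in zip(comps, X) if np.ptp(row) == 0.0]
        if constant:
            raise ConstantColumnError(
                f"constant profile column(s) {constant}: correlation distance "
                "is undefined; drop them or use metric='jaccard'"
            )
        m = len(comps)
        condensed = np.array(
            [
                correlation_distance(X[i], X[j])
                for i in range(m)
                for j in range(i + 1, m)
            ]
        )
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric=metric)
    Z = hierarchy.linkage(condensed, method="average")
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        flat = np.arange(1, len(comps) + 1)
    coph = hierarchy.cophenet(Z)
    return ClusterResult(
        components=comps,
        linkage=Z,
        flat_clusters={c: int(f) for c, f in zip(comps, flat)},
        cophenetic=coph,
        distances=condensed,
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as newick, branch lengths from merge heights.

    Each branch length is parent merge height minus child merge height
    (leaves have height 0), so root-to-leaf path length equals the root
    merge height.
    """
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        inner = ",".join(walk(ch, node.dist) for ch in (node.left, node.right))
        return f"({inner}):{parent_height - node.dist:.10g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


@dataclass
class HeatmapData:
    ordered_matrix: pd.DataFrame
    leaf_order: list[str]
    newick: str


def export_heatmap_data(matrix: ProfileMatrix, result: ClusterResult) -> HeatmapData:
    """Column-permuted matrix (dendrogram leaf order) plus newick dendrogram."""
    order = [result.components[i] for i in hierarchy.leaves_list(result.linkage)]
    return HeatmapData(
        ordered_matrix=matrix.data[order],
        leaf_order=order,
        newick=linkage_to_newick(result.linkage, result.components),
    )
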