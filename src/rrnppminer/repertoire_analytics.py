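"""Strain-by-cluster repertoire matrices and their summary statistics.

A repertoire is the binary presence/absence vector of regulator clusters
in one strain.  The module computes per-species cluster prevalence, the
number of distinct repertoire profiles, the mean pairwise profile
distance (Hamming count over cluster columns, averaged over unordered
distinct strain pairs), a hierarchically clustered strain ordering
(average linkage on Hamming distances), and neighbor-joining trees with
midpoint rooting for cluster representatives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "RepertoireMatrix",
    "ProfileStats",
    "build_matrix",
    "prevalence",
    "profile_stats",
    "hierarchical_order",
    "nj_tree",
    "midpoint_root",
    "linkage_to_newick",
]


@dataclass
class RepertoireMatrix:
    strain_ids: list[str]
    species_labels: list[str]
    cluster_ids: list[str]
    cells: np.ndarray  # (n_strains, n_clusters) in {0, 1}

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.species_labels):
            raise ValueError("strain_ids and species_labels must be parallel")
        if self.cells.shape != (len(self.strain_ids), len(self.cluster_ids)):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")

    def rows_for_species(self, species: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.species_labels) if s == species]
        return self.cells[idx]


@dataclass
class ProfileStats:
    n_distinct_profiles: int
    top_k_profile_fraction: float
    mean_pairwise_difference: float
    per_cluster_prevalence: dict[str, float] = field(default_factory=dict)


def build_matrix(
    cluster_memberships: dict[str, list[str]],
    strains: list[tuple[str, str]],
) -> RepertoireMatrix:
    """Presence/absence matrix from cluster -> genome-id memberships.

    ``cluster_memberships`` maps cluster_id to the genome ids carrying at
    least one member hit (duplicates are fine: presence is binary);
    ``strains`` is a list of (strain_id, species_label).
    """
    strain_ids = [s for s, _ in strains]
    species = [sp for _, sp in strains]
    cluster_ids = sorted(cluster_memberships)
    index = {s: i for i, s in enumerate(strain_ids)}
    cells = np.zeros((len(strain_ids), len(cluster_ids)), dtype=int)
    for k, cid in enumerate(cluster_ids):
        for gid in cluster_memberships[cid]:
            if gid in index:
                cells[index[gid], k] = 1
    return RepertoireMatrix(strain_ids, species, cluster_ids, cells)


def prevalence(matrix: RepertoireMatrix, species: str) -> dict[str, float]:
    """Fraction of the species' strains carrying each cluster."""
    rows = matrix.rows_for_species(species)
    if rows.shape[0] == 0:
        raise ValueError(f"no strains labelled {species!r}")
    frac = rows.mean(axis=0)
    return dict(zip(matrix.cluster_ids, frac.tolist()))


def profile_stats(
    matrix: RepertoireMatrix,
    species: str,
    top_k: int = 1,
    with_replacement: bool = False,
) -> ProfileStats:
    """Distinct-profile count and mean pairwise Hamming distance.

    The distance between two strains is the number of clusters present in
    one but not the other; the mean is over unordered distinct pairs
    (``with_replacement`` rescales by (n-1)/n for the sampling-with-
    replacement convention).
    """
    rows = matrix.rows_for_species(species)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("profile_stats needs at least 2 strains of the species")
    profiles = [tuple(r) for r in rows]
    counts = sorted(
        (sum(1 for p in profiles if p == q) for q in set(profiles)), reverse=True
    )
    n_distinct = len(set(profiles))
    total = 0
    for a, b in itertools.combinations(range(n), 2):
        total += int(np.sum(rows[a] != rows[b]))
    mean_diff = total / (n * (n - 1) / 2)
    if with_replacement:
        mean_diff *= (n - 1) / n
    return ProfileStats(
        n_distinct_profiles=n_distinct,
        top_k_profile_fraction=sum(counts[:top_k]) / n,
        mean_pairwise_difference=mean_diff,
        per_cluster_prevalence=prevalence(matrix, species),
    )


def _hamming_condensed(cells: np.ndarray) -> np.ndarray:
    if cells.shape[1] == 0:
        return np.zeros(cells.shape[0] * (cells.shape[0] - 1) // 2)
    return pdist(cells, metric="hamming") * cells.shape[1]


def hierarchical_order(
    matrix: RepertoireMatrix,
) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage ordering of strains on Hamming profile distances.

    Strains are pre-sorted by id so that ties break deterministically.
    Returns (ordered strain ids, the scipy linkage matrix, newick string).
    """
    if len(matrix.strain_ids) < 2:
        raise ValueError("need at least 2 strains")
    order0 = np.argsort(np.array(matrix.strain_ids, dtype=object))
    ids = [matrix.strain_ids[i] for i in order0]
    cells = matrix.cells[order0]
    z = linkage(_hamming_condensed(cells), method="average")
    leaf_order = [ids[i] for i in leaves_list(z)]
    newick = linkage_to_newick(z, ids)
    return leaf_order, z, newick


def cophenetic_distances(z: np.ndarray) -> np.ndarray:
    return cophenet(z)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a rooted Newick string."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = z[i - n]
        a, b = int(a), int(b)
        return (
            f"({node(a)}:{h / 2 - heights[a] / 2:.6f},"
            f"{node(b)}:{h / 2 - heights[b] / 2:.6f})"
        )

    for i in range(z.shape[0]):
        heights[n + i] = z[i, 2]
    return node(n + z.shape[0] - 1) + ";"


def nj_tree(distance_matrix: np.ndarray, leaf_ids: list[str]) -> str:
    """Neighbor-joining tree (Newick) from a symmetric distance matrix."""
    dm = DistanceMatrix(np.asarray(distance_matrix, dtype=float), leaf_ids)
    tree = nj(dm)
    for n_ in tree.postorder():
        if n_.length is not None and n_.length < 0:
            n_.length = 0.0  # NJ can yield tiny negative estimates
    return str(tree).strip()


def midpoint_root(newick: str) -> str:
    """Re-root a Newick tree at the midpoint of its longest leaf path."""
    tree = TreeNode.read([newick])
    rooted = tree.root_at_midpoint()
    return str(rooted).strip()
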