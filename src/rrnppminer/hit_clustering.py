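"""Clustering of regulator hits and of their genomic-context genes.

Filtered profile-HMM hits, projected onto the retained match columns, are
grouped into similarity clusters: an edge joins two hits whose pairwise
identity on the shared (mutually non-gap) retained columns exceeds the
cutoff, and clusters are the connected components of that graph.  Each
cluster is classified by its best-scoring bait (local alignment, BLOSUM62,
gap open 11 / extend 1); identity below 40% earns the subfamily a "-like"
signifier.  Cluster identifiers follow the species-scoped naming scheme
(single-species tokens, or the group token when a cluster spans at least
two species).  Genes within 2 kbp of a regulator are clustered by
all-against-all local alignment requiring >= 70% coverage of both
sequences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .profile_hmm import HmmHit, RetainedColumnMask

__all__ = [
    "AlignedHitMatrix",
    "RegulatorCluster",
    "FamilyAssignment",
    "ContextGeneCluster",
    "SPECIES_TOKENS",
    "GROUP_TOKEN",
    "pairwise_identity",
    "cluster_hits",
    "assign_family",
    "name_cluster",
    "cluster_context_genes",
    "local_align",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1),
# used for the context-gene edge E-values.
_KA_LAMBDA = 0.267
_KA_K = 0.041

#: Species-label -> identifier token for cluster naming.
SPECIES_TOKENS = {
    "Streptococcus thermophilus": "Sthermo",
    "Streptococcus salivarius": "Ssali",
    "Streptococcus vestibularis": "Svesti",
}
GROUP_TOKEN = "gp_sali"


def _aligner(mode: str = "local") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = mode
    return al


def local_align(query: str, target: str) -> tuple[float, float, float, float, float]:
    """Best local alignment of two protein sequences.

    Returns (score, identity_fraction, query_coverage, target_coverage,
    n_aligned_columns).  Identity is identical pairs over aligned residue
    pairs; coverage is the aligned span over each sequence's length.
    """
    al = _aligner("local")
    try:
        alns = al.align(query, target)
    except Exception:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    aln = alns[0]
    ident = 0
    ncols = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for a, b in zip(query[qs:qe], target[ts:te]):
            ncols += 1
            if a == b:
                ident += 1
    qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    tspan = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    identity = ident / ncols if ncols else 0.0
    return (
        float(aln.score),
        identity,
        qspan / len(query),
        tspan / len(target),
        float(ncols),
    )


@dataclass
class AlignedHitMatrix:
    """Hits projected onto the retained match columns (rows all same length)."""

    hit_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must all have the same length")

    @classmethod
    def from_hits(
        cls, hits: list[HmmHit], mask: RetainedColumnMask
    ) -> "AlignedHitMatrix":
        cols = [j for j, keep in enumerate(mask.mask) if keep]
        rows = ["".join(h.aligned_row[j] for j in cols) for h in hits]
        return cls(hit_ids=[h.protein_id for h in hits], rows=rows)


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Identity over columns where both rows carry a residue (0 if none)."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows have different lengths")
    both = 0
    same = 0
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            both += 1
            if a == b:
                same += 1
    return same / both if both else 0.0


@dataclass
class FamilyAssignment:
    best_bait: str
    family: str
    subfamily: str
    identity_pct: float
    coverage_pct: float
    like_flag: bool
    unclassified: bool = False


@dataclass
class RegulatorCluster:
    cluster_id: str = ""
    members: list[str] = field(default_factory=list)
    family: str = ""
    subfamily: str = ""
    best_bait: str = ""
    bait_identity: float = 0.0
    bait_coverage: float = 0.0
    like_flag: bool = False
    species_set: set[str] = field(default_factory=set)
    aip_name: str | None = None


def cluster_hits(
    matrix: AlignedHitMatrix, cutoff: float = 0.90, strict: bool = True
) -> list[RegulatorCluster]:
    """Connected components of the identity graph at the cutoff.

    ``strict`` uses identity > cutoff ("more than 90%"); set False for >=.
    Clusters are ordered by size (descending), then by lexicographically
    smallest member, so the partition is deterministic for a given input.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.hit_ids)
    n = len(matrix.hit_ids)
    for i in range(n):
        for k in range(i + 1, n):
            ident = pairwise_identity(matrix.rows[i], matrix.rows[k])
            if (ident > cutoff) if strict else (ident >= cutoff):
                g.add_edge(matrix.hit_ids[i], matrix.hit_ids[k])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [RegulatorCluster(members=c) for c in comps]


def assign_family(
    representative_seq: str,
    baits: list[tuple[str, str, str, str]],
    like_identity_pct: float = 40.0,
) -> FamilyAssignment:
    """Transfer family/subfamily from the closest bait.

    ``baits`` rows are (bait_id, family, subfamily, sequence); the best
    bait is the highest-scoring local alignment (the closest match in the
    blastp ranking sense), ties broken by identity, then coverage, then
    bait order; the reported identity/coverage are that alignment's.
    Identity below ``like_identity_pct`` sets the "-like" flag.
    """
    best = None
    for order, (bait_id, family, subfamily, seq) in enumerate(baits):
        seq = seq.replace("-", "")
        score, ident, qcov, _tcov, _n = local_align(representative_seq, seq)
        if score <= 0:
            continue
        key = (score, ident, qcov, -order)
        if best is None or key > best[0]:
            best = (key, bait_id, family, subfamily, ident, qcov)
    if best is None:
        return FamilyAssignment("", "", "", 0.0, 0.0, False, unclassified=True)
    _, bait_id, family, subfamily, ident, qcov = best
    return FamilyAssignment(
        best_bait=bait_id,
        family=family,
        subfamily=subfamily,
        identity_pct=100.0 * ident,
        coverage_pct=100.0 * qcov,
        like_flag=100.0 * ident < like_identity_pct,
    )


class ClusterNamer:
    """Deterministic running counter for species-scoped cluster ids."""

    def __init__(self) -> None:
        self._counter = 0

    def next_index(self) -> int:
        self._counter += 1
        return self._counter


def name_cluster(
    cluster: RegulatorCluster,
    species_set: set[str],
    namer: ClusterNamer,
    species_tokens: dict[str, str] | None = None,
) -> str:
    """Species-scoped identifier, e.g. ``SHP/Rgg_Sthermo_6_``.

    The label is the subfamily (with "-like" when the bait identity is
    below 40%), the species token when the cluster is confined to one
    species or the group token when it spans at least two, a running
    integer, and a trailing underscore.
    """
    tokens = species_tokens or SPECIES_TOKENS
    base = cluster.subfamily or cluster.family or "unclassified"
    if cluster.like_flag and not base.endswith("-like"):
        base = f"{base}-like"
    if len(species_set) == 1:
        label = next(iter(species_set))
        scope = tokens.get(label, label.replace(" ", "")[:6])
    else:
        scope = GROUP_TOKEN
    return f"{base}_{scope}_{namer.next_index()}_"


@dataclass
class ContextGeneCluster:
    members: list[str]
    annotation_consensus: str = ""


def cluster_context_genes(
    neighborhood_proteins: list[tuple[str, str, str]],
    evalue_max: float = 1e-3,
    coverage_min: float = 0.70,
) -> list[ContextGeneCluster]:
    """Cluster neighborhood genes by mutual-coverage local alignment.

    ``neighborhood_proteins`` rows are (protein_id, sequence, product).
    An edge requires a Karlin-Altschul E-value <= ``evalue_max`` and an
    aligned span covering >= ``coverage_min`` of BOTH sequences; clusters
    are connected components.
    """
    g = nx.Graph()
    products = {}
    seqs = {}
    for pid, seq, product in neighborhood_proteins:
        g.add_node(pid)
        products[pid] = product
        seqs[pid] = seq
    ids = [p[0] for p in neighborhood_proteins]
    n = len(ids)
    db_residues = sum(len(s) for s in seqs.values())
    for i in range(n):
        for k in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[k]]
            score, _ident, qcov, tcov, _ncols = local_align(a, b)
            if score <= 0:
                continue
            ev = _KA_K * len(a) * db_residues * math.exp(-_KA_LAMBDA * score)
            if ev <= evalue_max and qcov >= coverage_min and tcov >= coverage_min:
                g.add_edge(ids[i], ids[k])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = []
    for comp in comps:
        consensus = Counter(products[p] for p in comp if products[p]).most_common(1)
        out.append(
            ContextGeneCluster(
                members=comp,
                annotation_consensus=consensus[0][0] if consensus else "",
            )
        )
    return out
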