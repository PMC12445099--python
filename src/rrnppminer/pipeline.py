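"""End-to-end mining workflow over a genome corpus.

Chains the stages: build and calibrate the generic regulator profile,
search every proteome, filter hits, project them onto high-posterior
columns, cluster at the identity cutoff, classify and name clusters,
detect short CDSs near each regulator, annotate AIP candidates, and
assemble the strain-by-cluster repertoire matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import (
    aip_annotator,
    hit_clustering,
    profile_hmm,
    repertoire_analytics,
    sequence_io,
    short_cds_finder,
)

__all__ = ["MiningResult", "run_pipeline"]


@dataclass
class MiningResult:
    profile: profile_hmm.ProfileHMM
    calibration: profile_hmm.CalibrationParams
    hits: list = field(default_factory=list)
    filtered_hits: list = field(default_factory=list)
    mask: profile_hmm.RetainedColumnMask | None = None
    clusters: list = field(default_factory=list)
    aip_candidates: dict = field(default_factory=dict)  # regulator protein_id -> list
    matrix: repertoire_analytics.RepertoireMatrix | None = None


def run_pipeline(
    genomes: list[sequence_io.GenomeRecord],
    baits: profile_hmm.BaitAlignment,
    seeds=None,
    calibration_seed: int = 0,
    hit_filter: profile_hmm.HitFilterConfig | None = None,
    identity_cutoff: float = 0.90,
    pp_threshold: float = 0.85,
    train_genome_count: int = 5,
    neighborhood_window: int = 300,
) -> MiningResult:
    """Run the full mining workflow on parsed genomes.

    The short-CDS composition model is trained on the first
    ``train_genome_count`` genomes (emulating a small set of
    representative annotated isolates).
    """
    profile = profile_hmm.build_profile(baits)
    calib = profile_hmm.calibrate_evalues(profile, seed=calibration_seed)

    proteome = []
    genome_by_id = {}
    feature_by_pid = {}
    for g in genomes:
        genome_by_id[g.genome_id] = g
        for p in sequence_io.extract_proteome(g):
            proteome.append(p)
        for contig in g.contigs:
            for f in contig.features:
                feature_by_pid[f.feature_id] = (g.genome_id, contig.contig_id, f)

    hits = profile_hmm.search(profile, proteome, calib)
    filtered = profile_hmm.filter_hits(hits, hit_filter)
    result = MiningResult(profile=profile, calibration=calib, hits=hits,
                          filtered_hits=filtered)
    if not filtered:
        return result

    mask = profile_hmm.retained_columns(filtered, pp_threshold)
    matrix = hit_clustering.AlignedHitMatrix.from_hits(filtered, mask)
    clusters = hit_clustering.cluster_hits(matrix, cutoff=identity_cutoff)

    hit_by_pid = {h.protein_id: h for h in filtered}
    prot_by_pid = {p.protein_id: p for p in proteome}
    namer = hit_clustering.ClusterNamer()
    bait_rows = baits.rows
    for cluster in clusters:
        rep = min(cluster.members)
        fam = hit_clustering.assign_family(prot_by_pid[rep].sequence, bait_rows)
        cluster.family = fam.family
        cluster.subfamily = fam.subfamily
        cluster.best_bait = fam.best_bait
        cluster.bait_identity = fam.identity_pct
        cluster.bait_coverage = fam.coverage_pct
        cluster.like_flag = fam.like_flag
        cluster.species_set = {
            genome_by_id[hit_by_pid[m].genome_id].species_label
            for m in cluster.members
        }
        cluster.cluster_id = hit_clustering.name_cluster(
            cluster, cluster.species_set, namer
        )

    # short-CDS / AIP annotation around every filtered hit
    model = short_cds_finder.train_cds_model(genomes[:train_genome_count])
    candidates_by_genome = {}
    aip_candidates = {}
    for h in filtered:
        gid, cid, feat = feature_by_pid[h.protein_id]
        if gid not in candidates_by_genome:
            candidates_by_genome[gid] = short_cds_finder.predict_short_cds(
                genome_by_id[gid], model
            )
        nearby = short_cds_finder.neighborhood_scan(
            candidates_by_genome[gid], feat, contig_id=cid, window=neighborhood_window
        )
        nearby = [c for c in nearby if not (c.start == feat.start and c.end == feat.end)]
        aip_candidates[h.protein_id] = aip_annotator.annotate_regulator(
            feat, nearby, seeds
        )

    memberships = {
        c.cluster_id: [hit_by_pid[m].genome_id for m in c.members] for c in clusters
    }
    strains = [(g.genome_id, g.species_label) for g in genomes]
    result.mask = mask
    result.clusters = clusters
    result.aip_candidates = aip_candidates
    result.matrix = repertoire_analytics.build_matrix(memberships, strains)
    return result
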