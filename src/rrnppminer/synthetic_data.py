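"""Synthetic genome corpus with a ground-truth manifest.

The generator emulates the statistical structure the mining pipeline
assumes in real streptococcal genomes: contigs whose coding regions are
back-translated through a biased codon-usage model, intergenic background
drawn from a distinct low-GC order-2 Markov chain, regulator homologs
planted at controlled pairwise identities (tight within a cluster, well
separated between clusters), unannotated short AIP genes placed within
300 bp of their regulator in a chosen gene orientation, shared
neighborhood (context) genes, and decoy short ORFs.  Every planted
feature is recorded in a manifest that serves as the oracle for recovery
tests.

Planted-but-unannotated genes (AIPs, decoys) carry an immediately
upstream in-frame stop codon so that the start-to-first-stop reading
frame reproduces the planted coordinates exactly; real intergenic DNA is
saturated with stops in the same way.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .profile_hmm import AMINO_ACIDS, BACKGROUND_FREQS, BaitAlignment
from .sequence_io import (
    STOP_CODONS,
    CdsFeature,
    Contig,
    GenomeRecord,
    reverse_complement,
    translate_cds,
)
from .aip_annotator import AipSeedSet

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "PlantedRegulator",
    "PlantedAip",
    "PlantedContextGene",
    "DecoyOrf",
    "AipTemplate",
    "mutate_protein",
    "back_translate",
    "random_protein",
    "generate_corpus",
    "write_corpus",
    "default_codon_usage",
    "default_background_transitions",
]

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

_CODONS_BY_AA: dict[str, list[str]] = {}


def _init_codon_maps() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                aa = aas[i]
                i += 1
                if aa != "*":
                    _CODONS_BY_AA.setdefault(aa, []).append(b1 + b2 + b3)


_init_codon_maps()

_SENSE_CODONS = sorted(c for cs in _CODONS_BY_AA.values() for c in cs)
_SENSE_INDEX = {c: i for i, c in enumerate(_SENSE_CODONS)}


def default_codon_usage() -> np.ndarray:
    """61-codon usage: background amino-acid frequencies with a 3x
    preference for A/T-ending synonymous codons (low-GC streptococcal
    style)."""
    usage = np.zeros(61)
    aa_freq = dict(zip(AMINO_ACIDS, BACKGROUND_FREQS))
    for aa, codons in _CODONS_BY_AA.items():
        weights = np.array([3.0 if c[2] in "AT" else 1.0 for c in codons])
        weights = weights / weights.sum()
        for c, w in zip(codons, weights):
            usage[_SENSE_INDEX[c]] = aa_freq[aa] * w
    return usage / usage.sum()


def default_background_transitions(gc: float = 0.34, stickiness: float = 1.25):
    """Order-2 intergenic chain: low-GC base composition with a mild
    preference for repeating the previous nucleotide."""
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.zeros((16, 4))
    for ctx in range(16):
        prev = ctx % 4
        row = base.copy()
        row[prev] *= stickiness
        trans[ctx] = row / row.sum()
    return trans, base


@dataclass
class AipTemplate:
    name: str
    aip_class: str
    precursor: str
    mature: str


def _default_aip_templates() -> list[AipTemplate]:
    # SHP-grammar precursors (20-26 aa, N-terminal K, hydrophobic C-tail,
    # terminal G, central acidic residue); mature = C-terminal-half rule.
    return [
        AipTemplate("aipT1", "SHP", "MKKILSKFLVLALVLDIIIIVGG", "DIIIIVGG"),
        AipTemplate("aipT2", "SHP", "MKNFLSLALILPFVFEGIIVIAVG", "EGIIVIAVG"),
        AipTemplate("aipT3", "SHP", "MKKQVLLPLLLAVFESIIVILVG", "ESIIVILVG"),
        AipTemplate("aipT4", "ComS", "MKNTNKFLSLFEVELAGFWGWG", "ELAGFWGWG"),
        AipTemplate("aipT5", "PapR", "MKKLALSVLALTLLLSACSNQENVFADLPFEF", "DLPFEF"),
    ]


@dataclass
class SyntheticConfig:
    rng_seed: int = 0
    n_genomes_per_species: dict[str, int] = field(
        default_factory=lambda: {
            "Streptococcus thermophilus": 8,
            "Streptococcus salivarius": 7,
            "Streptococcus vestibularis": 5,
        }
    )
    genome_length: int = 200_000
    background_markov_order: int = 2
    background_gc: float = 0.34
    coding_codon_usage: np.ndarray = field(default_factory=default_codon_usage)
    n_baits: int = 33
    bait_length: int = 250
    #: the four regulator families share the TPR/HTH fold; their synthetic
    #: prototypes descend from one ancestral sequence at this identity
    family_identity_to_ancestor: float = 0.55
    bait_identity_to_prototype: float = 0.65
    #: residues at each end excluded from substitution in the regulator
    #: hierarchy, emulating the conserved terminal HTH/TPR-cap segments
    #: that let real homologs align over the (nearly) entire profile
    conserved_terminal_aa: int = 15
    n_clusters: int = 5
    cluster_seed_identity_to_bait: float = 0.75
    within_cluster_identity: float = 0.95
    between_cluster_identity_max: float = 0.70
    aip_planting_rate: float = 0.9
    decoy_short_orf_rate: float = 0.2  # per kbp
    filler_gene_length_aa: int = 250
    coding_density: float = 0.5
    #: presence probability per cluster, per species
    presence_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "Streptococcus thermophilus": (1.0, 0.8, 0.6, 0.3, 0.0),
            "Streptococcus salivarius": (0.7, 0.0, 0.5, 0.9, 0.4),
            "Streptococcus vestibularis": (0.5, 0.0, 0.0, 0.3, 0.8),
        }
    )
    aip_templates: list[AipTemplate] = field(default_factory=_default_aip_templates)


@dataclass
class PlantedRegulator:
    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cluster_index: int
    source_bait: str
    realized_identity_to_cluster_seed: float
    protein: str


@dataclass
class PlantedAip:
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    precursor: str
    mature: str
    aip_class: str
    orientation: str
    regulator_id: str


@dataclass
class PlantedContextGene:
    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    pool_index: int
    product: str


@dataclass
class DecoyOrf:
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str


@dataclass
class GroundTruthManifest:
    regulators: list[PlantedRegulator] = field(default_factory=list)
    aips: list[PlantedAip] = field(default_factory=list)
    context_genes: list[PlantedContextGene] = field(default_factory=list)
    decoys: list[DecoyOrf] = field(default_factory=list)

    def regulators_of(self, genome_id: str) -> list[PlantedRegulator]:
        return [r for r in self.regulators if r.genome_id == genome_id]

    def cluster_partition(self) -> dict[str, int]:
        """protein_id -> planted cluster index (the acceptance oracle)."""
        return {r.protein_id: r.cluster_index for r in self.regulators}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulators": [asdict(r) for r in self.regulators],
            "aips": [asdict(a) for a in self.aips],
            "context_genes": [asdict(c) for c in self.context_genes],
            "decoys": [asdict(d) for d in self.decoys],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            regulators=[PlantedRegulator(**r) for r in payload["regulators"]],
            aips=[PlantedAip(**a) for a in payload["aips"]],
            context_genes=[PlantedContextGene(**c) for c in payload["context_genes"]],
            decoys=[DecoyOrf(**d) for d in payload["decoys"]],
        )


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------


def random_protein(length: int, rng: np.random.Generator, start_with_met: bool = True) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    aa = "".join(AMINO_ACIDS[i] for i in idx)
    if start_with_met:
        aa = "M" + aa[1:]
    return aa


def mutate_protein(
    seq: str, target_identity: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Substitute an exact number of positions to hit the target identity.

    Replacement residues are drawn from the background frequencies
    excluding the original residue, so every substitution lowers identity.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    n = len(seq)
    n_sub = int(round(n * (1.0 - target_identity)))
    if n_sub == 0:
        return seq, 1.0
    positions = rng.choice(n, size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        orig = chars[pos]
        probs = BACKGROUND_FREQS.copy()
        if orig in AMINO_ACIDS:
            probs[AMINO_ACIDS.index(orig)] = 0.0
        probs = probs / probs.sum()
        chars[pos] = AMINO_ACIDS[rng.choice(20, p=probs)]
    mutated = "".join(chars)
    realized = sum(a == b for a, b in zip(seq, mutated)) / n
    return mutated, round(realized, 3)


def _mutate_interior(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    protected_ends: int,
) -> tuple[str, float]:
    """Like :func:`mutate_protein` but substitutions avoid the terminal
    ``protected_ends`` residues (conserved domain caps)."""
    n = len(seq)
    n_sub = int(round(n * (1.0 - target_identity)))
    interior = np.arange(protected_ends, n - protected_ends)
    if n_sub == 0:
        return seq, 1.0
    if n_sub > interior.size:
        raise ValueError("too many substitutions for the unprotected interior")
    positions = rng.choice(interior, size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        orig = chars[pos]
        probs = BACKGROUND_FREQS.copy()
        if orig in AMINO_ACIDS:
            probs[AMINO_ACIDS.index(orig)] = 0.0
        probs = probs / probs.sum()
        chars[pos] = AMINO_ACIDS[rng.choice(20, p=probs)]
    mutated = "".join(chars)
    realized = sum(a == b for a, b in zip(seq, mutated)) / n
    return mutated, round(realized, 3)


def back_translate(
    protein: str, codon_usage: np.ndarray, rng: np.random.Generator
) -> str:
    """Sample a coding sequence (with stop codon) under the codon usage.

    The first codon avoids start-codon synonyms unless the residue is M,
    so in-silico retranslation reproduces the protein exactly.
    """
    parts = []
    for i, aa in enumerate(protein):
        codons = _CODONS_BY_AA[aa]
        if i == 0:
            if aa == "M":
                parts.append("ATG")
                continue
            codons = [c for c in codons if c not in ("ATG", "GTG", "TTG")]
        probs = np.array([codon_usage[_SENSE_INDEX[c]] for c in codons])
        probs = probs / probs.sum()
        parts.append(codons[rng.choice(len(codons), p=probs)])
    parts.append(STOP_CODONS[rng.choice(3)])
    return "".join(parts)


@njit(cache=False)
def _markov_path(trans_cum, init_cum, us, k):
    n = us.shape[0]
    out = np.empty(n, dtype=np.int64)
    ctx = 0
    have = 0
    for i in range(n):
        u = us[i]
        if have < k:
            b = 0
            while init_cum[b] < u:
                b += 1
        else:
            b = 0
            while trans_cum[ctx, b] < u:
                b += 1
        out[i] = b
        ctx = (ctx * 4 + b) % 4**k
        have = min(have + 1, k)
    return out


class _BackgroundSampler:
    def __init__(self, trans: np.ndarray, init: np.ndarray, k: int):
        self.trans_cum = np.cumsum(trans, axis=1)
        self.init_cum = np.cumsum(init)
        self.k = k

    def sample(self, length: int, rng: np.random.Generator, forbid: list[str]) -> str:
        for _ in range(20):
            us = rng.random(length)
            idx = _markov_path(self.trans_cum, self.init_cum, us, self.k)
            seq = "".join(_NT[i] for i in idx)
            if not _contains_planted_peptide(seq, forbid):
                return seq
        raise RuntimeError("could not sample clean background segment")


def _contains_planted_peptide(seq: str, peptides: list[str]) -> bool:
    """Six-frame scan for an exact planted peptide (rejection sampling)."""
    if not peptides:
        return False
    for s in (seq, reverse_complement(seq)):
        for frame in range(3):
            aa = translate_cds(s[frame:], truncate_at_stop=False)
            for pep in peptides:
                if pep in aa:
                    return True
    return False


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

_CONTEXT_PRODUCTS = [
    "radical SAM peptide maturase",
    "ABC transporter ATP-binding protein",
    "peptide pheromone permease",
    "ThiF family adenylyltransferase",
    "transposase fragment",
    "hypothetical protein",
]


@dataclass
class _Segment:
    """A forward-axis piece of genome with locally positioned features."""

    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    regulators: list[PlantedRegulator] = field(default_factory=list)
    aips: list[PlantedAip] = field(default_factory=list)
    context: list[PlantedContextGene] = field(default_factory=list)
    decoys: list[DecoyOrf] = field(default_factory=list)


def _place_gene(nt: str, strand: str, guard: bool) -> tuple[str, int, int]:
    """Return (segment sequence, gene start, gene end) on the forward axis.

    ``guard`` prepends an in-frame stop on the coding strand so that ORF
    enumeration starts exactly at the planted start codon.
    """
    core = ("TAA" + nt) if guard else nt
    offset = 3 if guard else 0
    if strand == "+":
        return core, offset, len(core)
    rc = reverse_complement(core)
    if guard:
        return rc, 0, len(rc) - 3
    return rc, 0, len(rc)


def generate_corpus(
    cfg: SyntheticConfig | None = None,
) -> tuple[list[GenomeRecord], GroundTruthManifest, BaitAlignment, AipSeedSet]:
    """Generate genomes, manifest, bait alignment and AIP seed set.

    Deterministic given ``cfg.rng_seed`` (a rerun is byte-identical).
    """
    cfg = cfg or SyntheticConfig()
    master = np.random.default_rng([cfg.rng_seed, 0])
    trans, base = default_background_transitions(cfg.background_gc)
    sampler = _BackgroundSampler(trans, base, cfg.background_markov_order)
    forbid = [t.precursor for t in cfg.aip_templates]

    # --- baits: indel-free mutants of four family prototypes -------------
    families = [
        ("Rgg", "SHP/Rgg", 20),
        ("ComR", "ComS/ComR", 5),
        ("PlcR", "PapR/TprA", 5),
        ("PrgX", "PrgX", 3),
    ]
    ancestor = random_protein(cfg.bait_length, master)
    prototypes = {
        fam: _mutate_interior(ancestor, cfg.family_identity_to_ancestor, master,
                              cfg.conserved_terminal_aa)[0]
        for fam, _, _ in families
    }
    bait_rows = []
    k = 0
    for fam, subfam, count in families:
        for _ in range(count):
            k += 1
            seq, _ident = _mutate_interior(
                prototypes[fam], cfg.bait_identity_to_prototype, master,
                cfg.conserved_terminal_aa,
            )
            bait_rows.append((f"bait{k}_{subfam.replace('/', '-')}", fam, subfam, seq))
    baits = BaitAlignment(bait_rows[: cfg.n_baits])

    # --- cluster seeds: mutants of chosen baits ---------------------------
    # three SHP/Rgg clusters, one ComS/ComR, one PapR/TprA
    parent_bait_idx = [0, 1, 2, 20, 25][: cfg.n_clusters]
    cluster_seeds = []
    for ci in range(cfg.n_clusters):
        bait_id, fam, subfam, bait_seq = baits.rows[parent_bait_idx[ci]]
        seed_seq, _ = _mutate_interior(
            bait_seq, cfg.cluster_seed_identity_to_bait, master,
            cfg.conserved_terminal_aa,
        )
        cluster_seeds.append((ci, bait_id, fam, subfam, seed_seq))

    # --- AIP seeds: noisy copies of the planted templates ----------------
    seed_records = []
    for t in cfg.aip_templates:
        noisy, _ = mutate_protein(t.precursor, 0.9, master)
        seed_records.append((f"seed_{t.name}", t.aip_class, noisy))
    seeds = AipSeedSet(seed_records)

    # --- context-gene pool ------------------------------------------------
    context_pool = [
        (random_protein(150, master), product) for product in _CONTEXT_PRODUCTS
    ]

    species_order = []
    for sp, n in cfg.n_genomes_per_species.items():
        species_order.extend([sp] * n)

    member_identity = (1.0 + cfg.within_cluster_identity) / 2.0
    manifest = GroundTruthManifest()
    genomes = []
    aip_cycle = {ci: cfg.aip_templates[ci % len(cfg.aip_templates)] for ci in range(cfg.n_clusters)}

    for gi, species in enumerate(species_order):
        rng = np.random.default_rng([cfg.rng_seed, 1 + gi])
        genome_id = f"SYN{gi + 1:03d}"
        contig_id = f"{genome_id}_c1"
        segments: list[_Segment] = []
        probs = cfg.presence_probs.get(species, (1.0,) * cfg.n_clusters)

        n_reg = 0
        for ci, bait_id, fam, subfam, seed_seq in cluster_seeds:
            if rng.random() >= probs[ci % len(probs)]:
                continue
            n_reg += 1
            segments.append(
                _build_regulator_locus(
                    cfg, rng, genome_id, contig_id, n_reg, ci, bait_id,
                    seed_seq, member_identity, aip_cycle[ci], context_pool,
                )
            )

        n_decoys = int(round(cfg.decoy_short_orf_rate * cfg.genome_length / 1000))
        for di in range(n_decoys):
            length = int(rng.integers(7, 61))
            pep = random_protein(length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            nt = back_translate(pep, cfg.coding_codon_usage, rng)
            seg_seq, s, e = _place_gene(nt, strand, guard=True)
            seg = _Segment(sequence=seg_seq)
            seg.decoys.append(
                DecoyOrf(genome_id, contig_id, s, e, strand, translate_cds(nt))
            )
            segments.append(seg)

        # filler coding genes up to the target coding density
        coding_nt = sum(len(s.sequence) for s in segments)
        target_coding = cfg.coding_density * cfg.genome_length
        fi = 0
        while coding_nt < target_coding:
            fi += 1
            pep = random_protein(cfg.filler_gene_length_aa, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            nt = back_translate(pep, cfg.coding_codon_usage, rng)
            seg_seq, s, e = _place_gene(nt, strand, guard=False)
            seg = _Segment(sequence=seg_seq)
            seg.features.append(
                CdsFeature(
                    f"{genome_id}_f{fi}", s, e, strand, pep, "hypothetical protein"
                )
            )
            segments.append(seg)
            coding_nt += len(seg_seq)

        rng.shuffle(segments)

        # assemble with background spacers
        pieces: list[str] = []
        pos = 0
        contig_features: list[CdsFeature] = []

        def _shift(seg: _Segment, offset: int) -> None:
            for f in seg.features:
                contig_features.append(
                    CdsFeature(
                        f.feature_id, f.start + offset, f.end + offset,
                        f.strand, f.protein, f.product,
                    )
                )
            for r in seg.regulators:
                r.start += offset
                r.end += offset
                manifest.regulators.append(r)
            for a in seg.aips:
                a.start += offset
                a.end += offset
                manifest.aips.append(a)
            for c in seg.context:
                c.start += offset
                c.end += offset
                manifest.context_genes.append(c)
            for d in seg.decoys:
                d.start += offset
                d.end += offset
                manifest.decoys.append(d)

        for seg in segments:
            spacer_len = int(rng.integers(100, 400))
            spacer = sampler.sample(spacer_len, rng, forbid)
            pieces.append(spacer)
            pos += spacer_len
            pieces.append(seg.sequence)
            _shift(seg, pos)
            pos += len(seg.sequence)
        if pos < cfg.genome_length:
            pieces.append(sampler.sample(cfg.genome_length - pos, rng, forbid))
        sequence = "".join(pieces)

        contig_features.sort(key=lambda f: f.start)
        contig = Contig(contig_id, sequence, contig_features)
        genomes.append(GenomeRecord(genome_id, species, [contig]))

    return genomes, manifest, baits, seeds


def _build_regulator_locus(
    cfg, rng, genome_id, contig_id, n_reg, ci, bait_id, seed_seq,
    member_identity, template, context_pool,
) -> _Segment:
    seg = _Segment(sequence="")
    protein, realized = _mutate_interior(
        seed_seq, member_identity, rng, cfg.conserved_terminal_aa
    )
    reg_strand = "+" if rng.random() < 0.5 else "-"
    reg_nt = back_translate(protein, cfg.coding_codon_usage, rng)
    reg_id = f"{genome_id}_r{n_reg}"

    plant_aip = rng.random() < cfg.aip_planting_rate
    orientation = ["divergent", "convergent", "co_upstream", "co_downstream"][
        int(rng.integers(0, 4))
    ]

    # context gene on each side of the locus
    def context_piece(pool_idx: int, tag: str) -> tuple[str, CdsFeature, PlantedContextGene]:
        pep, product = context_pool[pool_idx]
        strand = "+" if rng.random() < 0.5 else "-"
        nt = back_translate(pep, cfg.coding_codon_usage, rng)
        seq, s, e = _place_gene(nt, strand, guard=False)
        fid = f"{reg_id}_{tag}"
        feat = CdsFeature(fid, s, e, strand, pep, product)
        ctx = PlantedContextGene(fid, genome_id, contig_id, s, e, strand, pool_idx, product)
        return seq, feat, ctx

    pieces: list[tuple[str, str]] = []  # (kind, seq) in forward order
    left_idx = int(rng.integers(0, len(context_pool)))
    right_idx = int(rng.integers(0, len(context_pool)))

    # decide whether the AIP gene sits before (left of) the regulator
    if plant_aip:
        if orientation == "divergent":
            aip_strand = "-" if reg_strand == "+" else "+"
            aip_left = reg_strand == "+"
        elif orientation == "convergent":
            aip_strand = "-" if reg_strand == "+" else "+"
            aip_left = reg_strand == "-"
        elif orientation == "co_upstream":
            aip_strand = reg_strand
            aip_left = reg_strand == "+"
        else:  # co_downstream
            aip_strand = reg_strand
            aip_left = reg_strand == "-"
        aip_nt = back_translate(template.precursor, cfg.coding_codon_usage, rng)

    # build the locus: [ctxL] gap [maybe AIP] gap [regulator] gap [ctxR]
    parts: list[str] = []
    features: list[CdsFeature] = []
    cursor = 0

    def append_background(lo: int, hi: int) -> None:
        nonlocal cursor
        n = int(rng.integers(lo, hi))
        parts.append(_simple_background(n, rng, cfg))
        cursor += n

    def append_raw(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    seqL, featL, ctxL = context_piece(left_idx, "ctxL")
    off = append_raw(seqL)
    featL = CdsFeature(featL.feature_id, featL.start + off, featL.end + off, featL.strand, featL.protein, featL.product)
    ctxL.start += off
    ctxL.end += off
    features.append(featL)
    seg.context.append(ctxL)
    append_background(100, 300)

    aip_record = None
    if plant_aip and aip_left:
        aip_record = _append_aip(
            cfg, rng, append_raw, aip_nt, aip_strand, template,
            genome_id, contig_id, reg_id, orientation,
        )
        append_background(20, 150)

    reg_seq, rs, re_ = _place_gene(reg_nt, reg_strand, guard=False)
    off = append_raw(reg_seq)
    features.append(
        CdsFeature(reg_id, rs + off, re_ + off, reg_strand, protein, "transcriptional regulator")
    )
    seg.regulators.append(
        PlantedRegulator(
            reg_id, genome_id, contig_id, rs + off, re_ + off, reg_strand,
            ci, bait_id, realized, protein,
        )
    )

    if plant_aip and not aip_left:
        append_background(20, 150)
        aip_record = _append_aip(
            cfg, rng, append_raw, aip_nt, aip_strand, template,
            genome_id, contig_id, reg_id, orientation,
        )

    append_background(100, 300)
    seqR, featR, ctxR = context_piece(right_idx, "ctxR")
    off = append_raw(seqR)
    featR = CdsFeature(featR.feature_id, featR.start + off, featR.end + off, featR.strand, featR.protein, featR.product)
    ctxR.start += off
    ctxR.end += off
    features.append(featR)
    seg.context.append(ctxR)

    if aip_record is not None:
        seg.aips.append(aip_record)
    seg.features = features
    seg.sequence = "".join(parts)
    return seg


def _append_aip(
    cfg, rng, append_raw, aip_nt, aip_strand, template,
    genome_id, contig_id, reg_id, orientation,
) -> PlantedAip:
    seq, s, e = _place_gene(aip_nt, aip_strand, guard=True)
    off = append_raw(seq)
    return PlantedAip(
        genome_id, contig_id, s + off, e + off, aip_strand,
        template.precursor, template.mature, template.aip_class,
        orientation, reg_id,
    )


def _simple_background(n: int, rng: np.random.Generator, cfg) -> str:
    trans, base = default_background_transitions(cfg.background_gc)
    sampler = _BackgroundSampler(trans, base, cfg.background_markov_order)
    return sampler.sample(n, rng, [t.precursor for t in cfg.aip_templates])


def write_corpus(
    genomes: list[GenomeRecord],
    manifest: GroundTruthManifest,
    baits: BaitAlignment,
    seeds: AipSeedSet,
    outdir: str | Path,
) -> None:
    """Write the corpus in the formats the pipeline reads."""
    from .sequence_io import extract_proteome, write_fasta, write_genbank

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genbank(genomes, outdir / "genomes.gbff")
    for g in genomes:
        prots = extract_proteome(g)
        write_fasta(
            [(p.protein_id, p.sequence) for p in prots],
            outdir / f"{g.genome_id}_translated_cds.faa",
        )
    write_fasta(
        [(f"{bid} {fam} {sub}", seq) for bid, fam, sub, seq in baits.rows],
        outdir / "baits_aligned.fasta",
    )
    write_fasta(
        [(f"{sid} {cls}", seq) for sid, cls, seq in seeds.records],
        outdir / "aip_seeds.fasta",
    )
    manifest.to_json(outdir / "manifest.json")
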