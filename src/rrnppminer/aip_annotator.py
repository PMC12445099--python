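"""Identification and annotation of auto-inducing peptide (AIP) genes.

Short CDSs found near a regulator gene are screened in two ways: by
global-alignment similarity to published AIP seeds (SHP, ComS, PapR, LCP,
MutS classes), and by the sequence grammar of SHP precursors — 20-26
residues, an N-terminal lysine, a C-terminal hydrophobic stretch, often a
terminal glycine and/or a central acidic residue.  The mature SHP is
predicted as the suffix starting at the last aspartate/glutamate in the
C-terminal half of the precursor, reflecting the maturation cleavage that
usually occurs in front of an acidic residue; precursors whose mature
form does not start with D/E are flagged for a per-cluster override
rather than forced through the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .peptide_chem import KYTE_DOOLITTLE
from .sequence_io import CdsFeature
from .short_cds_finder import ShortCdsCandidate

__all__ = [
    "AIP_CLASSES",
    "AipFeatureFlags",
    "AipCandidate",
    "AipSeedSet",
    "read_seed_fasta",
    "score_shp_likeness",
    "predict_mature_form",
    "match_known_aips",
    "assign_orientation",
    "annotate_regulator",
]

AIP_CLASSES = ("SHP", "ComS", "PapR", "LCP", "MutS", "unknown")


@dataclass
class AipFeatureFlags:
    length_in_range: bool
    n_term_lys: bool
    c_term_hydrophobic_stretch: bool
    c_term_gly: bool
    central_acidic: bool

    @property
    def score(self) -> int:
        return sum(
            (
                self.length_in_range,
                self.n_term_lys,
                self.c_term_hydrophobic_stretch,
                self.c_term_gly,
                self.central_acidic,
            )
        )


@dataclass
class AipSeedSet:
    records: list[tuple[str, str, str]]  # (seed_id, class, sequence)

    def __post_init__(self) -> None:
        for _sid, cls, _seq in self.records:
            if cls not in AIP_CLASSES:
                raise ValueError(f"unknown AIP class {cls!r}")


def read_seed_fasta(path: str | Path) -> AipSeedSet:
    """Seed FASTA with the class as the second word of the description."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        cls = parts[1] if len(parts) > 1 else "unknown"
        records.append((rec.id, cls, str(rec.seq)))
    return AipSeedSet(records)


@dataclass
class AipCandidate:
    short_cds: ShortCdsCandidate
    aip_class: str
    flags: AipFeatureFlags
    best_seed: tuple[str, float] | None  # (seed_id, identity_pct)
    mature_form: str | None
    orientation: str | None


def score_shp_likeness(peptide: str) -> tuple[AipFeatureFlags, int]:
    """SHP-precursor feature flags and their count (0-5).

    The hydrophobic C-terminal stretch requires >= 5 consecutive terminal
    residues with positive Kyte-Doolittle hydropathy, glycine tolerated
    (mature SHPs often end in glycine-rich tails).  The N-terminal lysine
    may sit anywhere in the first four residues (precursors start with
    M-K...).  A central acidic residue is a D/E in the C-terminal half
    that is not the last residue.
    """
    if len(peptide) < 7:
        raise ValueError("peptide too short to score")
    n = len(peptide)
    length_in_range = 20 <= n <= 26
    n_term_lys = "K" in peptide[:4]
    stretch = 0
    for ch in reversed(peptide):
        if ch == "G" or KYTE_DOOLITTLE.get(ch, -5.0) > 0:
            stretch += 1
        else:
            break
    c_term_hydrophobic_stretch = stretch >= 5
    c_term_gly = peptide[-1] == "G"
    half = n // 2
    central_acidic = any(ch in "DE" for ch in peptide[half : n - 1])
    flags = AipFeatureFlags(
        length_in_range,
        n_term_lys,
        c_term_hydrophobic_stretch,
        c_term_gly,
        central_acidic,
    )
    return flags, flags.score


def predict_mature_form(precursor: str) -> str | None:
    """Suffix starting at the last D/E in the C-terminal half, else None.

    The acidic residue must not be the final residue (a single-residue
    "mature form" is not a peptide cleavage product).  Returning None
    flags the precursor for a manual/per-cluster override.
    """
    if len(precursor) < 8:
        raise ValueError("precursor too short")
    half = len(precursor) // 2
    for i in range(len(precursor) - 2, half - 1, -1):
        if precursor[i] in "DE":
            return precursor[i:]
    return None


def _global_identity(a: str, b: str) -> float:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    try:
        aln = al.align(a, b)[0]
    except Exception:
        return 0.0
    ident = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for x, y in zip(a[qs:qe], b[ts:te]):
            if x == y:
                ident += 1
    return 100.0 * ident / max(len(a), len(b))


def match_known_aips(
    peptide: str, seeds: AipSeedSet, min_identity: float = 40.0
) -> tuple[str, str, float] | None:
    """Best global-alignment identity to any seed; class transferred when
    identity >= ``min_identity`` percent, else None."""
    if not seeds.records:
        raise ValueError("empty seed set")
    best = None
    for sid, cls, seq in seeds.records:
        ident = _global_identity(peptide, seq)
        if best is None or ident > best[2]:
            best = (sid, cls, ident)
    if best is None or best[2] < min_identity:
        return None
    return best


def assign_orientation(aip_cds: ShortCdsCandidate, regulator_feature: CdsFeature) -> str:
    """Relative gene geometry: divergent / convergent / co_upstream / co_downstream.

    For opposite strands the pair is divergent when the genes point away
    from each other (5' ends adjacent in the middle) and convergent when
    they point toward each other (3' ends adjacent).  For the same strand
    the AIP gene is co_upstream when it lies 5' of the regulator.
    """
    a_start, a_end, a_strand = aip_cds.start, aip_cds.end, aip_cds.strand
    r_start, r_end, r_strand = (
        regulator_feature.start,
        regulator_feature.end,
        regulator_feature.strand,
    )
    a_mid = (a_start + a_end) / 2
    r_mid = (r_start + r_end) / 2
    if a_strand != r_strand:
        left_strand = a_strand if a_mid <= r_mid else r_strand
        # left gene pointing left (-) and right gene pointing right (+)
        # means transcription runs outward from the shared intergenic region
        return "divergent" if left_strand == "-" else "convergent"
    if r_strand == "+":
        return "co_upstream" if a_mid < r_mid else "co_downstream"
    return "co_upstream" if a_mid > r_mid else "co_downstream"


def annotate_regulator(
    regulator_feature: CdsFeature,
    neighborhood_cds: list[ShortCdsCandidate],
    seeds: AipSeedSet | None = None,
    shp_score_min: int = 3,
    seed_min_identity: float = 40.0,
) -> list[AipCandidate]:
    """Annotate neighborhood short CDSs as AIP candidates.

    Classification order: a seed match at or above the identity threshold
    transfers the seed's class; otherwise an SHP-likeness score >= 3 of 5
    calls SHP; otherwise the candidate is "unknown".  Candidates are
    sorted by descending SHP score then position.
    """
    out = []
    for cds in neighborhood_cds:
        peptide = cds.aa_sequence
        if len(peptide) < 7:
            continue
        flags, score = score_shp_likeness(peptide)
        best_seed = None
        aip_class = "unknown"
        if seeds is not None and seeds.records:
            m = match_known_aips(peptide, seeds, min_identity=seed_min_identity)
            if m is not None:
                aip_class = m[1]
                best_seed = (m[0], m[2])
        if aip_class == "unknown" and score >= shp_score_min:
            aip_class = "SHP"
        mature = predict_mature_form(peptide) if len(peptide) >= 8 else None
        orientation = assign_orientation(cds, regulator_feature)
        out.append(
            AipCandidate(
                short_cds=cds,
                aip_class=aip_class,
                flags=flags,
                best_seed=best_seed,
                mature_form=mature,
                orientation=orientation,
            )
        )
    out.sort(key=lambda c: (-c.flags.score, c.short_cds.start))
    return out
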