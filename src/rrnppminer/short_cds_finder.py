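"""Detection of short coding sequences (7-60 aa) on both strands.

Candidate open reading frames (allowed start codon to the first in-frame
stop) are scored with a two-class model: a coding model built from the
codon usage of annotated CDSs versus an order-k Markov background chain
estimated from whole genome sequence.  The reported confidence is the
posterior probability of the coding class,

    confidence = pi * L_C / (pi * L_C + (1 - pi) * L_B),

computed in log space, with prior ``pi`` = 0.5 by default so the 0.01
threshold acts purely on the likelihood ratio.  Both strands are scanned
with exactly the same model (forward sequence and reverse complement),
which makes predictions exactly strand-symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import (
    START_CODONS,
    STOP_CODONS,
    CdsFeature,
    GenomeRecord,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "CdsCompositionModel",
    "ShortCdsCandidate",
    "DetectionConfig",
    "train_cds_model",
    "enumerate_orfs",
    "score_confidence",
    "predict_short_cds",
    "neighborhood_scan",
]

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

_SENSE_CODONS = sorted(
    c1 + c2 + c3
    for c1 in _NT
    for c2 in _NT
    for c3 in _NT
    if c1 + c2 + c3 not in STOP_CODONS
)
_CODON_INDEX = {c: i for i, c in enumerate(_SENSE_CODONS)}


@dataclass
class DetectionConfig:
    min_len_aa: int = 7
    max_len_aa: int = 60
    confidence_min: float = 0.01
    start_codons: tuple[str, ...] = START_CODONS
    stop_codons: tuple[str, ...] = STOP_CODONS


@dataclass
class CdsCompositionModel:
    """Codon-usage coding model plus an order-k Markov background chain."""

    codon_usage: np.ndarray  # (61,) over _SENSE_CODONS
    background_order: int
    background_transitions: np.ndarray  # (4**k, 4), rows sum to 1
    background_initial: np.ndarray  # (4,) marginal nucleotide frequencies
    prior_coding: float = 0.5
    training_genome_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isclose(self.codon_usage.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("codon usage must sum to 1")
        if not np.allclose(self.background_transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("background transition rows must sum to 1")

    # -- log-likelihoods -------------------------------------------------
    def log_coding(self, nt: str) -> float:
        """Log-likelihood under the coding model.

        Sense codons are scored by the usage table.  A terminal stop codon
        is uniform over the three stops; an internal stop contradicts the
        coding hypothesis and is scored with a vanishing probability.
        """
        ll = 0.0
        last = len(nt) - len(nt) % 3 - 3
        for i in range(0, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3]
            if codon in self._stop_set:
                ll += math.log(1.0 / 3.0) if i == last else math.log(1e-9)
            else:
                idx = _CODON_INDEX.get(codon)
                if idx is None:  # codon containing N: neutral
                    ll += 3.0 * math.log(0.25)
                else:
                    ll += math.log(self.codon_usage[idx])
        return ll

    def log_background(self, nt: str) -> float:
        k = self.background_order
        ll = 0.0
        ctx = 0
        have = 0
        for ch in nt:
            b = _NT_INDEX.get(ch)
            if b is None:
                ll += math.log(0.25)
                have = 0
                ctx = 0
                continue
            if have < k:
                ll += math.log(self.background_initial[b])
            else:
                ll += math.log(self.background_transitions[ctx, b])
            ctx = (ctx * 4 + b) % (4**k)
            have = min(have + 1, k)
        return ll

    @property
    def _stop_set(self) -> set[str]:
        return set(STOP_CODONS)


def train_cds_model(
    genomes: list[GenomeRecord],
    background_order: int = 2,
    prior_coding: float = 0.5,
    laplace: float = 1.0,
) -> CdsCompositionModel:
    """Estimate codon usage from annotated CDSs and the background chain
    from full genome sequence, both Laplace-smoothed."""
    codon_counts = np.full(61, laplace)
    k = background_order
    trans_counts = np.full((4**k, 4), laplace)
    init_counts = np.full(4, laplace)
    n_cds = 0
    for g in genomes:
        for contig in g.contigs:
            seq = contig.sequence
            ctx = 0
            have = 0
            for ch in seq:
                b = _NT_INDEX.get(ch)
                if b is None:
                    have = 0
                    ctx = 0
                    continue
                init_counts[b] += 1
                if have >= k:
                    trans_counts[ctx, b] += 1
                ctx = (ctx * 4 + b) % (4**k)
                have = min(have + 1, k)
            for feat in contig.features:
                nt = contig.feature_nt(feat)
                n_cds += 1
                for i in range(0, len(nt) - len(nt) % 3, 3):
                    idx = _CODON_INDEX.get(nt[i : i + 3])
                    if idx is not None:
                        codon_counts[idx] += 1
    if n_cds == 0:
        raise ValueError("no annotated CDS in the training genomes")
    return CdsCompositionModel(
        codon_usage=codon_counts / codon_counts.sum(),
        background_order=k,
        background_transitions=trans_counts / trans_counts.sum(axis=1, keepdims=True),
        background_initial=init_counts / init_counts.sum(),
        prior_coding=prior_coding,
        training_genome_ids=[g.genome_id for g in genomes],
    )


@dataclass
class ShortCdsCandidate:
    contig_id: str
    strand: str
    start: int  # 0-based half-open on the forward axis, stop codon included
    end: int
    aa_sequence: str
    confidence: float

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


def enumerate_orfs(
    sequence: str, cfg: DetectionConfig | None = None
) -> list[tuple[int, int, str]]:
    """All start-to-first-stop spans of 7-60 aa on both strands.

    Returns (start, end, strand) with coordinates on the forward axis and
    the stop codon included in the span.
    """
    cfg = cfg or DetectionConfig()
    spans: list[tuple[int, int, str]] = []
    L = len(sequence)

    def scan(seq: str):
        found = []
        stops = set(cfg.stop_codons)
        starts = set(cfg.start_codons)
        for s in range(len(seq) - 2):
            if seq[s : s + 3] not in starts:
                continue
            # first in-frame stop
            for e in range(s + 3, len(seq) - 2, 3):
                codon = seq[e : e + 3]
                if codon in stops:
                    aa_len = (e - s) // 3
                    if cfg.min_len_aa <= aa_len <= cfg.max_len_aa:
                        found.append((s, e + 3))
                    break
                if (e - s) // 3 > cfg.max_len_aa:
                    break
        return found

    for s, e in scan(sequence):
        spans.append((s, e, "+"))
    rc = reverse_complement(sequence)
    for s, e in scan(rc):
        spans.append((L - e, L - s, "-"))
    spans.sort()
    return spans


def score_confidence(span_sequence: str, model: CdsCompositionModel) -> float:
    """Posterior probability that the span is coding (log-space logistic)."""
    if len(span_sequence) % 3 != 0:
        raise ValueError("span length must be divisible by 3")
    lc = model.log_coding(span_sequence)
    lb = model.log_background(span_sequence)
    pi = model.prior_coding
    # confidence = pi*Lc / (pi*Lc + (1-pi)*Lb), computed stably
    z = (math.log(pi) + lc) - (math.log1p(-pi) + lb)
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def predict_short_cds(
    genome: GenomeRecord,
    model: CdsCompositionModel,
    cfg: DetectionConfig | None = None,
) -> list[ShortCdsCandidate]:
    """Enumerate, score, filter and deduplicate short CDS candidates.

    Nested ORFs sharing a stop codon keep only the longest passing
    candidate.  Output order is deterministic (contig, start, strand).
    """
    cfg = cfg or DetectionConfig()
    out: list[ShortCdsCandidate] = []
    for contig in genome.contigs:
        per_stop: dict[tuple[str, int], ShortCdsCandidate] = {}
        for s, e, strand in enumerate_orfs(contig.sequence, cfg):
            nt = contig.sequence[s:e]
            if strand == "-":
                nt = reverse_complement(nt)
            conf = score_confidence(nt, model)
            if conf < cfg.confidence_min:
                continue
            aa = translate_cds(nt)
            cand = ShortCdsCandidate(
                contig_id=contig.contig_id,
                strand=strand,
                start=s,
                end=e,
                aa_sequence=aa,
                confidence=conf,
            )
            stop_key = (strand, e if strand == "+" else s)
            prev = per_stop.get(stop_key)
            if prev is None or cand.length_aa > prev.length_aa:
                per_stop[stop_key] = cand
        out.extend(
            sorted(per_stop.values(), key=lambda c: (c.contig_id, c.start, c.strand))
        )
    return out


def neighborhood_scan(
    candidates: list[ShortCdsCandidate],
    hit_feature: CdsFeature,
    contig_id: str | None = None,
    window: int = 300,
) -> list[ShortCdsCandidate]:
    """Candidates whose span intersects the +/- ``window`` bp neighborhood.

    The window is [hit.start - window, hit.end + window), clamped at 0;
    intersection is half-open interval overlap.
    """
    lo = max(0, hit_feature.start - window)
    hi = hit_feature.end + window
    kept = []
    for c in candidates:
        if contig_id is not None and c.contig_id != contig_id:
            continue
        if c.start < hi and c.end > lo:
            kept.append(c)
    return kept
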