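"""Generic profile HMM for RRNPP regulator detection.

A single profile HMM is built from a multiple alignment of experimentally
characterized "bait" regulators (Rgg, ComR, PlcR, PrgX families share the
HTH + five-TPR-repeat topology, which is what makes one generic profile
possible).  Proteomes are searched with a local (Smith–Waterman-style)
Viterbi decoder over the plan7-like state graph; per-column posterior
probabilities come from forward–backward over the same graph; E-values are
calibrated by a maximum-likelihood Gumbel fit to Viterbi scores of random
background-composition sequences.

Scoring is log-odds against the Robinson–Robinson background amino-acid
frequencies; insert states emit the background, so unaligned residues are
score-neutral.  Entry is uniform over match states, exit is free from any
match state, and flanking target residues cost nothing — the usual local
alignment semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

__all__ = [
    "AMINO_ACIDS",
    "BACKGROUND_FREQS",
    "BaitAlignment",
    "ProfileHMM",
    "CalibrationParams",
    "HmmHit",
    "HitFilterConfig",
    "RetainedColumnMask",
    "build_profile",
    "calibrate_evalues",
    "search",
    "filter_hits",
    "retained_columns",
    "encode_sequence",
    "read_bait_alignment",
    "write_profile",
    "read_profile",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_LN2 = math.log(2.0)

#: Robinson & Robinson (1991) amino-acid frequencies, the standard null
#: model for protein profile scoring.
BACKGROUND_FREQS = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


def encode_sequence(seq: str) -> np.ndarray:
    """Encode residues as 0..19; X/unknown become the neutral index 20."""
    return np.array([_AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.int64)


@dataclass
class BaitAlignment:
    """Rows of (bait_id, family, subfamily, aligned sequence)."""

    rows: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("bait alignment needs at least 2 rows")
        lengths = {len(r[3]) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("bait alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][3])


def read_bait_alignment(path: str | Path) -> BaitAlignment:
    """Read an aligned FASTA whose headers are ``id family subfamily``."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        family = parts[1] if len(parts) > 1 else "Rgg"
        subfamily = parts[2] if len(parts) > 2 else family
        rows.append((rec.id, family, subfamily, str(rec.seq).upper()))
    return BaitAlignment(rows)


@dataclass
class ProfileHMM:
    M: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    t_mm: np.ndarray  # (M,) P(M_j -> M_{j+1})
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    match_column_map: np.ndarray  # alignment column index per match state
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_FREQS.copy())

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("profile must have at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")

    def match_scores(self) -> np.ndarray:
        """(M, 21) natural-log odds; column 20 is the neutral X score."""
        msc = np.zeros((self.M, 21))
        msc[:, :20] = np.log(self.match_emissions) - np.log(self.background)
        return msc

    def log_transitions(self) -> tuple[np.ndarray, ...]:
        return tuple(
            np.log(t)
            for t in (
                self.t_mm,
                self.t_mi,
                self.t_md,
                self.t_im,
                self.t_ii,
                self.t_dm,
                self.t_dd,
            )
        )


def build_profile(aln: BaitAlignment, pseudocount_weight: float = 1.0) -> ProfileHMM:
    """Estimate a profile HMM from a bait alignment.

    Match states are the alignment columns with gap fraction <= 0.5.
    Match emissions are column residue frequencies blended with the
    background by ``pseudocount_weight`` (total pseudocount mass, spread
    proportionally to the background).  Transitions come from the observed
    gap structure with add-one (Laplace) smoothing.
    """
    n_rows = len(aln.rows)
    cols = np.array([[c for c in r[3]] for r in aln.rows])
    gap_frac = (cols == "-").mean(axis=0)
    match_cols = np.where(gap_frac <= 0.5)[0]
    if match_cols.size == 0:
        raise ValueError("no alignment column has gap fraction <= 0.5")
    M = match_cols.size

    emissions = np.zeros((M, 20))
    for k, c in enumerate(match_cols):
        counts = np.zeros(20)
        for r in range(n_rows):
            a = cols[r, c]
            if a in _AA_INDEX:
                counts[_AA_INDEX[a]] += 1.0
        total = counts.sum()
        emissions[k] = (counts + pseudocount_weight * BACKGROUND_FREQS) / (
            total + pseudocount_weight
        )

    # Transition counts from each row's path through the match columns.
    is_match = np.zeros(aln.n_columns, dtype=bool)
    is_match[match_cols] = True
    c_mm = np.ones(M)  # Laplace smoothing: start every counter at 1
    c_mi = np.ones(M)
    c_md = np.ones(M)
    c_im = np.ones(M)
    c_ii = np.ones(M)
    c_dm = np.ones(M)
    c_dd = np.ones(M)
    for r in range(n_rows):
        prev = None  # ("M"|"I"|"D", match-state index)
        j = -1
        for c in range(aln.n_columns):
            a = cols[r, c]
            if is_match[c]:
                j += 1
                state = ("D", j) if a == "-" else ("M", j)
            elif a != "-":
                state = ("I", j)
            else:
                continue
            if prev is not None:
                ps, pj = prev
                ss, _ = state
                if ps == "M" and ss == "M":
                    c_mm[pj] += 1
                elif ps == "M" and ss == "I":
                    c_mi[pj] += 1
                elif ps == "M" and ss == "D":
                    c_md[pj] += 1
                elif ps == "I" and ss == "M":
                    c_im[pj] += 1
                elif ps == "I" and ss == "I":
                    c_ii[pj] += 1
                elif ps == "D" and ss == "M":
                    c_dm[pj] += 1
                elif ps == "D" and ss == "D":
                    c_dd[pj] += 1
                # D->I / I->D are not representable in the plan7-like graph
            prev = state
    m_tot = c_mm + c_mi + c_md
    i_tot = c_im + c_ii
    d_tot = c_dm + c_dd
    return ProfileHMM(
        M=M,
        match_emissions=emissions,
        insert_emissions=BACKGROUND_FREQS.copy(),
        t_mm=c_mm / m_tot,
        t_mi=c_mi / m_tot,
        t_md=c_md / m_tot,
        t_im=c_im / i_tot,
        t_ii=c_ii / i_tot,
        t_dm=c_dm / d_tot,
        t_dd=c_dd / d_tot,
        match_column_map=match_cols,
    )


# ---------------------------------------------------------------------------
# DP kernels (natural-log units).  State indexing: i = 1..L target position,
# j = 1..M match state; row/col 0 are boundary.  Entry B->M_j is uniform
# (cost ln(1/M)) at any target position; exit from any match state is free;
# flanking target residues are score-neutral.
# ---------------------------------------------------------------------------

_NEG = -1e30


@njit(cache=False)
def _viterbi(msc, lmm, lmi, lmd, lim, lii, ldm, ldd, xs, entry):
    L = xs.shape[0]
    M = msc.shape[0]
    vm = np.full((L + 1, M + 1), _NEG)
    vi = np.full((L + 1, M + 1), _NEG)
    vd = np.full((L + 1, M + 1), _NEG)
    pm = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 entry,1 MM,2 IM,3 DM
    pi = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 MI,1 II
    pd = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 MD,1 DD
    best = _NEG
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        x = xs[i - 1]
        for j in range(1, M + 1):
            e = msc[j - 1, x]
            v = entry
            p = 0
            if j >= 2:
                a = vm[i - 1, j - 1] + lmm[j - 2]
                if a > v:
                    v = a
                    p = 1
                a = vi[i - 1, j - 1] + lim[j - 2]
                if a > v:
                    v = a
                    p = 2
                a = vd[i - 1, j - 1] + ldm[j - 2]
                if a > v:
                    v = a
                    p = 3
            vm[i, j] = e + v
            pm[i, j] = p
            # insert I_j (emits background, score-neutral emission)
            a = vm[i - 1, j] + lmi[j - 1]
            b = vi[i - 1, j] + lii[j - 1]
            if a >= b:
                vi[i, j] = a
                pi[i, j] = 0
            else:
                vi[i, j] = b
                pi[i, j] = 1
            # delete D_j
            if j >= 2:
                a = vm[i, j - 1] + lmd[j - 2]
                b = vd[i, j - 1] + ldd[j - 2]
                if a >= b:
                    vd[i, j] = a
                    pd[i, j] = 0
                else:
                    vd[i, j] = b
                    pd[i, j] = 1
            if vm[i, j] > best:
                best = vm[i, j]
                bi = i
                bj = j
    return vm, vi, vd, pm, pi, pd, best, bi, bj


@njit(cache=False)
def _forward(msc, lmm, lmi, lmd, lim, lii, ldm, ldd, xs, entry):
    L = xs.shape[0]
    M = msc.shape[0]
    fm = np.full((L + 1, M + 1), _NEG)
    fi = np.full((L + 1, M + 1), _NEG)
    fd = np.full((L + 1, M + 1), _NEG)
    total = _NEG
    for i in range(1, L + 1):
        x = xs[i - 1]
        for j in range(1, M + 1):
            v = entry
            if j >= 2:
                v = np.logaddexp(v, fm[i - 1, j - 1] + lmm[j - 2])
                v = np.logaddexp(v, fi[i - 1, j - 1] + lim[j - 2])
                v = np.logaddexp(v, fd[i - 1, j - 1] + ldm[j - 2])
            fm[i, j] = msc[j - 1, x] + v
            fi[i, j] = np.logaddexp(
                fm[i - 1, j] + lmi[j - 1], fi[i - 1, j] + lii[j - 1]
            )
            if j >= 2:
                fd[i, j] = np.logaddexp(
                    fm[i, j - 1] + lmd[j - 2], fd[i, j - 1] + ldd[j - 2]
                )
            total = np.logaddexp(total, fm[i, j])
    return fm, fi, fd, total


@njit(cache=False)
def _backward(msc, lmm, lmi, lmd, lim, lii, ldm, ldd, xs, entry):
    L = xs.shape[0]
    M = msc.shape[0]
    bm = np.full((L + 2, M + 2), _NEG)
    bi_ = np.full((L + 2, M + 2), _NEG)
    bd = np.full((L + 2, M + 2), _NEG)
    for i in range(L, 0, -1):
        for j in range(M, 0, -1):
            v = 0.0  # free exit from any match state
            if j <= M - 1:
                if i <= L - 1:
                    v = np.logaddexp(
                        v, lmm[j - 1] + msc[j, xs[i]] + bm[i + 1, j + 1]
                    )
                v = np.logaddexp(v, lmd[j - 1] + bd[i, j + 1])
            if i <= L - 1:
                v = np.logaddexp(v, lmi[j - 1] + bi_[i + 1, j])
            bm[i, j] = v
            w = _NEG
            if i <= L - 1:
                w = np.logaddexp(w, lii[j - 1] + bi_[i + 1, j])
                if j <= M - 1:
                    w = np.logaddexp(
                        w, lim[j - 1] + msc[j, xs[i]] + bm[i + 1, j + 1]
                    )
            bi_[i, j] = w
            w = _NEG
            if j <= M - 1:
                w = np.logaddexp(w, ldd[j - 1] + bd[i, j + 1])
                if i <= L - 1:
                    w = np.logaddexp(
                        w, ldm[j - 1] + msc[j, xs[i]] + bm[i + 1, j + 1]
                    )
            bd[i, j] = w
    total = _NEG
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            total = np.logaddexp(total, entry + msc[j - 1, xs[i - 1]] + bm[i, j])
    return bm, total


def _dp_inputs(profile: ProfileHMM):
    msc = profile.match_scores()
    logs = profile.log_transitions()
    entry = math.log(1.0 / profile.M)
    return msc, logs, entry


def viterbi_score(profile: ProfileHMM, sequence: str) -> float:
    """Best local alignment score in bits (no traceback)."""
    msc, logs, entry = _dp_inputs(profile)
    xs = encode_sequence(sequence)
    if xs.size == 0:
        return float("-inf")
    *_, best, _bi, _bj = _viterbi(msc, *logs, xs, entry)
    return best / _LN2


def forward_score(profile: ProfileHMM, sequence: str) -> float:
    """Total log-odds (bits) summed over all local alignments."""
    msc, logs, entry = _dp_inputs(profile)
    xs = encode_sequence(sequence)
    *_, total = _forward(msc, *logs, xs, entry)
    return total / _LN2


def backward_score(profile: ProfileHMM, sequence: str) -> float:
    msc, logs, entry = _dp_inputs(profile)
    xs = encode_sequence(sequence)
    *_, total = _backward(msc, *logs, xs, entry)
    return total / _LN2


@dataclass
class CalibrationParams:
    mu: float
    lambda_: float
    n_random: int
    random_seed: int
    db_size_for_evalue: int = 0  # 0 -> use the searched proteome size

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.n_random < 100:
            raise ValueError("calibration needs at least 100 random sequences")

    def evalue(self, bit_score: float, db_size: int) -> float:
        return db_size * math.exp(-self.lambda_ * (bit_score - self.mu))


def calibrate_evalues(
    profile: ProfileHMM,
    n_random: int = 1000,
    seed: int = 0,
    length_dist: int | tuple[int, int] = 350,
) -> CalibrationParams:
    """Gumbel ML fit to Viterbi scores of random background sequences.

    ``length_dist`` is either a fixed length or a (low, high) range sampled
    uniformly.  The fitted location/scale give E(s, D) = D exp(-lambda (s - mu)).
    """
    rng = np.random.default_rng(seed)
    msc, logs, entry = _dp_inputs(profile)
    scores = np.empty(n_random)
    for k in range(n_random):
        if isinstance(length_dist, tuple):
            L = int(rng.integers(length_dist[0], length_dist[1] + 1))
        else:
            L = int(length_dist)
        xs = rng.choice(20, size=L, p=profile.background).astype(np.int64)
        *_, best, _bi, _bj = _viterbi(msc, *logs, xs, entry)
        scores[k] = best / _LN2
    if np.ptp(scores) == 0:
        raise ValueError("degenerate calibration score distribution")
    loc, scale = gumbel_r.fit(scores)
    return CalibrationParams(
        mu=float(loc), lambda_=1.0 / float(scale), n_random=n_random, random_seed=seed
    )


@dataclass
class HmmHit:
    protein_id: str
    genome_id: str
    bit_score: float
    evalue: float
    profile_start: int  # 1-based inclusive over match states
    profile_end: int
    target_start: int  # 1-based inclusive
    target_end: int
    aligned_row: str  # length M, hit projected onto match states
    column_posteriors: np.ndarray  # (M,) in [0, 1]

    @property
    def coverage(self) -> float:
        return (self.profile_end - self.profile_start + 1) / len(self.aligned_row)


@dataclass
class HitFilterConfig:
    evalue_max: float = 1e-5
    profile_start_max: int = 10
    coverage_min: float = 0.90


def _traceback(pm, pi, pd, bi, bj, xs, M):
    """Recover the Viterbi path ending at match state (bi, bj)."""
    path = _viterbi_pairs(pm, pi, pd, bi, bj)
    aligned = ["-"] * M
    for state, i, j in path:
        if state == "M":
            aligned[j - 1] = AMINO_ACIDS[xs[i - 1]] if xs[i - 1] < 20 else "X"
    j_first = path[0][2]
    i_first = path[0][1]
    return "".join(aligned), j_first, bj, i_first, bi, path


def search(
    profile: ProfileHMM,
    proteome: list,
    calib: CalibrationParams,
    report_evalue_max: float = 10.0,
) -> list[HmmHit]:
    """Search a proteome; return hits below the permissive reporting floor.

    ``proteome`` is a list of :class:`~rrnppminer.sequence_io.ProteinRecord`.
    Column posteriors are computed by forward–backward only for reported
    hits.  The E-value database size is the number of proteins searched
    unless the calibration pins ``db_size_for_evalue``.
    """
    msc, logs, entry = _dp_inputs(profile)
    D = calib.db_size_for_evalue or len(proteome)
    hits: list[HmmHit] = []
    for prot in proteome:
        xs = encode_sequence(prot.sequence)
        if xs.size == 0:
            continue
        vm, vi, vd, pm, pi, pd, best, bi, bj = _viterbi(msc, *logs, xs, entry)
        bits = best / _LN2
        ev = calib.evalue(bits, D)
        if ev > report_evalue_max:
            continue
        aligned, j0, j1, i0, i1, state_path = _traceback(
            pm, pi, pd, bi, bj, xs, profile.M
        )
        fm, fi, fd, ftot = _forward(msc, *logs, xs, entry)
        bm, _btot = _backward(msc, *logs, xs, entry)
        # posterior that match state j emits the residue the Viterbi path
        # assigned to it, for every aligned column
        pp = np.zeros(profile.M)
        for st, i, j in state_path:
            if st == "M":
                pp[j - 1] = float(np.exp(fm[i, j] + bm[i, j] - ftot))
        pp = np.clip(pp, 0.0, 1.0)
        hits.append(
            HmmHit(
                protein_id=prot.protein_id,
                genome_id=prot.genome_id,
                bit_score=float(bits),
                evalue=float(ev),
                profile_start=j0,
                profile_end=j1,
                target_start=i0,
                target_end=i1,
                aligned_row=aligned,
                column_posteriors=pp,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.protein_id))
    return hits


def _viterbi_pairs(pm, pi, pd, bi, bj):
    path = []
    state, i, j = "M", bi, bj
    while True:
        path.append((state, i, j))
        if state == "M":
            p = pm[i, j]
            if p == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(p)]
            i, j = i - 1, j - 1
        elif state == "I":
            p = pi[i, j]
            state = "M" if p == 0 else "I"
            i = i - 1
        else:
            p = pd[i, j]
            state = "M" if p == 0 else "D"
            j = j - 1
    path.reverse()
    return path


def filter_hits(hits: list[HmmHit], cfg: HitFilterConfig | None = None) -> list[HmmHit]:
    """Keep hits with E <= max, profile_start <= max and coverage >= min.

    All three thresholds are inclusive; the filter is idempotent and
    order-preserving.
    """
    cfg = cfg or HitFilterConfig()
    return [
        h
        for h in hits
        if h.evalue <= cfg.evalue_max
        and h.profile_start <= cfg.profile_start_max
        and h.coverage >= cfg.coverage_min
    ]


@dataclass
class RetainedColumnMask:
    mask: np.ndarray  # (M,) bool
    pp_threshold: float = 0.85


def retained_columns(hits: list[HmmHit], pp_threshold: float = 0.85) -> RetainedColumnMask:
    """Retain match columns whose mean posterior over aligned hits >= threshold."""
    if not hits:
        raise ValueError("retained_columns needs at least one hit")
    M = len(hits[0].aligned_row)
    sums = np.zeros(M)
    counts = np.zeros(M)
    for h in hits:
        for j, ch in enumerate(h.aligned_row):
            if ch != "-":
                sums[j] += h.column_posteriors[j]
                counts[j] += 1
    mean = np.divide(sums, counts, out=np.zeros(M), where=counts > 0)
    mask = mean >= pp_threshold
    if not mask.any():
        mask[int(np.argmax(mean))] = True
    return RetainedColumnMask(mask=mask, pp_threshold=pp_threshold)


def write_profile(profile: ProfileHMM, path: str | Path) -> None:
    """Serialize emissions/transitions to a text format at 6 decimals."""
    with open(path, "w") as fh:
        fh.write(f"PROFILE M={profile.M}\n")
        fh.write("ALPHABET " + AMINO_ACIDS + "\n")
        fh.write("COLMAP " + " ".join(map(str, profile.match_column_map)) + "\n")
        fh.write("BG " + " ".join(f"{v:.6f}" for v in profile.background) + "\n")
        fh.write("INSERT " + " ".join(f"{v:.6f}" for v in profile.insert_emissions) + "\n")
        for j in range(profile.M):
            fh.write(
                f"MATCH {j + 1} "
                + " ".join(f"{v:.6f}" for v in profile.match_emissions[j])
                + "\n"
            )
            fh.write(
                f"TRANS {j + 1} "
                + " ".join(
                    f"{v:.6f}"
                    for v in (
                        profile.t_mm[j],
                        profile.t_mi[j],
                        profile.t_md[j],
                        profile.t_im[j],
                        profile.t_ii[j],
                        profile.t_dm[j],
                        profile.t_dd[j],
                    )
                )
                + "\n"
            )


def read_profile(path: str | Path) -> ProfileHMM:
    lines = Path(path).read_text().splitlines()
    M = int(lines[0].split("M=")[1])
    colmap = np.array([int(x) for x in lines[2].split()[1:]], dtype=np.int64)
    bg = np.array([float(x) for x in lines[3].split()[1:]])
    insert = np.array([float(x) for x in lines[4].split()[1:]])
    em = np.zeros((M, 20))
    trans = np.zeros((M, 7))
    for line in lines[5:]:
        parts = line.split()
        if parts[0] == "MATCH":
            em[int(parts[1]) - 1] = [float(x) for x in parts[2:]]
        elif parts[0] == "TRANS":
            trans[int(parts[1]) - 1] = [float(x) for x in parts[2:]]
    em = em / em.sum(axis=1, keepdims=True)  # undo 6-decimal rounding drift
    return ProfileHMM(
        M=M,
        match_emissions=em,
        insert_emissions=insert,
        t_mm=trans[:, 0],
        t_mi=trans[:, 1],
        t_md=trans[:, 2],
        t_im=trans[:, 3],
        t_ii=trans[:, 4],
        t_dm=trans[:, 5],
        t_dd=trans[:, 6],
        match_column_map=colmap,
        background=bg,
    )
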