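import math

import numpy as np
import pytest

from rrnppminer import profile_hmm as ph
from rrnppminer.sequence_io import ProteinRecord


def _toy_profile(M=3, seed=0):
    """Small random-but-valid profile for exhaustive-path checks."""
    rng = np.random.default_rng(seed)
    em = rng.dirichlet(np.ones(20) * 0.5, size=M)
    t = rng.dirichlet(np.ones(3), size=M)
    ti = rng.dirichlet(np.ones(2), size=M)
    td = rng.dirichlet(np.ones(2), size=M)
    return ph.ProfileHMM(
        M=M,
        match_emissions=em,
        insert_emissions=ph.BACKGROUND_FREQS.copy(),
        t_mm=t[:, 0], t_mi=t[:, 1], t_md=t[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1],
        t_dm=td[:, 0], t_dd=td[:, 1],
        match_column_map=np.arange(M),
    )


def _enumerate_best_score(profile, sequence):
    """Brute-force maximum over every path through the local state graph."""
    msc = profile.match_scores()
    lmm, lmi, lmd, lim, lii, ldm, ldd = profile.log_transitions()
    xs = ph.encode_sequence(sequence)
    L, M = len(xs), profile.M
    entry = math.log(1.0 / M)
    best = [-math.inf]

    def step(state, i, j, score):
        if state == "M":
            best[0] = max(best[0], score)  # free exit from any match state
            if j < M and i < L:
                step("M", i + 1, j + 1, score + lmm[j - 1] + msc[j, xs[i]])
            if i < L:
                step("I", i + 1, j, score + lmi[j - 1])
            if j < M:
                step("D", i, j + 1, score + lmd[j - 1])
        elif state == "I":
            if i < L:
                step("I", i + 1, j, score + lii[j - 1])
            if j < M and i < L:
                step("M", i + 1, j + 1, score + lim[j - 1] + msc[j, xs[i]])
        else:
            if j < M:
                step("D", i, j + 1, score + ldd[j - 1])
            if j < M and i < L:
                step("M", i + 1, j + 1, score + ldm[j - 1] + msc[j, xs[i]])

    for i0 in range(1, L + 1):
        for j0 in range(1, M + 1):
            step("M", i0, j0, entry + msc[j0 - 1, xs[i0 - 1]])
    return best[0] / math.log(2.0)


class TestBuildProfile:
    def test_identical_ungapped_rows(self):
        aln = ph.BaitAlignment(
            [("a", "Rgg", "SHP/Rgg", "MKVLG"), ("b", "Rgg", "SHP/Rgg", "MKVLG")]
        )
        prof = ph.build_profile(aln)
        assert prof.M == 5
        for j, res in enumerate("MKVLG"):
            k = ph.AMINO_ACIDS.index(res)
            assert prof.match_emissions[j].argmax() == k
            assert prof.match_emissions[j, k] > 0.5

    def test_majority_gap_column_is_not_a_match_state(self):
        rows = [
            ("a", "Rgg", "r", "MK-VL"),
            ("b", "Rgg", "r", "MK-VL"),
            ("c", "Rgg", "r", "MKAVL"),
            ("d", "Rgg", "r", "MK-VL"),
            ("e", "Rgg", "r", "MK-VL"),
        ]
        prof = ph.build_profile(ph.BaitAlignment(rows))
        assert prof.M == 4  # 60% gaps in column 3 -> dropped
        assert list(prof.match_column_map) == [0, 1, 3, 4]

    def test_match_state_count_equals_low_gap_column_count(self, default_corpus):
        _, _, baits, _ = default_corpus
        cols = np.array([[c for c in r[3]] for r in baits.rows])
        expected = int(((cols == "-").mean(axis=0) <= 0.5).sum())
        assert ph.build_profile(baits).M == expected

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            ph.build_profile(
                ph.BaitAlignment([("a", "Rgg", "r", "--"), ("b", "Rgg", "r", "--")])
            )

    def test_emission_rows_are_distributions(self, mini_profile):
        _, prof, _ = mini_profile
        assert np.allclose(prof.match_emissions.sum(axis=1), 1.0, atol=1e-9)

    def test_profile_text_round_trip(self, mini_profile, tmp_path):
        _, prof, _ = mini_profile
        path = tmp_path / "p.hmm"
        ph.write_profile(prof, path)
        back = ph.read_profile(path)
        assert back.M == prof.M
        assert np.allclose(back.match_emissions, prof.match_emissions, atol=1e-5)
        assert np.allclose(back.t_mm, prof.t_mm, atol=1e-5)


class TestViterbiAndPosteriors:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_viterbi_matches_exhaustive_enumeration(self, seed):
        prof = _toy_profile(M=3, seed=seed)
        rng = np.random.default_rng(seed + 10)
        seq = "".join(rng.choice(list(ph.AMINO_ACIDS), size=4))
        assert ph.viterbi_score(prof, seq) == pytest.approx(
            _enumerate_best_score(prof, seq), abs=1e-9
        )

    def test_viterbi_matches_enumeration_on_four_state_profile(self):
        prof = _toy_profile(M=4, seed=7)
        assert ph.viterbi_score(prof, "MKVL") == pytest.approx(
            _enumerate_best_score(prof, "MKVL"), abs=1e-9
        )

    def test_forward_backward_totals_agree(self, mini_profile):
        _, prof, _ = mini_profile
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = "".join(rng.choice(list(ph.AMINO_ACIDS), size=80))
            f = ph.forward_score(prof, seq)
            b = ph.backward_score(prof, seq)
            assert f == pytest.approx(b, abs=1e-6)

    def test_viterbi_never_exceeds_forward(self, mini_profile):
        _, prof, _ = mini_profile
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = "".join(rng.choice(list(ph.AMINO_ACIDS), size=100))
            assert ph.viterbi_score(prof, seq) <= ph.forward_score(prof, seq) + 1e-9

    def test_posteriors_in_unit_interval(self, mini_profile):
        aln, prof, calib = mini_profile
        target = [ProteinRecord("p", "g", "c", 0, 1, "+", aln.rows[0][3])]
        hits = ph.search(prof, target, calib)
        assert hits
        pp = hits[0].column_posteriors
        assert ((pp >= 0) & (pp <= 1)).all()


class TestCalibrationAndSearch:
    def test_evalue_monotone_and_proportional_to_db_size(self):
        calib = ph.CalibrationParams(mu=5.0, lambda_=0.7, n_random=100, random_seed=0)
        assert calib.evalue(10, 100) > calib.evalue(20, 100)
        assert calib.evalue(12.5, 200) == pytest.approx(2 * calib.evalue(12.5, 100))

    def test_calibrated_evalues_are_calibrated_on_fresh_nulls(self, mini_profile):
        _, prof, calib = mini_profile
        rng = np.random.default_rng(99)
        n = 1000
        count = 0
        for _ in range(n):
            seq = "".join(
                np.array(list(ph.AMINO_ACIDS))[
                    rng.choice(20, size=120, p=prof.background)
                ]
            )
            s = ph.viterbi_score(prof, seq)
            if calib.evalue(s, n) <= 1.0:
                count += 1
        assert 0 <= count <= 5

    def test_degenerate_scores_rejected(self):
        aln = ph.BaitAlignment(
            [("a", "Rgg", "r", "MKVLG"), ("b", "Rgg", "r", "MKVLG")]
        )
        prof = ph.build_profile(aln)
        with pytest.raises(ValueError):
            # length-1 targets give an (almost surely) degenerate best score
            ph.calibrate_evalues(prof, n_random=100, seed=0, length_dist=0)

    def test_bait_self_search_is_significant_full_coverage(self, mini_profile):
        aln, prof, calib = mini_profile
        target = [ProteinRecord("bait0", "g", "c", 0, 1, "+", aln.rows[0][3])]
        hits = ph.search(prof, target, calib)
        assert len(hits) == 1
        assert hits[0].evalue < 1e-5
        assert hits[0].coverage >= 0.9

    def test_shuffled_bait_rarely_significant(self, mini_profile):
        aln, prof, calib = mini_profile
        seq = list(aln.rows[0][3])
        rng = np.random.default_rng(12)
        significant = 0
        for _ in range(100):
            rng.shuffle(seq)
            s = ph.viterbi_score(prof, "".join(seq))
            if calib.evalue(s, 1) <= 1e-5:
                significant += 1
        assert significant <= 5

    def test_empty_proteome_gives_no_hits(self, mini_profile):
        _, prof, calib = mini_profile
        assert ph.search(prof, [], calib) == []


class TestHitFiltering:
    def _hit(self, evalue=1e-9, start=1, end=None, M=100):
        end = end if end is not None else M
        return ph.HmmHit(
            "p", "g", 50.0, evalue, start, end, 1, end - start + 1,
            "A" * M, np.ones(M),
        )

    def test_boundary_values_are_kept(self):
        # E = 1e-5, profile_start = 10, coverage = 0.90 all sit exactly on
        # their inclusive thresholds
        hit = self._hit(evalue=1e-5, start=10, end=99, M=100)
        assert hit.coverage == pytest.approx(0.90)
        assert ph.filter_hits([hit]) == [hit]

    def test_rejections_just_past_each_threshold(self):
        assert ph.filter_hits([self._hit(evalue=1e-4)]) == []
        assert ph.filter_hits([self._hit(start=11)]) == []
        assert ph.filter_hits([self._hit(start=1, end=89, M=100)]) == []

    def test_filter_idempotent_and_order_preserving(self):
        hits = [self._hit(evalue=10 ** -(6 + i)) for i in range(5)]
        once = ph.filter_hits(hits)
        assert once == ph.filter_hits(once)
        assert [h.evalue for h in once] == [h.evalue for h in hits]


class TestRetainedColumns:
    def test_all_posterior_one_retains_everything(self):
        hit = ph.HmmHit("p", "g", 1, 1e-9, 1, 4, 1, 4, "ACDE", np.ones(4))
        mask = ph.retained_columns([hit], 0.85)
        assert mask.mask.all()

    def test_low_posterior_column_dropped(self):
        pp = np.array([1.0, 0.5, 1.0, 1.0])
        hit = ph.HmmHit("p", "g", 1, 1e-9, 1, 4, 1, 4, "ACDE", pp)
        mask = ph.retained_columns([hit], 0.85)
        assert list(mask.mask) == [True, False, True, True]

    def test_retained_count_matches_direct_recomputation(self, default_result):
        hits = default_result.filtered_hits
        mask = default_result.mask
        M = len(hits[0].aligned_row)
        expected = 0
        for j in range(M):
            vals = [
                h.column_posteriors[j] for h in hits if h.aligned_row[j] != "-"
            ]
            if vals and float(np.mean(vals)) >= mask.pp_threshold:
                expected += 1
        assert int(mask.mask.sum()) == expected
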