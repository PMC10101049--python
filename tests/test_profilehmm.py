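from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import kstest

from _oracles import enumerate_local_path_scores, random_profile
from rdrpscout import profilehmm as phmm
from rdrpscout.seqio import SeedAlignment

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, length, p=None):
    return "".join(rng.choice(list(AA), size=length, p=p))


class TestBuildProfile:
    def test_identical_rows_give_peaked_emissions(self):
        aln = SeedAlignment("f", [("a", "ACDEF"), ("b", "ACDEF"), ("c", "ACDEF")])
        prof = phmm.build_profile(aln)
        assert prof.M == 5
        assert AA[np.argmax(prof.match_em[0])] == "A"
        assert AA[np.argmax(prof.match_em[4])] == "F"

    def test_majority_gap_column_is_not_match_state(self):
        aln = SeedAlignment(
            "f", [("a", "AC-EF"), ("b", "AC-EF"), ("c", "AC-EF"), ("d", "ACDEF")]
        )
        prof = phmm.build_profile(aln)  # column 3 is 75% gaps
        assert prof.M == 4

    def test_single_sequence_seed_builds_valid_profile(self):
        prof = phmm.build_profile(SeedAlignment("f", [("a", "MKV")]))
        assert prof.M == 3
        prof.validate()

    def test_crop_restricts_columns(self):
        aln = SeedAlignment("f", [("a", "ACDEFGH"), ("b", "ACDEFGH")])
        prof = phmm.build_profile(aln, crop=(2, 5))
        assert prof.M == 3
        assert prof.crop == (2, 5)
        assert AA[np.argmax(prof.match_em[0])] == "D"

    def test_all_gap_crop_rejected(self):
        aln = SeedAlignment("f", [("a", "A--F"), ("b", "A--F")])
        with pytest.raises(ValueError, match="no match columns"):
            phmm.build_profile(aln, crop=(1, 3))


class TestDPOracle:
    """Viterbi and Forward must equal exhaustive path enumeration."""

    @pytest.mark.parametrize("trial", range(25))
    def test_viterbi_and_forward_match_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        M = int(rng.integers(1, 4))
        L = int(rng.integers(1, 6))
        prof = random_profile(rng, M)
        seq = _random_seq(rng, L)
        scores = enumerate_local_path_scores(prof, seq)
        assert scores, "every (M>=1, L>=1) instance admits at least one path"
        expect_vit = max(scores)
        expect_fwd = math.log2(sum(2.0**s for s in scores))
        assert phmm.viterbi_bits(prof, seq) == pytest.approx(expect_vit, abs=1e-9)
        assert phmm.forward_bits(prof, seq) == pytest.approx(expect_fwd, abs=1e-9)

    def test_traceback_span_consistent_with_score(self):
        rng = np.random.default_rng(5)
        prof = random_profile(rng, 3)
        seq = _random_seq(rng, 5)
        hit = phmm.score_sequence(prof, seq)
        assert 1 <= hit.seq_from <= hit.seq_to <= len(seq)
        assert 1 <= hit.prof_from <= hit.prof_to <= prof.M
        assert hit.bit_score == pytest.approx(phmm.viterbi_bits(prof, seq), abs=1e-12)
        mi, mk = hit.match_map
        assert mi[0] == hit.seq_from and mi[-1] == hit.seq_to
        assert mk[0] == hit.prof_from and mk[-1] == hit.prof_to

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            prof = random_profile(rng, int(rng.integers(1, 8)))
            seq = _random_seq(rng, int(rng.integers(1, 30)))
            assert phmm.forward_bits(prof, seq) >= phmm.viterbi_bits(prof, seq) - 1e-12


class TestScoreProperties:
    def test_background_flanks_change_score_at_most_entry_bound(
        self, small_family, small_profile, rng
    ):
        """Appending bg-drawn flanks leaves the local score unchanged up to
        the log2(M) local-entry term."""
        bound = np.log2(small_profile.M)
        core = small_family.members[1][1]
        base = phmm.viterbi_bits(small_profile, core)
        for _ in range(5):
            left = _random_seq(rng, int(rng.integers(0, 40)), p=small_profile.bg)
            right = _random_seq(rng, int(rng.integers(0, 40)), p=small_profile.bg)
            flanked = phmm.viterbi_bits(small_profile, left + core + right)
            assert flanked >= base - 1e-9  # more sequence can only help Viterbi
            assert flanked <= base + bound + 1e-9

    def test_training_member_scores_positive_decoys_nonpositive_mean(
        self, small_family, small_profile, rng
    ):
        member_bits = phmm.viterbi_bits(small_profile, small_family.members[0][1])
        assert member_bits > 50
        decoy_bits = [
            phmm.viterbi_bits(small_profile, _random_seq(rng, 150, p=small_profile.bg))
            for _ in range(30)
        ]
        # local Viterbi max runs slightly positive; far below any true member
        assert np.mean(decoy_bits) < 15
        assert max(decoy_bits) < member_bits / 3

    def test_empty_sequence_rejected(self, small_profile):
        with pytest.raises(ValueError):
            phmm.score_sequence(small_profile, "")


class TestCalibration:
    def test_same_seed_reproduces_parameters(self, small_family):
        prof = phmm.build_profile(small_family.seed_alignment)
        a = phmm.calibrate_profile(prof, n_decoys=500, decoy_len=100, seed=9)
        b = phmm.calibrate_profile(prof, n_decoys=500, decoy_len=100, seed=9)
        assert a.gumbel_mu == b.gumbel_mu
        assert a.gumbel_lambda == b.gumbel_lambda

    def test_p_value_at_mu_is_gumbel_closed_form(self, small_profile):
        assert small_profile.p_value(small_profile.gumbel_mu) == pytest.approx(
            1.0 - math.exp(-1.0), rel=1e-12
        )

    def test_pvalues_uniform_on_fresh_decoys(self, small_profile):
        """Kolmogorov-Smirnov check of p-value uniformity at n=5000."""
        rng = np.random.default_rng(77)
        decoys = phmm.sample_decoys(small_profile.bg, 5000, 200, rng)
        from rdrpscout import _dp

        scores = _dp.viterbi_batch(*phmm._batch_args(small_profile, decoys))
        pvals = np.array([small_profile.p_value(s) for s in scores])
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.05

    def test_uncalibrated_pvalue_request_rejected(self, small_family):
        prof = phmm.build_profile(small_family.seed_alignment)
        with pytest.raises(ValueError, match="not calibrated"):
            phmm.score_sequence(prof, "MKV", with_pvalue=True)

    def test_too_few_decoys_rejected(self, small_profile):
        with pytest.raises(ValueError, match=">= 200"):
            phmm.calibrate_profile(small_profile, n_decoys=50)


class TestSearch:
    def test_database_size_smaller_than_orfs_rejected(self, small_profile):
        from rdrpscout.orfs import Orf

        orfs = [
            Orf("c", 1, "+", 0, 0, 30, "MKVLLDQWER"),
            Orf("c", 1, "+", 1, 1, 31, "MKVLLDQWEA"),
        ]
        with pytest.raises(ValueError, match="database_size"):
            phmm.search([small_profile], orfs, database_size=1)

    def test_planted_member_found_decoys_not(self, small_family, small_profile, rng):
        from rdrpscout.orfs import Orf

        member_aa = small_family.heldout_members[0][1]
        orfs = [Orf("vc", 1, "+", 0, 0, 3 * len(member_aa), member_aa)]
        for i in range(50):
            aa = _random_seq(rng, 150, p=small_profile.bg)
            orfs.append(Orf(f"dc{i}", 1, "+", 0, 0, 450, aa))
        hits = phmm.search([small_profile], orfs, p_threshold=1e-6, database_size=10**6)
        assert {h.orf_ref.split("|")[0] for h in hits} == {"vc"}
        assert hits[0].p_value < 1e-20
        assert hits[0].e_value == pytest.approx(hits[0].p_value * 10**6)
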