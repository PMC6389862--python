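"""Profile HMM core: blocks, construction, I/O, Viterbi, calibration."""

import math

import numpy as np
import pytest

from helpers import (all_sequences, enumerate_best_score, path_is_legal,
                     path_score, random_reduced_profile)
from pirsite.profilehmm import (CalibrationError, CalibrationParams,
                                HmmFormatError, ProfileError, ProfileHMM,
                                build_profile, calibrate, extract_site_blocks,
                                read_profile, score_to_evalue, viterbi_align,
                                write_profile)


class TestSiteBlocks:
    def test_single_window(self):
        msa = ["A" * 100, "A" * 100]
        sub, spec = extract_site_blocks(msa, {50}, flank=5)
        assert len(sub[0]) == 11
        assert spec.blocks == [(45, 56)]
        assert spec.source_columns == list(range(45, 56))

    def test_overlapping_windows_merge(self):
        msa = ["A" * 30, "A" * 30]
        _sub, spec = extract_site_blocks(msa, {10, 14}, flank=3)
        assert spec.blocks == [(7, 18)]

    def test_empty_site_set_rejected(self):
        with pytest.raises(ProfileError):
            extract_site_blocks(["AAAA", "AAAA"], set(), flank=1)

    def test_matches_interval_union_oracle(self, rng):
        width = 60
        msa = ["".join(rng.choice(list("ACDE"), size=width)) for _ in range(3)]
        for _ in range(30):
            k = int(rng.integers(1, 6))
            sites = set(int(c) for c in rng.integers(0, width, size=k))
            flank = int(rng.integers(0, 8))
            _sub, spec = extract_site_blocks(msa, sites, flank)
            covered = sorted({c for s in sites
                              for c in range(max(0, s - flank),
                                             min(width, s + flank + 1))})
            assert spec.source_columns == covered
            # blocks are disjoint, increasing, and tile the covered set
            flat = [c for a, b in spec.blocks for c in range(a, b)]
            assert flat == covered
            assert all(b0 < a1 for (_, b0), (a1, _)
                       in zip(spec.blocks, spec.blocks[1:]))


class TestBuildProfile:
    def test_identical_gapless_rows_zero_pseudocount(self):
        hmm = build_profile(["ACDE"] * 4, pseudocount_weight=0.0)
        assert hmm.M == 4
        for k, aa in enumerate("ACDE", start=1):
            assert hmm.match_emissions[k]["ACDEFGHIKLMNPQRSTVWY".index(aa)] \
                == pytest.approx(1.0)

    def test_half_gap_column_is_not_match_state(self):
        msa = ["AC-E", "ACDE", "AC-E", "ACDE"]
        hmm = build_profile(msa, gap_threshold=0.5)
        assert hmm.M == 3  # 0.5 is not strictly below the threshold

    def test_zero_match_columns_rejected(self):
        with pytest.raises(ProfileError):
            build_profile(["--", "--", "AA"], gap_threshold=0.3)

    def test_emissions_match_counting_oracle(self, rng):
        # independent recount: (counts + w*bg) / (n_observed + w)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            nrows = int(rng.integers(3, 7))
            ncols = int(rng.integers(2, 6))
            msa = []
            for _r in range(nrows):
                row = "".join(
                    "-" if rng.random() < 0.2
                    else alphabet[int(rng.integers(0, 20))]
                    for _c in range(ncols))
                msa.append(row)
            w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            try:
                hmm = build_profile(msa, pseudocount_weight=w,
                                    gap_threshold=0.5)
            except ProfileError:
                continue  # all columns gappy at this threshold
            match_cols = [j for j in range(ncols)
                          if sum(r[j] == "-" for r in msa) / nrows < 0.5]
            assert hmm.M == len(match_cols)
            for k, j in enumerate(match_cols, start=1):
                counts = np.zeros(20)
                for r in msa:
                    if r[j] != "-":
                        counts[alphabet.index(r[j])] += 1
                n_obs = counts.sum()
                if n_obs + w > 0:
                    expected = (counts + w / 20) / (n_obs + w)
                    np.testing.assert_allclose(hmm.match_emissions[k],
                                               expected, atol=1e-12)

    def test_probability_conservation(self, rng):
        msa = ["ACDEFG", "AC-EFG", "ACDE-G", "ACDEFG"]
        hmm = build_profile(msa)
        hmm.validate()  # raises if any row/group is off by > 1e-9


class TestHmmIO:
    def test_round_trip_within_tolerance(self, small_hmm):
        again = read_profile(write_profile(small_hmm))
        assert again.M == small_hmm.M
        np.testing.assert_allclose(again.match_emissions,
                                   small_hmm.match_emissions, atol=1e-4)
        np.testing.assert_allclose(again.insert_emissions,
                                   small_hmm.insert_emissions, atol=1e-4)
        np.testing.assert_allclose(again.transitions, small_hmm.transitions,
                                   atol=1e-4)
        np.testing.assert_allclose(again.background, small_hmm.background,
                                   atol=1e-4)
        assert again.calibration is not None
        assert again.calibration.lam == pytest.approx(
            small_hmm.calibration.lam, abs=1e-4)
        assert again.calibration.tau == pytest.approx(
            small_hmm.calibration.tau, abs=1e-4)

    def test_stats_line_populates_calibration(self, small_hmm):
        text = write_profile(small_hmm)
        assert "STATS LOCAL VITERBI" in text
        uncalibrated = ProfileHMM(
            hmm_id=small_hmm.hmm_id,
            match_emissions=small_hmm.match_emissions,
            insert_emissions=small_hmm.insert_emissions,
            transitions=small_hmm.transitions,
            background=small_hmm.background)
        assert "STATS" not in write_profile(uncalibrated)

    def test_truncated_model_reports_line(self, small_hmm):
        lines = write_profile(small_hmm).splitlines()
        truncated = "\n".join(lines[:-4]) + "\n//\n"  # drop the last node
        with pytest.raises(HmmFormatError, match="node"):
            read_profile(truncated)

    def test_missing_terminator(self, small_hmm):
        text = write_profile(small_hmm).replace("//\n", "")
        with pytest.raises(HmmFormatError, match="//"):
            read_profile(text)

    def test_unknown_header_line_preserved(self, small_hmm):
        text = write_profile(small_hmm).replace(
            "ALPH  amino", "ALPH  amino\nDATE  someday")
        again = read_profile(text)
        assert "DATE  someday" in again.extra_header
        assert "DATE  someday" in write_profile(again)

    def test_pyhmmer_parses_our_output(self, small_hmm, tmp_path):
        # the standard toolchain is the independent format oracle
        pyhmmer = pytest.importorskip("pyhmmer")
        # pyhmmer insists on the full STATS trio, so check the plain model
        plain = ProfileHMM(
            hmm_id=small_hmm.hmm_id,
            match_emissions=small_hmm.match_emissions,
            insert_emissions=small_hmm.insert_emissions,
            transitions=small_hmm.transitions,
            background=small_hmm.background)
        path = tmp_path / "tiny.hmm"
        path.write_text(write_profile(plain))
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            model = fh.read()
        assert model.M == small_hmm.M
        theirs = np.asarray(model.match_emissions)[1:]
        np.testing.assert_allclose(theirs, small_hmm.match_emissions[1:],
                                   atol=1e-4)


class TestViterbi:
    def one_node_profile(self):
        me = np.zeros((2, 20))
        me[1, 0] = 1.0  # emits only A
        ie = np.full((2, 20), 1 / 20)
        tr = np.zeros((2, 7))
        tr[0] = [1, 0, 0, 1, 0, 1, 0]
        tr[1] = [1, 0, 0, 1, 0, 1, 0]
        return ProfileHMM("one", me, ie, tr, np.full(20, 1 / 20))

    def test_single_match_closed_form(self):
        aln = viterbi_align(self.one_node_profile(), "A")
        assert aln.state_path == [("M", 1, 1)]
        assert aln.bit_score == pytest.approx(math.log2(20))

    def test_consensus_path_uses_only_match_states(self, small_hmm):
        aln = viterbi_align(small_hmm, small_hmm.consensus)
        assert [k for k, _, _ in aln.state_path] == ["M"] * small_hmm.M

    def test_flanking_residues_are_free(self, small_hmm):
        core = viterbi_align(small_hmm, small_hmm.consensus)
        flanked = viterbi_align(small_hmm, "WW" + small_hmm.consensus + "YY")
        assert flanked.bit_score == pytest.approx(core.bit_score)
        positions = [p for _, _, p in flanked.state_path]
        assert positions == [3, 4, 5, 6]

    def test_empty_sequence_rejected(self, small_hmm):
        with pytest.raises(ProfileError):
            viterbi_align(small_hmm, "")

    def test_score_equals_exhaustive_enumeration(self, rng):
        for M in (1, 2, 3, 4):
            hmm = random_reduced_profile(rng, M)
            for seq in all_sequences("ACD", 4):
                got = viterbi_align(hmm, seq).bit_score
                want = enumerate_best_score(hmm, seq)
                assert got == pytest.approx(want, abs=1e-9), (M, seq)

    def test_paths_are_legal_and_rescore_identically(self, rng):
        for _ in range(20):
            M = int(rng.integers(1, 6))
            hmm = random_reduced_profile(rng, M)
            n = int(rng.integers(1, 9))
            seq = "".join(rng.choice(list("ACD"), size=n))
            aln = viterbi_align(hmm, seq)
            assert path_is_legal(hmm, aln.state_path, seq)
            assert path_score(hmm, aln.state_path, seq) == pytest.approx(
                aln.bit_score, abs=1e-9)

    def test_background_profile_never_scores_positive(self, rng):
        bg = np.full(20, 1 / 20)
        me = np.tile(bg, (4, 1))
        me = np.vstack([np.zeros(20), me])
        ie = np.tile(bg, (5, 1))
        tr = np.zeros((5, 7))
        for k in range(5):
            tr[k] = [0.8, 0.1, 0.1, 0.7, 0.3, 0.7, 0.3]
        hmm = ProfileHMM("bg", me, ie, tr, bg)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=int(rng.integers(1, 15))))
            assert viterbi_align(hmm, seq).bit_score <= 1e-9

    def test_deterministic(self, small_hmm):
        a = viterbi_align(small_hmm, "AGDEACDE")
        b = viterbi_align(small_hmm, "AGDEACDE")
        assert a.state_path == b.state_path and a.bit_score == b.bit_score

    def test_ambiguity_codes_score_background(self, small_hmm):
        # X at every position: all emissions log-odds 0, score = transitions only
        aln = viterbi_align(small_hmm, "X" * small_hmm.M)
        assert aln.bit_score <= 0.0


class TestEvalues:
    def test_score_at_tau_gives_one(self):
        calib = CalibrationParams(lam=0.7, tau=3.0)
        assert score_to_evalue(3.0, calib, Z=1) == pytest.approx(1.0)

    def test_stated_formula(self):
        calib = CalibrationParams(lam=0.69, tau=5.0)
        assert score_to_evalue(25.0, calib, Z=1) == pytest.approx(
            math.exp(-0.69 * 20), rel=1e-12)
        assert score_to_evalue(25.0, calib, Z=1) == pytest.approx(1.0e-6,
                                                                  rel=0.05)

    def test_monotone_and_clamped(self):
        calib = CalibrationParams(lam=0.5, tau=0.0)
        scores = [-10, -1, 0, 1, 10, 100]
        evalues = [score_to_evalue(s, calib, Z=1) for s in scores]
        assert all(a >= b for a, b in zip(evalues, evalues[1:]))
        assert evalues[0] == 1.0  # clamped at Z
        assert evalues[-1] >= 0.0

    def test_missing_calibration_instructs(self):
        with pytest.raises(CalibrationError, match="calibrate"):
            score_to_evalue(10.0, None)


class TestCalibrate:
    def test_deterministic_given_seed(self, small_hmm):
        a = calibrate(small_hmm, n=60, length=15, seed=7)
        b = calibrate(small_hmm, n=60, length=15, seed=7)
        assert (a.lam, a.tau, a.n_calib) == (b.lam, b.tau, b.n_calib)

    def test_minimum_sample_size(self, small_hmm):
        with pytest.raises(CalibrationError):
            calibrate(small_hmm, n=10)

    def test_degenerate_scores_rejected(self):
        # a background-equal single-node profile scores every sequence 0
        bg = np.full(20, 1 / 20)
        me = np.vstack([np.zeros(20), bg])
        ie = np.tile(bg, (2, 1))
        tr = np.zeros((2, 7))
        tr[0] = [1, 0, 0, 1, 0, 1, 0]
        tr[1] = [1, 0, 0, 1, 0, 1, 0]
        hmm = ProfileHMM("flat", me, ie, tr, bg)
        with pytest.raises(CalibrationError, match="degenerate"):
            calibrate(hmm, n=60, length=5, seed=1)

    def test_lambda_stable_under_resampling(self, small_hmm):
        a = calibrate(small_hmm, n=200, length=20, seed=1)
        b = calibrate(small_hmm, n=2000, length=20, seed=2)
        assert abs(a.lam - b.lam) / b.lam < 0.25
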