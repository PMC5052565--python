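import numpy as np
import pytest

import lncclass as lc
from lncclass import features as ft
from lncclass.seqio import TranscriptRecord


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def orf_oracle(seq):
    """Exhaustive every-ATG scan over the three forward frames."""
    best = (0, 0, 0)  # (length, start, frame) with min on (start, frame) at ties
    n = len(seq)
    for frame in range(3):
        for pos in range(frame, n - 2, 3):
            if seq[pos : pos + 3] != "ATG":
                continue
            end = pos + 3
            complete = False
            q = pos + 3
            while q + 3 <= n:
                if seq[q : q + 3] in ft.STOP_CODONS:
                    end = q + 3
                    complete = True
                    break
                q += 3
            if not complete:
                end = q
            length = end - pos
            if length > best[0] or (
                length == best[0] and length > 0 and (pos, frame) < (best[1], best[2])
            ):
                best = (length, pos, frame)
    return best  # (length, start, frame)


class TestFindOrf:
    def test_complete_orf_hand_case(self):
        orf = ft.find_orf("ATGAAATAG")
        assert (orf.frame, orf.start, orf.length, orf.complete) == (0, 0, 9, True)
        assert orf.coverage == 1.0

    def test_no_start_codon_gives_empty(self):
        orf = ft.find_orf("CCCCCC")
        assert orf.length == 0 and orf.coverage == 0.0

    def test_incomplete_orf_runs_to_last_codon(self):
        # no stop: ORF extends to the last complete codon boundary
        orf = ft.find_orf("ATGAAAAAAAA")  # 11 nt
        assert orf.length == 9 and not orf.complete

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            seq = random_seq(rng, 300)
            orf = ft.find_orf(seq)
            length, start, frame = orf_oracle(seq)
            assert orf.length == length
            if length > 0:
                assert (orf.start, orf.frame) == (start, frame)


class TestFickett:
    def test_deterministic(self):
        s = "ATGGCATTTACCGGA"
        assert ft.fickett_score(s) == ft.fickett_score(s)

    def test_position_class_shuffle_invariance(self):
        # permuting bases within each codon-position class preserves both the
        # per-position counts and the composition, hence the score
        s = "ATGGCAGCTGAAGCT"
        shuffled = "".join(
            s[i] for i in [12, 1, 2, 3, 4, 5, 0, 7, 8, 9, 10, 11, 6, 13, 14]
        )
        assert sorted(s[0::3]) == sorted(shuffled[0::3])
        assert ft.fickett_score(s) == pytest.approx(ft.fickett_score(shuffled))

    def test_frozen_sixty_nt_regression_value(self):
        # value computed once from the published 1982 lookup tables by an
        # independent transcription of those tables
        s = "ATGGCAGCTGCTGAAGCTGCAGAAGCTGCAGCTGAAGAAGCTGCTGCAGAAGCTGCTTAA"
        assert ft.fickett_score(s) == pytest.approx(1.252, abs=1e-9)
        assert ft.fickett_score("ACGT" * 15) == pytest.approx(0.4651, abs=1e-9)

    def test_too_short_is_zero(self):
        assert ft.fickett_score("A") == 0.0


def brute_max_subarray(scores):
    best = None
    for i in range(len(scores)):
        for j in range(i, len(scores)):
            s = float(np.sum(scores[i : j + 1]))
            if best is None or s > best:
                best = s
    return best


class TestMaxSubarray:
    def test_hand_case(self):
        best, i, j = ft.max_subarray(np.array([1.0, -2.0, 3.0, 4.0, -1.0]))
        assert best == 7.0 and (i, j) == (2, 3)

    def test_all_negative_returns_single_max_element(self):
        arr = np.array([-5.0, -1.0, -3.0])
        best, i, j = ft.max_subarray(arr)
        assert best == -1.0 and i == j == 1

    def test_matches_quadratic_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(1, 61))
            arr = rng.normal(size=n)
            best, i, j = ft.max_subarray(arr)
            assert best == pytest.approx(brute_max_subarray(arr), abs=1e-9)
            assert best == pytest.approx(float(arr[i : j + 1].sum()), abs=1e-9)


class TestCodingScorePercentage:
    @pytest.mark.parametrize(
        "s,expected",
        [((3, 3, 3), 1 / 3), ((6, 2, 2), 0.6), ((-1, -2, -3), 1.0), ((0, 0, 0), 1.0)],
    )
    def test_closed_form_cases(self, s, expected):
        assert ft.coding_score_percentage(*s) == pytest.approx(expected)


class TestFindMcss:
    def test_short_sequence_gives_zero_result(self, toy_table):
        res = ft.find_mcss(toy_table, "ACGTA")
        assert res.coding_score == 0.0 and res.length == 0

    def test_span_and_length_convention(self, toy_table):
        rng = np.random.default_rng(31)
        for _ in range(30):
            seq = random_seq(rng, 200)
            res = ft.find_mcss(toy_table, seq)
            k = (res.end - res.start - 3) // 3
            assert res.length == 3 * k + 3 == res.end - res.start
            assert res.start % 3 == res.frame % 3
            assert res.coding_score == max(res.frame_scores)

    def test_per_frame_score_matches_brute_force(self, toy_table):
        rng = np.random.default_rng(37)
        for _ in range(20):
            seq = random_seq(rng, 150)
            res = ft.find_mcss(toy_table, seq)
            for frame in range(3):
                scores = [
                    toy_table.score_of(seq[i : i + 6])
                    for i in range(frame, len(seq) - 5, 3)
                ]
                assert res.frame_scores[frame] == pytest.approx(
                    brute_max_subarray(np.array(scores)), abs=1e-9
                )

    def test_max_run_at_least_total_frame_sum(self, toy_table):
        # the maximal run is never worse than taking the whole frame
        rng = np.random.default_rng(41)
        for _ in range(20):
            seq = random_seq(rng, 120)
            res = ft.find_mcss(toy_table, seq)
            frame = res.frame
            whole = sum(
                toy_table.score_of(seq[i : i + 6])
                for i in range(frame, len(seq) - 5, 3)
            )
            assert res.coding_score >= whole - 1e-9


class TestExonFeatures:
    def test_gc_maximum_over_exons(self, toy_table):
        hs, hsd, gc = ft.exon_features(toy_table, ["ATAT", "GCGC"])
        assert gc == 1.0

    def test_single_exon_identity(self, toy_table):
        seq = "ATGGCCAAATTTGGC" * 4
        hs, hsd, gc = ft.exon_features(toy_table, [seq])
        s_m, d = lc.hexamer_score_and_distance(toy_table, seq)
        assert (hs, hsd) == (s_m, d)
        assert gc == pytest.approx(ft.gc_content(seq))

    def test_maxima_taken_independently_per_feature(self, toy_table):
        rng = np.random.default_rng(43)
        exons = [random_seq(rng, int(rng.integers(30, 200))) for _ in range(5)]
        hs, hsd, gc = ft.exon_features(toy_table, exons)
        per_exon = [
            (*lc.hexamer_score_and_distance(toy_table, e), ft.gc_content(e))
            for e in exons
        ]
        assert hs == max(v[0] for v in per_exon)
        assert hsd == max(v[1] for v in per_exon)
        assert gc == max(v[2] for v in per_exon)


class TestFeatureVector:
    def test_always_eleven_features_in_fixed_order(self, toy_table):
        rec = TranscriptRecord(id="t", sequence="ATGAAATAGACGTACGTACGT")
        vec = ft.feature_vector(toy_table, rec)
        assert vec.shape == (11,)
        assert len(ft.FEATURE_NAMES) == 11

    def test_pure_n_sequence_zeroes_hexamer_features(self, toy_table):
        rec = TranscriptRecord(id="t", sequence="N" * 300)
        vec = dict(zip(ft.FEATURE_NAMES, ft.feature_vector(toy_table, rec)))
        for name in (
            "exon_hexamer_score", "exon_hexamer_distance",
            "orf_hexamer_score", "orf_hexamer_distance",
            "orf_length", "orf_coverage",
        ):
            assert vec[name] == 0.0

    def test_synthetic_coding_transcript_has_positive_signal(self, benchmark_pipeline):
        table = benchmark_pipeline["table"]
        cfg = lc.GeneratorConfig(seed=5, n_coding=5, n_noncoding=0)
        records, truth = lc.generate_dataset(cfg)
        for rec in records:
            vec = dict(zip(ft.FEATURE_NAMES, ft.feature_vector(table, rec)))
            assert 0.0 < vec["orf_coverage"] <= 1.0
            assert vec["mcss_score"] > 0.0

    def test_truncation_hits_orf_length_harder_than_mcss_score(self, benchmark_pipeline):
        # partial-length transcripts lose their ORF anchor points while the
        # frame-structure signal the MCSS measures survives truncation
        table = benchmark_pipeline["table"]
        full_recs, _ = lc.generate_dataset(
            lc.GeneratorConfig(seed=77, n_coding=300, n_noncoding=0, partial_fraction=0.0)
        )
        part_recs, _ = lc.generate_dataset(
            lc.GeneratorConfig(seed=77, n_coding=300, n_noncoding=0, partial_fraction=1.0)
        )
        x_full = lc.feature_matrix(table, full_recs)
        x_part = lc.feature_matrix(table, part_recs)
        names = list(ft.FEATURE_NAMES)
        i_orf, i_mcss = names.index("orf_length"), names.index("mcss_score")
        drop_orf = (x_full[:, i_orf].mean() - x_part[:, i_orf].mean()) / x_full[:, i_orf].mean()
        drop_mcss = (x_full[:, i_mcss].mean() - x_part[:, i_mcss].mean()) / x_full[:, i_mcss].mean()
        assert drop_orf > drop_mcss
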