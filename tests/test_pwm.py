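"""PWM parsing, log-odds scoring, scanning and threshold calibration."""

import numpy as np
import pytest

from metamotif.promoters import reverse_complement
from metamotif.pwm import (
    PWM,
    calibrate_threshold,
    log_odds_matrix,
    naive_scan,
    parse_pwms,
    scan_sequences,
    write_pwms,
)
from metamotif.simulate import simulate_pwm_library


def random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=np.asarray(p)))


class TestParseWrite:
    def test_round_trip_both_dialects(self, tmp_path, pwm_library):
        for dialect in ("transfac", "jaspar"):
            path = tmp_path / f"lib.{dialect}"
            write_pwms(pwm_library, path, dialect)
            parsed = parse_pwms(path, dialect)
            assert [p.matrix_id for p in parsed] == [p.matrix_id for p in pwm_library]
            for a, b in zip(parsed, pwm_library):
                np.testing.assert_allclose(a.counts, b.counts)

    def test_dialect_equivalence(self, tmp_path, pwm_library):
        write_pwms(pwm_library, tmp_path / "t", "transfac")
        write_pwms(pwm_library, tmp_path / "j", "jaspar")
        for a, b in zip(parse_pwms(tmp_path / "t", "transfac"), parse_pwms(tmp_path / "j", "jaspar")):
            np.testing.assert_allclose(a.probabilities, b.probabilities)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PWM(matrix_id="BAD", tf_names=[], counts=[[1, -1, 0, 0]])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            PWM(matrix_id="BAD", tf_names=[], counts=np.empty((0, 4)))


class TestLogOdds:
    def test_dominant_column_value(self):
        # column (8,0,0,0), pseudocount 1, uniform bg:
        # p_A = 8.25/9, cell = log2(0.91667/0.25)
        p = log_odds_matrix(PWM("M", [], [[8, 0, 0, 0]]))
        assert p.log_odds[0, 0] == pytest.approx(np.log2((8.25 / 9) / 0.25), abs=1e-12)
        assert p.log_odds[0, 0] == pytest.approx(1.874, abs=1e-3)

    def test_uniform_column_is_zero_bits(self):
        p = log_odds_matrix(PWM("M", [], [[2, 2, 2, 2]]))
        np.testing.assert_allclose(p.log_odds, 0.0, atol=1e-12)

    def test_background_equal_to_frequencies_is_zero(self):
        p = log_odds_matrix(
            PWM("M", [], [[1, 2, 3, 4]]), background=np.array([0.1, 0.2, 0.3, 0.4]),
            pseudocount=1e-9,
        )
        np.testing.assert_allclose(p.log_odds, 0.0, atol=1e-6)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            log_odds_matrix(PWM("M", [], [[1, 1, 1, 1]]), background=np.array([1, 0, 0, 0]))


class TestScan:
    def test_planted_consensus_found_at_offset(self, sharp_pwm, rng):
        seq = list(random_seq(rng, 100))
        seq[37:43] = "ACGTAC"
        hits = scan_sequences({"p1": "".join(seq)}, sharp_pwm, sharp_pwm.max_score() - 1e-9)
        fw = hits[hits.strand == "+"]
        assert list(fw.start) == [37]

    def test_matches_naive_oracle_exactly(self, pwm_library, rng):
        seqs = {f"p{i}": random_seq(rng, 500) for i in range(10)}
        seqs["with_n"] = seqs["p0"][:200] + "NNNN" + seqs["p0"][200:296]
        for pwm in pwm_library[:3]:
            thr = 0.6 * pwm.max_score()
            fast = scan_sequences(seqs, pwm, thr)
            slow = naive_scan(seqs, pwm, thr)
            assert len(fast) == len(slow)
            assert (fast["score"].to_numpy() == slow["score"].to_numpy()).all()
            assert (fast["start"].to_numpy() == slow["start"].to_numpy()).all()
            assert (fast["strand"].to_numpy() == slow["strand"].to_numpy()).all()

    def test_reverse_complement_coordinate_mirror(self, pwm_library, rng):
        seqs = {f"p{i}": random_seq(rng, 300) for i in range(5)}
        rc = {k: reverse_complement(v) for k, v in seqs.items()}
        for pwm in pwm_library[:3]:
            thr = 0.5 * pwm.max_score()
            fwd = scan_sequences(seqs, pwm, thr)
            mir = scan_sequences(rc, pwm, thr)
            key = lambda df, n: sorted(
                zip(df.promoter_id, df.start, df.strand, np.round(df.score, 9))
            )
            mapped = sorted(
                (pid, 300 - e, {"+": "-", "-": "+"}[s], round(sc, 9))
                for pid, e, s, sc in zip(mir.promoter_id, mir.end, mir.strand, mir.score)
            )
            assert mapped == key(fwd, 300)

    def test_palindrome_hits_both_strands_same_coordinate(self):
        counts = np.full((4, 4), 0.5)
        for i, b in enumerate("ACGT"):  # ACGT is its own reverse complement
            counts[i, "ACGT".index(b)] = 98.5
        pal = log_odds_matrix(PWM("PAL", [], counts))
        hits = scan_sequences({"p": "TTTACGTTTT"}, pal, pal.max_score() - 1e-6)
        assert sorted(zip(hits.start, hits.strand)) == [(3, "+"), (3, "-")]


class TestCalibration:
    def test_rate_on_independent_background(self, sharp_pwm, rng):
        bg = {"b": random_seq(rng, 300_000)}
        cal = calibrate_threshold(sharp_pwm, bg, 1 / 2000)
        assert cal.achieved_rate <= 1 / 2000
        indep = {"b2": random_seq(rng, 300_000)}
        hits = scan_sequences(indep, sharp_pwm, cal.threshold)
        rate = len(hits) / (300_000 - sharp_pwm.length + 1)
        assert rate == pytest.approx(1 / 2000, rel=0.2)

    def test_stricter_target_needs_higher_threshold(self, sharp_pwm, rng):
        bg = {"b": random_seq(rng, 600_000)}
        loose = calibrate_threshold(sharp_pwm, bg, 1 / 500)
        strict = calibrate_threshold(sharp_pwm, bg, 1 / 5000)
        assert strict.threshold >= loose.threshold

    def test_degenerate_target_admits_every_position(self, sharp_pwm, rng):
        bg = {"b": random_seq(rng, 1000)}
        cal = calibrate_threshold(sharp_pwm, bg, 2.5)
        hits = scan_sequences(bg, sharp_pwm, cal.threshold)
        assert len(hits) == 2 * (1000 - sharp_pwm.length + 1)

    def test_background_too_short_rejected(self, sharp_pwm):
        with pytest.raises(ValueError, match="background too short"):
            calibrate_threshold(sharp_pwm, {"b": "ACGT" * 100}, 1 / 2000)

    def test_planted_site_recall(self, rng):
        """Low-entropy planted sites are recovered at the 1/2000 threshold."""
        pwms = simulate_pwm_library(3, length_range=(10, 10), seed=3)
        low_entropy = log_odds_matrix(pwms[0])
        bg = {"b": random_seq(rng, 400_000)}
        cal = calibrate_threshold(low_entropy, bg, 1 / 2000)
        probs = low_entropy.probabilities
        n_planted, found = 200, 0
        for i in range(n_planted):
            seq = list(random_seq(rng, 2000))
            site = "".join(
                "ACGT"[rng.choice(4, p=probs[j])] for j in range(low_entropy.length)
            )
            pos = int(rng.integers(0, 2000 - 10))
            seq[pos : pos + 10] = site
            hits = scan_sequences({"p": "".join(seq)}, low_entropy, cal.threshold)
            if ((hits.start == pos) & (hits.strand == "+")).any():
                found += 1
        assert found / n_planted >= 0.9
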