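"""PWM I/O, similarity/clustering, scoring, calibration and scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cisreg.motifs import (PWM, BackgroundModel, calibrate_threshold, cluster_pwms,
                           pwm_similarity, read_pwms, reverse_complement,
                           scan_regions, score_window, write_pwms)
from conftest import random_dna, random_pwm

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# PWM construction and I/O
# ---------------------------------------------------------------------------

class TestPWMConstruction:
    def test_regularized_columns_sum_to_one(self):
        raw = [[0.97, 0.01, 0.01, 0.01]] * 6
        pwm = PWM.from_matrix("sharp", raw, pseudocount=1e-3)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-6)
        assert (pwm.matrix > 0).all()

    def test_zero_sum_column_rejected(self):
        raw = [[0.25] * 4] * 4
        raw[2] = [0.0] * 4
        with pytest.raises(ValueError, match="sums to 0"):
            PWM.from_matrix("bad", raw)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            PWM.from_matrix("short", [[0.25] * 4] * 3)

    def test_reverse_complement_is_involution(self, rng):
        pwm = random_pwm(rng, length=7)
        assert np.allclose(pwm.reverse_complement().reverse_complement().matrix, pwm.matrix)

    def test_reverse_complement_swaps_bases(self):
        pwm = PWM.from_consensus("m", "AACG", consensus_prob=0.9)
        assert pwm.reverse_complement().consensus() == "CGTT"


class TestMotifIO:
    def test_meme_uniform_record(self, tmp_path):
        path = tmp_path / "u.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF uniform\n"
            "letter-probability matrix: alength= 4 w= 6\n"
            + "0.25 0.25 0.25 0.25\n" * 6)
        (pwm,) = read_pwms(path, format="meme")
        assert pwm.id == "uniform"
        assert np.allclose(pwm.matrix, 0.25)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_probability_table_renormalized(self, tmp_path):
        path = tmp_path / "m.tab"
        path.write_text("# sharp\n" + "0.97\t0.01\t0.01\t0.01\n" * 5)
        (pwm,) = read_pwms(path, format="probability_table", pseudocount=1e-3)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("fmt", ["meme", "probability_table"])
    def test_roundtrip(self, tmp_path, rng, fmt):
        pwms = [random_pwm(rng, length=L, id=f"m{L}") for L in (4, 8, 12)]
        path = tmp_path / f"rt.{fmt}"
        write_pwms(path, pwms, format=fmt)
        # written matrices are already regularized: read back without re-shifting
        back = read_pwms(path, format=fmt, pseudocount=0.0)
        assert [b.id for b in back] == [p.id for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-8)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text("# m1\n0.25\t0.25\t0.25\t0.25\n0.1\t0.2\tnope\t0.5\n")
        with pytest.raises(ValueError, match="line 3"):
            read_pwms(path, format="probability_table")


# ---------------------------------------------------------------------------
# Similarity and clustering
# ---------------------------------------------------------------------------

def brute_force_similarity(a, b, min_overlap=6):
    """Independent exhaustive enumeration of offsets/orientations."""
    best = -np.inf
    for bmat in (b.matrix, b.matrix[::-1, ::-1]):
        la, lb = len(a), len(b)
        for off in range(-lb + 1, la):
            a_lo, a_hi = max(0, off), min(la, off + lb)
            k = a_hi - a_lo
            if k < min_overlap:
                continue
            x = a.matrix[a_lo:a_hi].ravel()
            y = bmat[a_lo - off: a_lo - off + k].ravel()
            # Pearson by the raw-moment formula, not numpy.corrcoef
            n = x.size
            sx = math.sqrt(max(np.sum(x * x) / n - (x.mean()) ** 2, 0))
            sy = math.sqrt(max(np.sum(y * y) / n - (y.mean()) ** 2, 0))
            if sx < 1e-12 or sy < 1e-12:
                r = 1.0 if np.allclose(x, y, atol=1e-9) else 0.0
            else:
                r = (np.sum(x * y) / n - x.mean() * y.mean()) / (sx * sy)
            best = max(best, r)
    return best


class TestSimilarity:
    def test_self_similarity_is_one(self, abox_pwm):
        sim, off, orient = pwm_similarity(abox_pwm, abox_pwm)
        assert sim == pytest.approx(1.0)
        assert (off, orient) == (0, "+")

    def test_reverse_complement_matches_in_reverse_orientation(self, abox_pwm):
        sim, off, orient = pwm_similarity(abox_pwm, abox_pwm.reverse_complement())
        assert sim == pytest.approx(1.0)
        assert orient == "-"

    def test_symmetry(self, rng):
        a, b = random_pwm(rng, 8, id="a"), random_pwm(rng, 10, id="b")
        assert pwm_similarity(a, b)[0] == pytest.approx(pwm_similarity(b, a)[0], abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            a, b = random_pwm(rng, 8, id="a"), random_pwm(rng, 8, id="b")
            assert pwm_similarity(a, b)[0] == pytest.approx(
                brute_force_similarity(a, b), abs=1e-9)

    def test_too_short_motifs_raise(self):
        a = PWM.from_consensus("a", "ACGT", 0.9)
        with pytest.raises(ValueError, match="min_overlap"):
            pwm_similarity(a, a, min_overlap=6)


class TestClustering:
    def test_identical_motifs_form_one_cluster(self, abox_pwm):
        triplicate = [PWM(id=f"m{i}", matrix=abox_pwm.matrix) for i in range(3)]
        out, membership = cluster_pwms(triplicate, sim_threshold=0.8)
        assert len(out) == 1
        assert set(membership.values()) == {0}
        assert np.allclose(out[0].matrix, abox_pwm.matrix, atol=1e-9)

    def test_dissimilar_motifs_stay_singletons(self):
        a = PWM.from_consensus("a", "AAAAAAAA", 0.95)
        b = PWM.from_consensus("b", "ACGCACGC", 0.95)
        out, membership = cluster_pwms([a, b], sim_threshold=0.8)
        assert len(out) == 2
        assert membership == {"a": 0, "b": 1}
        assert out[0] is a and out[1] is b  # singletons pass through unchanged

    def test_planted_partition_recovered(self, rng):
        """3 perturbations of one seed and 2 of another split 3+2."""
        seed_a = PWM.from_consensus("sa", "TTCTAATTAC", 0.9)
        seed_b = PWM.from_consensus("sb", "GGCGCGCCGG", 0.9)
        def perturb(seed, i):
            noisy = seed.matrix + rng.normal(0, 0.01, size=seed.matrix.shape)
            noisy = np.clip(noisy, 1e-4, 1.0)
            return PWM.from_matrix(f"{seed.id}_{i}", noisy / noisy.sum(axis=1, keepdims=True))
        pwms = [perturb(seed_a, i) for i in range(3)] + [perturb(seed_b, i) for i in range(2)]
        out, membership = cluster_pwms(pwms, sim_threshold=0.8)
        assert len(out) == 2
        groups = {}
        for mid, cid in membership.items():
            groups.setdefault(cid, set()).add(mid)
        assert sorted(len(g) for g in groups.values()) == [2, 3]
        # verify the partition against the pairwise similarity structure
        for g in groups.values():
            members = [p for p in pwms if p.id in g]
            for x in members:
                for y in members:
                    assert pwm_similarity(x, y)[0] >= 0.8

    def test_membership_is_partition(self, rng):
        pwms = [random_pwm(rng, 8, id=f"m{i}") for i in range(6)]
        out, membership = cluster_pwms(pwms, sim_threshold=0.8)
        assert sorted(membership) == sorted(p.id for p in pwms)
        assert set(membership.values()) == set(range(len(out)))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self, uniform_bg):
        pwm = PWM.from_matrix("u", [[0.25] * 4] * 6, pseudocount=0.0)
        assert score_window(pwm, "ACGTAC", uniform_bg) == pytest.approx(0.0)

    def test_consensus_hand_value(self, uniform_bg):
        # four positions at P(consensus)=0.97: score = 4 * log2(0.97/0.25)
        raw = [[0.97, 0.01, 0.01, 0.01]] * 4
        pwm = PWM.from_matrix("sharp", raw, pseudocount=0.0)
        expected = 4 * math.log2(0.97 / 0.25)
        assert score_window(pwm, "AAAA", uniform_bg) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch_raises(self, abox_pwm, uniform_bg):
        with pytest.raises(ValueError, match="length"):
            score_window(abox_pwm, "ACGT", uniform_bg)

    def test_n_bases_contribute_zero(self, abox_pwm, uniform_bg):
        full = score_window(abox_pwm, "TTCTAATTAC", uniform_bg)
        with_n = score_window(abox_pwm, "NTCTAATTAC", uniform_bg)
        first = math.log2(abox_pwm.matrix[0, 3] / 0.25)  # T at position 0
        assert with_n == pytest.approx(full - first, abs=1e-9)

    def test_matches_independent_table_lookup(self, rng, uniform_bg):
        pwm = random_pwm(rng, 9)
        for _ in range(20):
            w = random_dna(rng, 9)
            expected = sum(math.log2(pwm.matrix[i, ALPHABET.index(c)] / 0.25)
                           for i, c in enumerate(w))
            assert score_window(pwm, w, uniform_bg) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_fpr_one_lets_every_background_sequence_pass(self, abox_pwm, small_bg):
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=1.0)
        hits = scan_regions(abox_pwm, enumerate(small_bg.sequences), thr,
                            background=small_bg, passing_only=True)
        assert len({h.region_id for h in hits}) == len(small_bg.sequences)

    def test_threshold_equals_sorting_oracle(self, abox_pwm, rng):
        bg = BackgroundModel.iid(10, 60, rng=rng)
        maxima = []
        for seq in bg.sequences:  # independent per-window maximum
            scores = []
            for off in range(len(seq) - 10 + 1):
                w = seq[off:off + 10]
                scores.append(score_window(abox_pwm, w, bg))
                scores.append(score_window(abox_pwm, reverse_complement(w), bg))
            maxima.append(max(scores))
        maxima.sort()
        idx = math.ceil(0.9 * 10) - 1
        thr = calibrate_threshold(abox_pwm, bg, fpr=0.1)
        assert thr.threshold == pytest.approx(maxima[idx], abs=1e-9)
        assert thr.n_background == 10

    @pytest.mark.parametrize("fpr_pair", [(0.01, 0.05), (0.05, 0.2), (0.2, 1.0)])
    def test_threshold_monotone_in_fpr(self, abox_pwm, small_bg, fpr_pair):
        lo, hi = fpr_pair
        t_lo = calibrate_threshold(abox_pwm, small_bg, fpr=lo).threshold
        t_hi = calibrate_threshold(abox_pwm, small_bg, fpr=hi).threshold
        assert t_lo >= t_hi

    def test_invalid_fpr_and_empty_background_raise(self, abox_pwm, small_bg):
        with pytest.raises(ValueError, match="fpr"):
            calibrate_threshold(abox_pwm, small_bg, fpr=0.0)
        with pytest.raises(ValueError, match="no sequences"):
            calibrate_threshold(abox_pwm, BackgroundModel.uniform(), fpr=0.01)

    def test_heldout_fpr_near_nominal(self, rng):
        """Calibrate on half an i.i.d. background, scan the other half.

        Uses a continuous-valued (Dirichlet-noise) motif: heavily
        quantized matrices put large ties in the max-score distribution
        and no single cutoff can then hit the nominal rate.
        """
        from cisreg.simulate import gen_pwm

        fpr = 0.05
        pwm = gen_pwm("TTCTAATTAC", seed=11)
        bg = BackgroundModel.iid(4000, 150, rng=rng)
        train = BackgroundModel.uniform(bg.sequences[:2000])
        thr = calibrate_threshold(pwm, train, fpr=fpr)
        held = bg.sequences[2000:]
        hits = scan_regions(pwm, enumerate(held), thr, passing_only=True)
        rate = len({h.region_id for h in hits}) / len(held)
        tol = 3 * math.sqrt(fpr * (1 - fpr) / len(held))
        assert abs(rate - fpr) <= tol


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def brute_force_scan(pwm, seq, bg):
    """Score every (offset, strand) with the single-window scorer."""
    L = len(pwm)
    out = []
    for off in range(len(seq) - L + 1):
        w = seq[off:off + L]
        fwd = score_window(pwm, w, bg)
        rev = score_window(pwm, reverse_complement(w), bg)
        if fwd >= rev:
            out.append((off, "+", fwd))
        else:
            out.append((off, "-", rev))
    return out


class TestScan:
    def test_equivalent_to_brute_force(self, abox_pwm, rng, uniform_bg):
        seq = random_dna(rng, 500)
        thr = calibrate_threshold(abox_pwm, BackgroundModel.iid(100, 50, rng=rng), fpr=0.1)
        hits = scan_regions(abox_pwm, [("r", seq)], thr)
        expected = brute_force_scan(abox_pwm, seq, uniform_bg)
        assert len(hits) == len(expected)
        for h, (off, strand, score) in zip(hits, expected):
            assert h.offset == off
            assert h.score == pytest.approx(score, abs=1e-9)
            if abs(score - thr.threshold) > 1e-9:
                assert h.passed == (score >= thr.threshold)
        # strand choice must agree wherever the two strands are not tied
        for h, (off, strand, _) in zip(hits, expected):
            w = seq[off:off + len(abox_pwm)]
            margin = abs(score_window(abox_pwm, w, uniform_bg) -
                         score_window(abox_pwm, reverse_complement(w), uniform_bg))
            if margin > 1e-9:
                assert h.strand == strand

    def test_reverse_complement_region_mirrors_hits(self, abox_pwm, rng, small_bg):
        seq = random_dna(rng, 200)
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=0.1)
        fwd_hits = scan_regions(abox_pwm, [("r", seq)], thr, background=small_bg)
        rev_hits = scan_regions(abox_pwm, [("r", reverse_complement(seq))], thr,
                                background=small_bg)
        L, n = len(abox_pwm), len(seq)
        mirrored = sorted((n - L - h.offset, round(h.score, 9)) for h in rev_hits)
        original = sorted((h.offset, round(h.score, 9)) for h in fwd_hits)
        assert mirrored == original

    def test_planted_abox_site_recovered(self, abox_pwm, rng, small_bg):
        flank = random_dna(rng, 45)
        # neutral flanks: avoid accidental TAAT cores
        flank = flank.replace("TAAT", "TGGT").replace("ATTA", "AGGA")
        seq = flank + "TTCTAATTAC" + flank
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=0.01)
        hits = scan_regions(abox_pwm, [("r", seq)], thr, background=small_bg,
                            passing_only=True)
        assert any(h.offset == 45 and h.strand == "+" for h in hits)

    def test_taat_to_tact_mutation_lowers_score(self, abox_pwm, uniform_bg):
        wild = score_window(abox_pwm, "TTCTAATTAC", uniform_bg)
        mutant = score_window(abox_pwm, "TTCTACTTAC", uniform_bg)
        assert mutant < wild

    def test_all_n_region_yields_no_hits(self, abox_pwm, small_bg):
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=0.01)
        hits = scan_regions(abox_pwm, [("r", "N" * 80)], thr, background=small_bg,
                            passing_only=True)
        assert hits == []

    def test_region_shorter_than_motif_yields_no_hits(self, abox_pwm, small_bg):
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=0.01)
        assert scan_regions(abox_pwm, [("r", "ACGT")], thr) == []

    def test_mismatched_threshold_rejected(self, abox_pwm, small_bg):
        thr = calibrate_threshold(abox_pwm, small_bg, fpr=0.01)
        other = PWM.from_consensus("other", "CACGTGCA", 0.9)
        with pytest.raises(ValueError, match="calibrated"):
            scan_regions(other, [("r", "ACGTACGTAC")], thr)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), length=st.integers(12, 120))
def test_scan_matches_brute_force_property(seed, length):
    """Scan output equals exhaustive per-window scoring on random regions."""
    rng = np.random.default_rng(seed)
    pwm = random_pwm(rng, 6)
    bg = BackgroundModel.uniform()
    seq = random_dna(rng, length)
    thr = calibrate_threshold(pwm, BackgroundModel.uniform([random_dna(rng, 40)
                                                            for _ in range(20)]), fpr=0.5)
    hits = scan_regions(pwm, [("r", seq)], thr)
    expected = brute_force_scan(pwm, seq, bg)
    assert [h.offset for h in hits] == [o for o, _, _ in expected]
    assert np.allclose([h.score for h in hits], [sc for _, _, sc in expected], atol=1e-9)
    for h, (off, strand, _) in zip(hits, expected):
        w = seq[off:off + len(pwm)]
        margin = abs(score_window(pwm, w, bg) -
                     score_window(pwm, reverse_complement(w), bg))
        if margin > 1e-9:  # strand must agree except at floating-point ties
            assert h.strand == strand
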