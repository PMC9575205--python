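import itertools
import math

import numpy as np
import pytest

from pioneerindex import (
    GenomicInterval,
    PeakSet,
    PWM,
    MotifScanner,
    count_motifs_per_site,
    pvalue_score_threshold,
    pwm_log_odds,
    read_jaspar_pfm,
    scan_sequence,
)
from pioneerindex.motifs import (
    ALPHABET,
    DEFAULT_PRECISION,
    _discretize,
    _null_distribution,
    reverse_complement,
)

rng = np.random.default_rng(42)


def random_pwm(width, motif_id="rnd", concentration=0.3):
    return PWM(motif_id, rng.dirichlet([concentration] * 4, size=width))


def random_seq(n):
    return "".join(rng.choice(list(ALPHABET), n))


def enumerate_null(int_pssm, background):
    """Exhaustive enumeration of all 4^w words (independent oracle)."""
    w = int_pssm.shape[0]
    dist = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(int_pssm[i, b] for i, b in enumerate(word)))
        p = math.prod(background[b] for b in word)
        dist[s] = dist.get(s, 0.0) + p
    return dist


def brute_force_hits(seq, scanner):
    """Per-offset rescoring of both strands without the vectorized path."""
    w = scanner.width
    mat = scanner._int_pssm
    hits = set()
    for strand in "+-":
        for off in range(len(seq) - w + 1):
            window = seq[off : off + w]
            if any(c not in ALPHABET for c in window):
                continue
            scored = reverse_complement(window) if strand == "-" else window
            s = sum(mat[i, ALPHABET.index(c)] for i, c in enumerate(scored))
            if s >= scanner._int_threshold:
                hits.add((off, strand))
    return hits


class TestLogOdds:
    def test_uniform_pwm_uniform_background_scores_zero(self):
        pwm = PWM("u", np.full((4, 4), 0.25), pseudocount=0.0)
        assert np.allclose(pwm_log_odds(pwm), 0.0)

    def test_hand_computed_single_position(self):
        pwm = PWM("x", np.array([[1.0, 0, 0, 0]]), pseudocount=0.01)
        # regularised p(A) = (1 + 0.01*0.25) / 1.01 = 0.99257...
        p_a = (1 + 0.01 * 0.25) / (1 + 0.01)
        expected = math.log2(p_a / 0.25)
        assert pwm_log_odds(pwm)[0, 0] == pytest.approx(expected)

    def test_invariant_to_count_scaling(self):
        counts = np.array([[8, 2, 1, 1], [1, 1, 9, 1]], dtype=float)
        a = pwm_log_odds(PWM.from_counts("a", counts))
        b = pwm_log_odds(PWM.from_counts("b", 10 * counts))
        assert np.allclose(a, b)

    def test_zero_cell_without_pseudocount_rejected(self):
        pwm = PWM("z", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            pwm_log_odds(pwm)


class TestNullDistribution:
    @pytest.mark.parametrize("width", [2, 3, 5, 8])
    def test_dp_equals_exhaustive_enumeration(self, width):
        pwm = random_pwm(width)
        int_pssm = _discretize(pwm_log_odds(pwm), DEFAULT_PRECISION)
        dp = _null_distribution(int_pssm, pwm.background)
        oracle = enumerate_null(int_pssm, pwm.background)
        assert set(dp) == set(oracle)
        for s in dp:
            assert dp[s] == pytest.approx(oracle[s], abs=1e-12)

    def test_probabilities_sum_to_one(self):
        pwm = random_pwm(6)
        dist = _null_distribution(
            _discretize(pwm_log_odds(pwm), DEFAULT_PRECISION), pwm.background
        )
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_width2_threshold_by_enumeration(self):
        # all 16 dinucleotides equiprobable: tail of 3 top distinct scores
        pwm = random_pwm(2, "w2")
        pssm = pwm_log_odds(pwm)
        int_pssm = _discretize(pssm, DEFAULT_PRECISION)
        scores = sorted(
            (
                int_pssm[0, a] + int_pssm[1, b]
                for a in range(4)
                for b in range(4)
            ),
            reverse=True,
        )
        alpha = 3 / 16
        # oracle: smallest score s with #{words >= s}/16 <= alpha
        candidates = sorted(set(scores))
        ok = [s for s in candidates if sum(x >= s for x in scores) / 16 <= alpha]
        expected = min(ok) * DEFAULT_PRECISION
        got = pvalue_score_threshold(pssm, alpha)
        assert got == pytest.approx(expected)

    def test_alpha_one_gives_minimal_score(self):
        pwm = random_pwm(3)
        pssm = pwm_log_odds(pwm)
        int_pssm = _discretize(pssm, DEFAULT_PRECISION)
        min_score = int(int_pssm.min(axis=1).sum()) * DEFAULT_PRECISION
        assert pvalue_score_threshold(pssm, 1.0) == pytest.approx(min_score)

    def test_unattainable_alpha_warns_and_blocks_all_hits(self):
        pwm = random_pwm(2)
        pssm = pwm_log_odds(pwm)
        with pytest.warns(UserWarning, match="minimal attainable"):
            thr = pvalue_score_threshold(pssm, 1e-9)
        int_pssm = _discretize(pssm, DEFAULT_PRECISION)
        assert thr > int(int_pssm.max(axis=1).sum()) * DEFAULT_PRECISION


class TestScanner:
    def test_sequence_shorter_than_motif_gives_no_hits(self):
        pwm = random_pwm(6)
        assert scan_sequence("ACG", pwm) == []

    def test_embedded_consensus_found_at_recorded_offset(self):
        pwm = PWM.from_counts(
            "sharp",
            np.array([[97, 1, 1, 1]] * 3 + [[1, 97, 1, 1]] * 3),
        )
        seq = "N" * 20 + pwm.consensus + "N" * 20
        hits = scan_sequence(seq, pwm, alpha=1e-3)
        assert [(h.offset, h.strand) for h in hits] == [(20, "+")]
        assert all(h.pvalue <= 1e-3 for h in hits)

    def test_hits_identical_to_brute_force_oracle(self):
        pwm = random_pwm(6, "toy6")
        scanner = MotifScanner(pwm, alpha=0.01)
        for _ in range(100):
            seq = random_seq(50)
            got = {(h.offset, h.strand) for h in scanner.scan(seq)}
            assert got == brute_force_hits(seq, scanner)

    def test_strand_symmetry(self):
        pwm = random_pwm(5)
        scanner = MotifScanner(pwm, alpha=0.05)
        seq = random_seq(80)
        fwd = {(h.offset, h.strand) for h in scanner.scan(seq)}
        rc = {(h.offset, h.strand) for h in scanner.scan(reverse_complement(seq))}
        mapped = {
            (len(seq) - scanner.width - off, "+" if strand == "-" else "-")
            for off, strand in rc
        }
        assert fwd == mapped

    def test_threshold_monotonicity(self):
        pwm = random_pwm(6)
        seq = random_seq(300)
        n_hits = [
            len(MotifScanner(pwm, alpha=a).scan(seq)) for a in (0.1, 0.01, 1e-3)
        ]
        assert n_hits[0] >= n_hits[1] >= n_hits[2]

    def test_windows_containing_n_skipped(self):
        pwm = random_pwm(4)
        # alpha=1 matches every clean window; those crossing the N are absent
        hits = MotifScanner(pwm, alpha=1.0).scan("ACGTNACGT")
        assert {h.offset for h in hits} == {0, 5}

    def test_matches_biopython_pssm_scores(self):
        """Undiscretised log-odds agree with an independent PSSM implementation."""
        from Bio.Seq import Seq
        from Bio import motifs as bio_motifs

        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        pwm = PWM.from_counts("bp", counts, pseudocount=0.0)
        my = pwm_log_odds(pwm)
        m = bio_motifs.Motif(
            alphabet="GATC",
            counts={b: counts[:, i].tolist() for i, b in enumerate(ALPHABET)},
        )
        bio_pssm = m.counts.normalize(pseudocounts=0).log_odds()
        seq = random_seq(40)
        theirs = bio_pssm.calculate(Seq(seq))
        for off in range(len(seq) - 6 + 1):
            mine = sum(my[i, ALPHABET.index(seq[off + i])] for i in range(6))
            assert mine == pytest.approx(float(theirs[off]), abs=1e-6)


class TestMotifCounting:
    def test_all_n_sequence_counts_zero(self):
        pwm = random_pwm(5)
        sites = PeakSet([GenomicInterval("chr1", 0, 30, "s")])
        assert count_motifs_per_site(sites, {"s": "N" * 30}, pwm) == {"s": 0}

    def test_three_nonoverlapping_consensus_copies(self):
        pwm = PWM.from_counts(
            "sharp",
            np.array([[97, 1, 1, 1]] * 2 + [[1, 1, 97, 1]] * 2 + [[1, 1, 1, 97]] * 2),
        )
        seq = ("N" * 5 + pwm.consensus) * 3 + "N" * 5
        sites = PeakSet([GenomicInterval("chr1", 0, len(seq), "s")])
        assert count_motifs_per_site(sites, {"s": seq}, pwm) == {"s": 3}

    def test_missing_chromosome_raises(self):
        pwm = random_pwm(4)
        sites = PeakSet([GenomicInterval("chrX", 0, 30, "s")])
        with pytest.raises(KeyError, match="chrX"):
            count_motifs_per_site(sites, {"chr1": "A" * 100}, pwm)

    def test_null_hit_rate_matches_alpha(self):
        """Mean hits on random sequence ~ 2*(L-w+1)*alpha (both strands)."""
        pwm = random_pwm(6, "null6")
        alpha = 0.01
        scanner = MotifScanner(pwm, alpha=alpha)
        L, trials = 50, 1000
        total = sum(scanner.count(random_seq(L)) for _ in range(trials))
        expected = 2 * (L - 6 + 1) * alpha * trials
        # discretisation makes the realised tail <= alpha; allow Poisson slack
        assert total <= expected + 4 * math.sqrt(expected)
        assert total >= 0.5 * expected - 4 * math.sqrt(expected)


class TestJasparIO:
    JASPAR = ">MA0000.1 TOY\nA [ 10  0  0 ]\nC [  0 10  0 ]\nG [  0  0 10 ]\nT [  0  0  0 ]\n"
    FLAT = "10 0 0\n0 10 0\n0 0 10\n0 0 0\n"

    @pytest.mark.parametrize("text,name", [(JASPAR, "MA0000.1"), (FLAT, "pfm")])
    def test_both_flavours_parse_to_same_matrix(self, tmp_path, text, name):
        p = tmp_path / f"{name}.pfm"
        p.write_text(text)
        pwm = read_jaspar_pfm(p)
        assert pwm.width == 3
        assert pwm.consensus == "ACG"


class TestGenomeSource:
    def test_counts_from_indexed_fasta(self, tmp_path):
        from pioneerindex import GenomicInterval, PeakSet
        from pioneerindex.motifs import load_genome

        pwm = PWM.from_counts(
            "sharp", np.array([[97, 1, 1, 1]] * 3 + [[1, 97, 1, 1]] * 3)
        )
        seq = "T" * 10 + pwm.consensus + "T" * 10
        fasta = tmp_path / "toy.fa"
        fasta.write_text(f">chr1\n{seq}\n")
        genome = load_genome(fasta)
        sites = PeakSet([GenomicInterval("chr1", 5, len(seq), "s")])
        assert count_motifs_per_site(sites, genome, pwm) == {"s": 1}
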