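import itertools
import math

import numpy as np
import pytest

from qrepress.io_formats import GeneModel
from qrepress.motif_scan import (
    IUPAC,
    MotifHit,
    PromoterWindow,
    build_consensus_matrix,
    expand_iupac,
    expected_background_hit_rate,
    extract_promoter_window,
    reverse_complement,
    scan_iupac,
)


def brute_force_scan(seq, motif="CTCGAR", both_strands=True):
    """Independent oracle: test every k-mer against the expanded word sets,
    deduplicating the palindromic double match on span (strand +)."""
    fwd_words = set(expand_iupac(motif))
    rev_words = {reverse_complement(w) for w in fwd_words} if both_strands else set()
    hits = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        word = seq[i : i + m]
        if word in fwd_words:
            hits.append((i, "+", word))
        elif word in rev_words:
            hits.append((i, "-", word))
    return hits


def window(seq, gene="g"):
    return PromoterWindow(gene_id=gene, sequence=seq)


class TestExtraction:
    GENOME = {"chr1": "ACGT" * 500}  # 2000 bp

    def _model(self, start, strand="+"):
        return GeneModel("g", "chr1", strand, start, ((start, start + 100),))

    def test_plus_strand_window_span(self):
        win = extract_promoter_window(self._model(1001), self.GENOME, 800)
        assert win.span == (201, 1000)
        assert len(win) == 800
        assert not win.truncated
        assert win.sequence == self.GENOME["chr1"][200:1000]

    def test_plus_strand_truncated_at_contig_start(self):
        win = extract_promoter_window(self._model(300), self.GENOME, 800)
        assert win.span == (1, 299)
        assert len(win) == 299
        assert win.truncated

    def test_minus_strand_is_reverse_complement_downstream(self):
        contig = "".join(
            "ACGT"[i % 4] for i in range(1800)
        )
        genome = {"chr1": contig}
        win = extract_promoter_window(self._model(1000, "-"), genome, 800)
        assert win.span == (1001, 1800)
        assert win.sequence == reverse_complement(contig[1000:1800])

    def test_start_codon_excluded(self):
        # base at the translational start must not be in the window
        genome = {"chr1": "A" * 99 + "G" + "T" * 100}
        model = GeneModel("g", "chr1", "+", 100, ((100, 150),))
        win = extract_promoter_window(model, genome, 10)
        assert "G" not in win.sequence

    def test_window_below_motif_length_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            extract_promoter_window(self._model(1001), self.GENOME, 5)

    def test_missing_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extract_promoter_window(self._model(1001), {"chr2": "ACGT"}, 800)


class TestScan:
    def test_palindrome_reported_once_plus_strand(self):
        hits = scan_iupac(window("AACTCGAGTT"))
        assert hits == [MotifHit("g", 2, "+", "CTCGAG")]

    def test_reverse_strand_site(self):
        hits = scan_iupac(window("TTCGAGAA"))
        assert hits == [MotifHit("g", 0, "-", "TTCGAG")]
        assert hits[0].oriented_word() == "CTCGAA"

    def test_forward_variant_a(self):
        assert scan_iupac(window("CTCGAA")) == [MotifHit("g", 0, "+", "CTCGAA")]

    def test_short_window_empty(self):
        assert scan_iupac(window("CTCGA")) == []

    def test_forward_only_misses_reverse_site(self):
        assert scan_iupac(window("TTCGAGAA"), both_strands=False) == []

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_iupac(window("ACGTACGT"), motif="CTCGAX")

    def test_hits_sorted_by_offset(self):
        hits = scan_iupac(window("CTCGAG" + "TT" + "CTCGAA"))
        assert [h.offset for h in hits] == sorted(h.offset for h in hits)

    @pytest.mark.parametrize("gc", [0.5, 0.38])
    def test_matches_brute_force_on_random_windows(self, gc):
        rng = np.random.default_rng(42)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        for _ in range(100):
            seq = "".join(np.random.default_rng(rng.integers(2**31)).choice(
                list("ACGT"), size=1000, p=probs))
            got = [(h.offset, h.strand, h.word) for h in scan_iupac(window(seq))]
            assert got == brute_force_scan(seq)

    def test_general_iupac_alphabet(self):
        # N matches everything; B excludes A
        assert len(scan_iupac(window("ACGTAC"), motif="NNNNNN")) == 1
        assert scan_iupac(window("AAAAAA"), motif="BAAAAA", both_strands=False) == []

    def test_strand_symmetry(self):
        """Scanning the reverse complement mirrors offsets and flips strands."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd = scan_iupac(window(seq))
        rev = scan_iupac(window(reverse_complement(seq)))
        mapped = sorted(
            (len(seq) - h.offset - 6, {"+": "+", "-": "-"}[h.strand]) for h in rev
        )
        # a site at offset o maps to len-o-6 on the other strand; the set of
        # double-stranded sites is identical
        assert sorted((h.offset, h.strand in "+-") for h in fwd) == sorted(
            (o, s in "+-") for o, s in mapped
        )
        assert len(fwd) == len(rev)


class TestConsensus:
    def _hits(self, words):
        return [MotifHit(f"g{i}", 0, "+", w) for i, w in enumerate(words)]

    def test_identical_sites_give_two_bits_per_column(self):
        matrix = build_consensus_matrix(self._hits(["CTCGAG"] * 10))
        assert matrix.n_sites == 10
        assert matrix.frequencies[5, 2] == 1.0  # G column
        assert matrix.total_info_bits == pytest.approx(12.0, abs=1e-12)
        assert matrix.consensus() == "CTCGAG"

    def test_half_and_half_last_column(self):
        matrix = build_consensus_matrix(self._hits(["CTCGAG"] * 5 + ["CTCGAA"] * 5))
        freqs = dict(zip("ACGT", matrix.frequencies[5]))
        assert freqs["G"] == pytest.approx(0.5) and freqs["A"] == pytest.approx(0.5)
        assert matrix.info_bits[5] == pytest.approx(1.0, abs=1e-12)
        assert matrix.consensus() == "CTCGAR"

    def test_minus_hits_are_oriented_before_stacking(self):
        hits = [MotifHit("g1", 0, "-", "TTCGAG")]  # site is CTCGAA
        matrix = build_consensus_matrix(hits)
        assert matrix.frequencies[0, 1] == 1.0  # C at position 1

    def test_single_site_columns_sum_to_one(self):
        matrix = build_consensus_matrix(self._hits(["CTCGAA"]))
        assert np.allclose(matrix.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert ((matrix.info_bits >= 0) & (matrix.info_bits <= 2)).all()

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ValueError, match="zero hits"):
            build_consensus_matrix([])


class TestBackgroundRate:
    UNIFORM = {b: 0.25 for b in "ACGT"}

    def test_single_offset_analytic(self):
        expected, _ = expected_background_hit_rate(6, self.UNIFORM)
        assert expected == pytest.approx(3 * 0.25**6, rel=1e-12)

    def test_zero_gc_composition_gives_zero(self):
        comp = {"A": 0.5, "T": 0.5, "C": 0.0, "G": 0.0}
        expected, _ = expected_background_hit_rate(800, comp)
        assert expected == 0.0

    def test_window_shorter_than_motif(self):
        assert expected_background_hit_rate(5, self.UNIFORM) == (0.0, 0.0)

    def test_monte_carlo_matches_direct_simulation(self):
        expected, p_mc = expected_background_hit_rate(
            200, self.UNIFORM, mc_windows=20_000, seed=3
        )
        # independent direct simulation with the string scanner
        rng = np.random.default_rng(12345)
        n, hits = 4000, 0
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            if brute_force_scan(seq):
                hits += 1
        p_direct = hits / n
        se = math.sqrt(p_direct * (1 - p_direct) / n + p_mc * (1 - p_mc) / 20_000)
        assert abs(p_mc - p_direct) <= 3 * se

    def test_expectation_consistent_with_simulation(self):
        comp = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}
        expected, _ = expected_background_hit_rate(800, comp)
        rng = np.random.default_rng(9)
        total = 0
        n = 400
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=800,
                                     p=[comp[b] for b in "ACGT"]))
            total += len(brute_force_scan(seq))
        mean = total / n
        assert abs(mean - expected) < 4 * math.sqrt(expected / n) + 0.05
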