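"""Promoter-window extraction, IUPAC motif scanning and consensus building.

The default motif is the Xbp1 binding consensus ``CTCGAR`` (R = A/G).  Scans
cover both strands by default because transcription-factor sites are
double-stranded; two matches occupying the same span on opposite strands are
one physical site and are reported once (the palindromic ``CTCGAG`` case),
with strand ``+``.

Offsets in :class:`MotifHit` are 0-based within the promoter window; all
genomic coordinates elsewhere are 1-based inclusive.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel

__all__ = [
    "IUPAC",
    "reverse_complement",
    "expand_iupac",
    "PromoterWindow",
    "MotifHit",
    "ConsensusMatrix",
    "extract_promoter_window",
    "scan_iupac",
    "scan_promoters",
    "build_consensus_matrix",
    "expected_background_hit_rate",
]

# Full 15-letter IUPAC nucleotide alphabet.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_SET_TO_LETTER = {bases: letter for letter, bases in IUPAC.items()}

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement, supporting the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("motif is empty")
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letter(s) in motif: {sorted(bad)}")
    return motif


def expand_iupac(motif: str) -> list[str]:
    """Enumerate the concrete words an IUPAC pattern matches."""
    motif = _validate_motif(motif)
    return ["".join(w) for w in itertools.product(*(sorted(IUPAC[c]) for c in motif))]


def _iupac_regex(motif: str) -> re.Pattern[str]:
    # lookahead makes overlapping matches visible
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in motif
    )
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter window in promoter-strand orientation (5'->3' toward ATG).

    ``span`` is the 1-based inclusive genomic interval the window was cut
    from (``None`` for windows built directly from a promoter FASTA), and
    ``truncated`` flags windows clipped at a contig end.
    """

    gene_id: str
    sequence: str
    chrom: str | None = None
    span: tuple[int, int] | None = None
    strand: str = "+"
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One motif match: 0-based ``offset`` of its first base in the window.

    ``word`` is the matched 6-mer as read on the window strand;
    ``strand`` is the strand of the matching site relative to the window.
    """

    gene_id: str
    offset: int
    strand: str
    word: str

    def oriented_word(self) -> str:
        """The site in motif orientation (reverse-complemented for - hits)."""
        return self.word if self.strand == "+" else reverse_complement(self.word)


def extract_promoter_window(
    model: GeneModel, genome: Mapping[str, str], window: int = 800
) -> PromoterWindow:
    """Cut the promoter window upstream of the translational start.

    On ``+`` the window is genomic ``[start-window, start-1]``; on ``-`` it is
    ``[start+1, start+window]`` reverse-complemented.  The start codon itself
    is excluded.  Windows are clamped at contig ends and flagged truncated.
    """
    if window < 6:
        raise ValueError(f"window must be >= 6 bases, got {window}")
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not present in genome")
    contig = genome[model.chrom].upper()
    ts = model.translational_start
    if model.strand == "+":
        lo = max(1, ts - window)
        hi = ts - 1
        seq = contig[lo - 1 : hi] if hi >= lo else ""
        truncated = ts - window < 1
    else:
        lo = ts + 1
        hi = min(len(contig), ts + window)
        seq = reverse_complement(contig[lo - 1 : hi]) if hi >= lo else ""
        truncated = ts + window > len(contig)
    span = (lo, hi) if hi >= lo else (ts, ts - 1)
    return PromoterWindow(
        gene_id=model.gene_id,
        sequence=seq,
        chrom=model.chrom,
        span=span,
        strand=model.strand,
        truncated=truncated,
    )


def scan_iupac(
    window: PromoterWindow,
    motif: str = "CTCGAR",
    both_strands: bool = True,
) -> list[MotifHit]:
    """Find all motif matches in a window, both strands, deduplicated.

    Forward hits match the motif directly; reverse hits are window words
    whose reverse complement matches the motif.  A word matching in both
    orientations is a palindromic double-stranded site and is reported once
    with strand ``+``.  Hits are sorted by offset.
    """
    motif = _validate_motif(motif)
    seq = window.sequence.upper()
    m = len(motif)
    if len(seq) < m:
        return []
    fwd_offsets = {match.start() for match in _iupac_regex(motif).finditer(seq)}
    rev_offsets: set[int] = set()
    if both_strands:
        rc_pattern = reverse_complement(motif)
        rev_offsets = {match.start() for match in _iupac_regex(rc_pattern).finditer(seq)}
    hits = []
    for offset in sorted(fwd_offsets | rev_offsets):
        strand = "+" if offset in fwd_offsets else "-"
        hits.append(
            MotifHit(
                gene_id=window.gene_id,
                offset=offset,
                strand=strand,
                word=seq[offset : offset + m],
            )
        )
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    motif: str = "CTCGAR",
    both_strands: bool = True,
) -> dict[str, list[MotifHit]]:
    """Scan a promoter set (gene id -> window-strand sequence)."""
    return {
        gene: scan_iupac(PromoterWindow(gene_id=gene, sequence=seq), motif, both_strands)
        for gene, seq in promoters.items()
    }


@dataclass(frozen=True)
class ConsensusMatrix:
    """Per-position base frequencies of aligned motif sites.

    ``frequencies`` has shape (motif length, 4) with columns in A, C, G, T
    order; each row sums to 1.  ``info_bits`` is the per-position information
    content, 2 - H (Shannon entropy in bits) against a uniform background.
    """

    frequencies: np.ndarray
    n_sites: int

    @property
    def info_bits(self) -> np.ndarray:
        freqs = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        return 2.0 + terms.sum(axis=1)

    @property
    def total_info_bits(self) -> float:
        return float(self.info_bits.sum())

    def consensus(self, min_frequency: float = 0.25) -> str:
        """IUPAC consensus covering all bases with frequency >= ``min_frequency``."""
        letters = []
        for row in self.frequencies:
            covered = frozenset(
                BASES[i] for i in range(4) if row[i] >= min_frequency - 1e-12
            )
            if not covered:
                covered = frozenset(BASES[int(np.argmax(row))])
            letters.append(_SET_TO_LETTER[covered])
        return "".join(letters)

    def to_text(self) -> str:
        lines = ["pos\tA\tC\tG\tT\tinfo_bits"]
        for i, row in enumerate(self.frequencies):
            vals = "\t".join(f"{v:.4f}" for v in row)
            lines.append(f"{i + 1}\t{vals}\t{self.info_bits[i]:.4f}")
        lines.append(f"# n_sites = {self.n_sites}")
        lines.append(f"# consensus = {self.consensus()}")
        lines.append(f"# total_info_bits = {self.total_info_bits:.4f}")
        return "\n".join(lines) + "\n"


def build_consensus_matrix(
    hits: Iterable[MotifHit],
    windows: Mapping[str, PromoterWindow] | None = None,
    pseudocount: float = 0.0,
) -> ConsensusMatrix:
    """Stack matched sites (motif orientation) into a frequency matrix.

    Minus-strand hits are reverse-complemented before stacking so every row
    of the alignment reads in motif orientation.
    """
    words = []
    for hit in hits:
        if windows is not None and hit.gene_id not in windows:
            raise ValueError(f"hit references unknown window {hit.gene_id!r}")
        words.append(hit.oriented_word())
    if not words:
        raise ValueError("cannot build a consensus matrix from zero hits")
    length = len(words[0])
    if any(len(w) != length for w in words):
        raise ValueError("hit words have inconsistent lengths")
    counts = np.full((length, 4), float(pseudocount))
    base_index = {b: i for i, b in enumerate(BASES)}
    for word in words:
        for pos, base in enumerate(word):
            counts[pos, base_index[base]] += 1.0
    frequencies = counts / counts.sum(axis=1, keepdims=True)
    return ConsensusMatrix(frequencies=frequencies, n_sites=len(words))


# ---------------------------------------------------------------------------
# Background hit rate
# ---------------------------------------------------------------------------

def _event_words(motif: str, both_strands: bool) -> list[str]:
    """Distinct double-stranded match events, as window-strand words.

    Forward words are the motif's expansion; reverse events are words whose
    reverse complement matches, minus those already counted forward
    (palindromes are a single event).
    """
    fwd = set(expand_iupac(motif))
    events = set(fwd)
    if both_strands:
        events |= {reverse_complement(w) for w in fwd}
    return sorted(events)


def expected_background_hit_rate(
    window_length: int,
    base_composition: Mapping[str, float],
    motif: str = "CTCGAR",
    both_strands: bool = True,
    mc_windows: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Expected chance hits in a random window, and optionally P(>=1 hit).

    The per-offset hit probability sums the probabilities of the distinct
    double-stranded events (for ``CTCGAR``: forward CTCGAG, forward CTCGAA
    and reverse CTCGAA, i.e. the word TTCGAG); the expected count multiplies
    by the number of offsets.  Because overlapping offsets are dependent,
    P(>=1) has no simple closed form and is estimated by seeded Monte Carlo
    over ``mc_windows`` random windows when ``mc_windows > 0``.
    """
    total = sum(base_composition.get(b, 0.0) for b in BASES)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"base composition sums to {total}, expected 1")
    motif = _validate_motif(motif)
    m = len(motif)
    if window_length < m:
        return 0.0, 0.0
    events = _event_words(motif, both_strands)
    p_offset = sum(
        float(np.prod([base_composition.get(b, 0.0) for b in word])) for word in events
    )
    n_offsets = window_length - m + 1
    expected = p_offset * n_offsets

    p_ge1: float | None = None
    if mc_windows > 0:
        rng = np.random.default_rng(seed)
        probs = np.array([base_composition.get(b, 0.0) for b in BASES])
        probs = probs / probs.sum() if probs.sum() > 0 else probs
        codes = [np.array([BASES.index(b) for b in w], dtype=np.int8) for w in events]
        n_hit = 0
        chunk = max(1, min(mc_windows, 20_000))
        remaining = mc_windows
        while remaining > 0:
            n = min(chunk, remaining)
            arr = rng.choice(4, size=(n, window_length), p=probs).astype(np.int8)
            any_hit = np.zeros(n, dtype=bool)
            for code in codes:
                match = np.ones((n, n_offsets), dtype=bool)
                for j, cj in enumerate(code):
                    match &= arr[:, j : j + n_offsets] == cj
                any_hit |= match.any(axis=1)
            n_hit += int(any_hit.sum())
            remaining -= n
        p_ge1 = n_hit / mc_windows
    return expected, p_ge1
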