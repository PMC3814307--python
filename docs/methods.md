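# Methods

## The discovery procedure

The pipeline identifies targets of a repressor that is induced at the
diauxic shift (DS) by comparing a deletion strain against wild type across
a time course (8 h log phase; 14 h, the shift; 18 h; 24 h; 48 h; purified
quiescent cells, Q). The underlying model is deliberately simple: if the
repressor silences a gene, removing the repressor elevates that gene's
transcript specifically at the timepoints where the repressor is normally
present — after the shift. The 14 h sample is the shift itself and is
excluded from the default post-DS set `{18, 24, 48, Q}` (configurable).

**Normalization.** Libraries are made comparable with median-of-ratios
size factors: the per-gene reference is the geometric mean across samples,
computed only on genes with nonzero counts everywhere (the geometric mean
is undefined at zero); each sample's factor is the median of count/reference
over those genes, and factors are rescaled to geometric mean 1. An
RPKM-style unit (reads per kilobase of modeled exon per million mapped
reads) is provided as an alternative basis; calling defaults to
size-factor-normalized counts because the selection rule is a fold
threshold, for which the per-gene length denominator cancels.

**Ratio definition.** log2((mutant + p)/(wild type + p)) per timepoint,
replicates averaged after normalization (ratio of means by default; a
paired mean-of-ratios mode exists for replicated designs). The symmetric
pseudocount p (default 0.5 normalized units, added to both strains) keeps
ratios defined at zero counts without directional bias. Note one algebraic
consequence of the geometric-mean-1 convention: rescaling one library by c
rescales *all* normalized counts by √c, so ratio invariance under library
rescaling is exact only at p = 0; with p = 0.5 the effect on a ratio is
O(p/μ) and negligible at typical expression levels.

**Calling.** A gene is derepressed at a timepoint when its log2 ratio is
≥ log2(3) there, and under-represented when ≤ −log2(3); the comparison is
inclusive (an exactly 3-fold change is called) with a 1e−9 relative slop
so that threshold-equal ratios computed through different floating-point
paths are not dropped. Raising the threshold can only shrink call sets.

**Motif scan.** Promoter windows are the 800 bp upstream of the
translational start (the first base of the start codon, itself excluded);
windows are clamped and flagged at contig ends. The binding consensus
`CTCGAR` is matched exactly (no position-weight scoring) on both strands;
a window word whose reverse complement matches is a minus-strand hit, and
a word matching in both orientations (the palindromic `CTCGAG`) is one
physical double-stranded site, reported once on the plus strand. Scanning
forward-only is available to measure the sensitivity of target counts to
this choice. The expected chance hit count in a background window sums the
probabilities of the distinct double-stranded events (forward `CTCGAG`,
forward `CTCGAA`, reverse `CTCGAA`) per offset; because overlapping
offsets are dependent, P(≥1 hit) is estimated by seeded Monte Carlo rather
than a closed form.

**Partition and consensus.** Derepressed ∧ ≥1 site → direct; derepressed
without a site → indirect. The consensus matrix stacks the matched words
(minus-strand hits reverse-complemented into motif orientation), reports
per-column base frequencies and information content 2 − H bits against a
uniform background, and emits the IUPAC letter covering all bases at
frequency ≥ 0.25 per column.

**Oscillation screen.** Cycle profiles are ranked by Pearson correlation
against the average of the z-scored (population SD) seed-gene profiles;
constant profiles get r = 0 and are flagged; ties break lexicographically.
Correlation is computed on linear values — for sinusoidal profiles the
ranking is monotone in phase distance regardless of monotone transforms.

**Enrichment.** One-sided hypergeometric upper tail per category
(via the survival function, evaluated stably in log space), Bonferroni
correction across the categories actually tested (those containing ≥ 1
target gene); Benjamini–Hochberg is available. The universe is the set of
genes in the count matrix — the detected transcriptome, not the
annotation, defines the draw population.

## The synthetic-data generator

The generator is the package's substitute for sequencing data: it encodes
the study conditions and makes every stage testable by parameter recovery.

* **Promoters**: i.i.d. bases at GC fraction 0.38 (yeast-like). Direct
  targets receive exactly one `CTCGA[G/A]` site at a uniform offset,
  uniform strand, uniform G/A variant. All incidental matches — in every
  promoter — are scrubbed by resampling the offending hexamer (re-checked,
  capped at 100 rounds), so the hit-bearing set equals the planted set
  exactly in both directions. Each gene sits on its own contig with the
  promoter at [1, L] and the start codon at L+1.
* **Counts**: negative binomial with mean μ = baseline × depth × effect
  and variance μ + dμ² (dispersion d, default 0.05); baselines are
  integer-rounded log-uniform draws in [20, 2000] (integrality keeps the
  d = 0 degenerate case, rounded deterministic means, exactly
  fold-accurate); per-sample depth factors are log-uniform in [0.5, 2] to
  exercise normalization. The effect (default 5-fold) applies only in the
  deletion strain at post-DS timepoints for the 100 direct + 50 indirect
  planted targets (defaults, of 2,000 genes). The repressor gene itself is
  induced 50-fold in wild type from the shift onward and has zero mean in
  the deletion strain. One replicate per strain/timepoint by default,
  matching the emulated design; replicates are configurable.
* **Cycle profiles**: sin(2πt/T + φ) + N(0, σ), one cycle over T
  timepoints (default 36, σ = 0.3). The repressor has φ = 0, planted
  targets φ = π. Non-target phases are uniform *outside* a π/4 band around
  π: a non-target at φ ≈ π would be statistically indistinguishable from a
  planted anti-phase gene, making the ground-truth labels unidentifiable —
  the guard band is the minimal design that keeps "planted anti-phase"
  a recoverable property at realistic noise. Numerically, at σ = 0.3 with
  fully uniform phases roughly 180 of 1,900 non-targets fall inside the
  noise band of true targets and top-100 recovery collapses to ~50%.
* **Annotation**: every gene receives one of eight background categories;
  ~60% of planted targets are pooled into an additional category so the
  enrichment stage has a planted positive.

What the generator does **not** emulate: read-level error and mapping
ambiguity, gene-length–dependent counting bias, correlated biological
replicates, secondary regulators (every non-target is strictly null), and
non-sinusoidal or multi-period cycle shapes. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated statistical model, not robustness to those real-data complications.

## Numerical choices

* Seeding: `numpy.random.default_rng([seed, stage])` gives each generator
  stage an independent, reproducible stream; identical config and seed
  yield byte-identical files (counts are zero-padded, floats written with
  fixed formats, the manifest carries no timestamps).
* Correlations are clipped to [−1, 1]; "exact" anti-correlation of
  noise-free anti-phase sinusoids holds to machine precision (~1e−16),
  and tests assert it at 1e−12.
* Hypergeometric tails come from the survival function rather than
  summing PMF terms, for stability at genome-scale N.
* Degenerate inputs: constant profiles rank with r = 0 and are flagged;
  constant seed profiles are an error (the reference would be undefined);
  promoters shorter than the motif yield no hits; a window shorter than
  6 bp is rejected at extraction.
* The scan is implemented with compiled regular expressions inside a
  lookahead (overlapping matches); an exhaustive 6-mer oracle in the test
  suite checks equivalence on random windows.

## Scale of the shipped experiments

The regression fixture is a 200-gene study (seed 5) whose inputs are
regenerated from the seed at test time and whose pipeline outputs are
committed verbatim; recovery experiments run at 2,000 genes, the scale at
which the planted effect, dispersion and thresholds interact realistically
while the full suite stays fast. The acceptance script re-runs everything
from scratch at a caller-supplied seed.

## Known limitations

* Exact-match IUPAC scanning only; no PWM-threshold scanning or motif
  discovery.
* No per-gene significance testing (no negative-binomial test); calling is
  a pure fold threshold, so dispersion directly sets the false-positive
  rate at a given threshold.
* Bonferroni across tested categories is conservative when categories
  overlap heavily; no ontology-graph propagation.
* GFF3 only (no GTF); standard gene/mRNA/CDS/exon structures.
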