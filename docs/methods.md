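# Methods

`virocomp` analyses the nucleotide composition of viral genomes and its
coupling to the composition of their hosts.  This note records the models
and procedures the package implements, the choices made where the design
was genuinely open, and what the synthetic data generator does and does
not emulate.

## Compositional quantities

For a genome (possibly deposited as several segments) the package
computes, from base counts pooled over all segments:

* **Genomic GC** — (G+C) / (A+C+G+T/U).  U is unified with T at counting
  time; RNA genomes are stored as deposited.  Any other IUPAC code is
  counted as *ambiguous* and excluded from both numerator and
  denominator.  Segmented genomes are summarised by global counts, never
  by averaging per-segment proportions — the two differ whenever
  segments have unequal lengths.
* **GC1 / GC2 / GC3** — GC fractions at the three codon positions,
  pooled over every CDS of the genome.  CDS sequences are reconstructed
  in reading frame: intervals concatenated in genomic order,
  reverse-complemented for minus-strand features, the GFF3 `phase`
  bases trimmed from the 5' end and any trailing partial codon dropped.
  A codon position holding an ambiguous base is excluded position-wise;
  whole codons are discarded only in codon-usage counting, where a
  partial codon is meaningless.
* **Non-coding GC** — GC of the complement of the union of CDS
  intervals, per segment.  Strand is ignored for the partition, so
  coding + non-coding bases always equal genome length exactly.
  Overlapping CDS are unioned for the partition but counted once per
  CDS for positional GC and codon usage, preserving per-gene reading
  frames while keeping the partition well defined.
* **Codon usage** — counts over all 64 RNA codons, stop codons
  included.  Virus tables are counted from CDS; host tables are read
  from a CoCoPUTs-like TSV (DNA or RNA codon spellings).  Fractions of
  the per-organism total are the default normalization for virus-host
  comparisons, making virus and host tables commensurable regardless of
  the absolute counts behind them; counts per thousand are available.

One genome is kept per taxonomy identifier.  When the metadata offers
several candidate representatives for a TaxID, the one whose sorted
record-id set is lexicographically smallest is kept.  This is a
deterministic stand-in: the upstream curation rule for choosing a
representative assembly is not recoverable from the data, and any fixed
choice serves, provided it is reproducible.

## Statistics

* **Spearman's ρ** (midranks for ties) measures virus-host and
  within-genome compositional association; p-values use the t
  approximation, with exact permutation enumeration available for
  n ≤ 10.  Rank correlation is preferred over Pearson because host and
  virus GC distributions are bounded, skewed and mixture-shaped.
* **OLS fits** report slope, intercept and adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − 2) for the single-predictor case.
* **Hartigans' dip statistic** is the maximum distance between the
  empirical CDF and the nearest unimodal CDF (convex then concave, with
  a jump permitted at the mode).  It is computed by the greatest-convex-
  minorant / least-concave-majorant recursion on a shrinking modal
  interval.  The implementation is validated in the test suite against
  an independent linear-programming oracle that minimises the band
  half-width directly over unimodal CDFs.  One consequence worth
  recording: for n = 4 the dip equals its floor 1/8 exactly when the
  middle inter-point gap is not the strict largest of the three; a
  "two tight pairs" configuration has a strictly larger dip (both
  routes agree, and a forced-slope argument proves it).
* **Dip test** p-values come from a Monte-Carlo bootstrap against the
  uniform null (the least favourable unimodal distribution), default
  2,000 replicates, p = (1 + #{dip_b ≥ dip_obs})/(B + 1).  The null
  depends only on n, so a precomputed null table can be shared across
  tests of equal sample size; results are seeded and reproducible.
  Published quantile tables are deliberately not used: the bootstrap
  works at any n and keeps the package self-contained.  Calibration is
  checked empirically (type-I error within [0.01, 0.10] at α = 0.05).
* **Kernel density estimation** uses a Gaussian kernel with the nrd0
  rule-of-thumb bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5) (a fixed
  bandwidth may be supplied), evaluated on a 512-point grid spanning the
  data range ± 3 bandwidths.  Modes are strict local maxima of the
  gridded density, sorted ascending, with no prominence threshold —
  "shoulders" are not detected.  Two numerical consequences: maxima
  whose density is below 10⁻⁴ of the peak are discarded (floating-point
  ripple in the far tails can fabricate strict maxima at negligible
  density), and a single isolated extreme observation lying several
  bandwidths from the bulk legitimately carries its own kernel bump and
  is reported as a mode.
* **Per-codon coupling** correlates, for each of the 64 codons, the
  virus codon frequency against the host codon frequency across all
  virus-host pairs (Spearman ρ plus the adjusted R² of the linear fit),
  and reports the 64 rows with their medians.  Codons with zero variance
  across pairs yield NaN rows excluded from the medians.

A virus associated with several hosts contributes one pair per host with
equal weight; no down-weighting rule is applied.

## The synthetic data generator

The generator emits complete datasets — FASTA, GFF3, metadata, host
table, host codon tables, virus-host map, truth record — whose
statistical structure emulates the study system at desk scale.  The
defaults are the study conditions:

| parameter | default | why |
|---|---|---|
| hosts per group | bacteria 240, archaea 20, animals 450, fungi 60, plants 220, protists 10 | 260 prokaryotic hosts × 4 viruses ≥ 1,000 phage pairs for coupling recovery; ~3,000 eukaryotic pairs so a null coupling is resolvable (se ≈ 0.018) |
| host GC mixture | N(0.45, 0.07) w 0.65 + N(0.68, 0.04) w 0.35, truncated to [0.13, 0.75] | spans the ~20-75% host range with a high-GC component, as in real host panels |
| phage coupling | GC_phage = −0.04 + 0.90·GC_host + N(0, 0.045), truncated [0.13, 0.77] | programs Spearman ρ ≈ 0.9 and keeps most phages below their host's GC |
| eukaryotic coupling | GC = 0.45 + 0·GC_host + N(0, 0.08) | decoupled, emulating the absent eukaryotic association |
| coding fraction | 0.91 | ~9% median non-coding |
| genome length | uniform 10-20 kb | large enough that realised GC sits within ±0.02 of target (binomial sd ≤ 0.005) while keeping a ~4,000-genome corpus tractable on one CPU |
| segments | 1 (85%), 2 (10%), 3 (5%) | segmented genomes exercise global-count aggregation |
| Baltimore mix | proportional to the seven-class census of the corpus | stratified reports get realistic class sizes |
| gc3_amplification | 2.8; GC1/GC2 response ratio 1.39 | see below |

**Codon-GC model.**  A genome with target GC g gets positional GC
targets p_k = 0.5 + w_k (g − 0.5), where the response weights
(w₁, w₂, w₃) keep the canonical ratios of the three codon positions —
w₁/w₂ = 1.39 and w₃ / mean(w₁, w₂) = `gc3_amplification` — and are
rescaled to mean 1 so coding GC tracks genomic GC.  (Using the observed
per-position slopes directly would make coding GC track only ~0.78 of
genomic GC and the generator could no longer hit its own target-GC
contract; keeping the ratios and renormalising preserves the ordering
and relative steepness, which is what the slope analyses measure.)
Targets are clipped to [0.02, 0.98] with clipped mass redistributed to
the free positions.  Codon probabilities start from the
independent-position product measure; stop codons are removed (ORF
interiors) or down-weighted (host tables, factor 0.05 ≈ genomic stop
frequencies), and iterative proportional fitting restores the positional
marginals.  Host codon tables use the same model driven by host GC, so
phage-host codon correlations emerge from the programmed GC coupling
rather than being inserted directly.

**Genome layout.**  Each segment carries non-overlapping ORFs (ATG
start, stop-terminated, interiors free of in-frame stops) on random
strands, with gene lengths near 900 nt splitting the coding budget and
intergenic gaps i.i.d. at the target GC.  RNA-class genomes are written
with U.  The truth record stores every virus's target GC and the
Spearman ρ actually realised among the drawn targets per host domain —
the "programmed" coupling that pipeline recovery is judged against.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: phylogenetic correlation between viruses
sharing a host clade, dinucleotide-level structure (e.g. CpG
suppression), codon usage shaped by translational selection rather than
GC, overlapping genes, introns/UTRs (non-coding is pure intergenic
sequence), within-genome GC heterogeneity, and the overrepresentation of
particular phage genera that drives some of the density structure seen
in real corpora.  Recovery of the programmed coupling shows the
pipeline's arithmetic is faithful, not that real virus-host coupling has
any particular strength.

## Numerical choices and degenerate inputs

* GC of a region with no unambiguous bases is `None` (distinct from 0);
  genomes without CDS report GC1/2/3 as `None`, written as `NA`.
* CDS whose in-frame length is zero after phase/codon trimming are
  flagged and skipped.
* Strata with n < 3 are reported `NA` rather than raising.
* Correlation/fit statistics on constant input raise `ValueError` in the
  library and are reported `NA` by the pipeline layer.
* Dip requires n ≥ 4; all-equal samples return the floor 1/(2n).
* Report files are byte-reproducible: all randomness flows from the run
  seed, log lines carry no timestamps, and floats are written with fixed
  formats.

## Problem sizes

The shipped test suite and the acceptance script run the generator at
its default scale (~4,000 genomes of 10-20 kb, ~61 Mb of sequence,
4,000 virus-host pairs) plus smaller seeded fixtures; a complete run of
suite plus script takes a few minutes on one CPU.  These sizes were
chosen so that every statistical check has comfortable resolving power
(coupling recovery to ±0.05, null couplings to ±0.05, dip calibration
over 200 × 2,000 bootstrap replicates) while staying desk-scale.
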