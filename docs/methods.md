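# Methods

## What the audit computes

The package treats a genome as a set of validated coding sequences
(CDSs) and asks whether a focal operon's codon usage simultaneously
optimizes translation (efficiency, accuracy, protein cost) and
transcription (nucleotide and elemental economy). The individual
metrics are classical; the contribution is wiring them into one
reproducible, seeded audit with explicit per-set contrasts.

### Genetic code and chemistry tables

The standard bacterial genetic code (NCBI table 11) is fixed
throughout; the taxa this audit is aimed at use it, and no alternative
tables are supported. Elemental accounting uses nucleobase atoms only
(adenine C5H5N5, guanine C5H5N5O, cytosine C4H5N3O, uracil C4H4N2O2):
the ribose-phosphate backbone adds an identical constant per residue
and cancels from every comparison the pipeline makes (deltas, shifts,
rank statistics), so including it would change no result while
suggesting false absolute precision.

The prebiotic ("inexpensive") amino-acid set is fixed to
{Gly, Ala, Asp, Glu, Val, Ser, Ile, Leu, Pro, Thr}, the consensus
early-amino-acid set of the origin-of-life literature; the other ten
are "modern". The split is configurable, and any downstream
class-usage result should be read as conditional on it.

### Stop-codon conventions

Whole-transcript metrics (GC content, pyrimidine fraction, the
transcriptome budget) include the terminal stop codon: it is
transcribed and paid for. Codon-family metrics (GC3, RSCU, CAI, ENC,
tAI, amino-acid usage, per-codon element demand) exclude it: it
belongs to no synonymous family. The two conventions differ by well
under 1% for realistic gene lengths; both are stated here rather than
silently mixed.

### CAI

Relative adaptiveness w is computed from reference codon counts after
adding a +0.5 pseudocount to every sense-codon count, the classic
guard against zero-count reference codons; the pseudocount is a
configuration knob. Two references are always computed: the whole
genome and the ribosomal-protein gene set (the proxy for highly
expressed genes). Single-codon families (Met, Trp) and stops are
excluded from the geometric mean, following the original formulation.

### ENC

Wright's estimator with per-family homozygosity
F = (n·Σp² − 1)/(n − 1), families with n < 2 skipped, class means
F̄_k, and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. A missing 3-fold
class (Ile absent) is imputed as (F̄₂ + F̄₄)/2, Wright's
recommendation. If any other class is entirely missing, its term is
dropped and the partial sum is rescaled so that the representable
maximum maps to 61. Estimates above 61 (a finite-sample effect) are
clipped to 61; values below 20 are deliberately not clipped upward so
that implementation defects surface instead of being hidden. Other
ENC implementations handle these edges differently, so small
divergences from them on short genes are expected and documented.

### tAI and pairing geometry

Anticodons are stored 5'→3'; the codon read is the reverse complement
in RNA. Pairing requires Watson–Crick complementarity at codon
positions 1–2 and an allowed (codon third base : anticodon first
base) pair. The selective-constraint table shipped with the package
(`data/wobble_s_table.tsv`) uses the widely adopted defaults: s = 0
for Watson–Crick, 0.41 for G:U, 0.68 for U:G, 0.28 for I:C and 0.9999
for I:A, with anticodons beginning A treated as inosine-modified
(reading U, C, A), the standard bacterial assumption; both the
inosine treatment and the s values are data, not code, and the
table's SHA-256 is stamped into every run's metadata so divergent
choices stay traceable. Codons with W = 0 (no pairable tRNA) are
excluded from the tAI geometric mean and counted per gene, rather
than zeroing the index or imputing; AUG is included in the mean.

### Access curves and networks

For each gene set, per-codon median RSCU (nan-aware across genes;
codons of amino acids a gene never uses express no preference) is
attached to the bipartite codon–anticodon network. The access curve
reports, for RSCU cutoffs 0.00–2.00 in steps of 0.01, the total gene
copies of anticodons able to read at least one codon at or above the
cutoff; it is non-increasing by construction and its endpoints feed a
chi-square test of equal accessible proportions. The loess-style
smoothing some figures draw over such curves is cosmetic and not
implemented.

### Statistics

PERMANOVA is one-way, on Euclidean distances between per-gene RSCU
vectors (absent codons imputed as 0 for the ordination only — a gene
cannot prefer a codon it never uses; this imputation choice is
flagged in the API docs). The permutation p value is
(#{F_perm ≥ F_obs} + 1)/(P + 1) with a seeded generator, default
P = 999; an exact mode enumerates all row orderings for n ≤ 8.
Implemented in-package so that the permutation stream is seeded and
enumerable; scikit-bio's PERMANOVA is used as an independent
cross-check in the test suite, never as the implementation.

Wilcoxon signed-rank drops zero differences before ranking
(Wilcoxon's prescription), is exact for n ≤ 25 and normal-approximate
above. The chi-square test of proportions is the uncorrected 2×2
contingency chi-square. All tests report two-sided p values alongside
the 99% confidence convention used for interpretation.

## The synthetic study conditions

`SyntheticGenomeSpec` defaults define the conditions under which the
audit is exercised and under which the parameter-recovery tests are
run:

* 300 background genes, 20 ribosomal genes, one planted 3-gene
  operon (323 genes total); lengths lognormal(meanlog 5.3, sdlog
  0.35, min 80 codons, median ≈ 200), except the planted genes, which
  get fixed lengths of 252, 414 and 415 codons — the scale of a real
  particulate-methane-monooxygenase operon.
* Background codon usage targets GC3 ≈ 0.72 at moderate sharpness
  (bias strength 1.2), so the genome shows the GC3 > GC trend typical
  of the audit's target clade.
* The ribosomal profile prefers pyrimidine-ending codons at GC3 0.35,
  strength 1.5 — the highly-expressed reference the planted operon
  resembles in *ranking*.
* The planted profile shares that ranking but is sharper (GC3 0.18,
  strength 3.0), yielding GC3 far below GC, third-position pyrimidine
  enrichment, low ENC, bottom-percentile CAI_genome and
  top-percentile CAI_ribosome. Its per-family sharpness scales with
  amino-acid usage (exponent multiplier 0.1–3.0, linear in usage),
  which plants the max-RSCU vs usage linear structure the accuracy
  regression detects. Its amino-acid frequencies are tilted toward
  residues with pyrimidine-rich codons (F, L, S, P, I, T, V, Y),
  making the transcripts pyrimidine-majority overall.
* The tRNA pool assigns Watson–Crick anticodons copy numbers
  proportional to background codon usage (120 total before rounding),
  by default excluding anticodons with 3'-cytosine from the
  proportional allocation (the supply pattern of the audit's target
  genomes); a coverage pass then adds single-copy anticodons so every
  sense codon stays readable.
* Expression is lognormal(meanlog 2, sdlog 1.5) with a 10× boost for
  ribosomal genes and 50× for the planted operon, putting the operon
  above the 95th background percentile — the "most expressed
  transcripts" condition.

One integer seed drives every draw, is recorded in the truth record,
and fixed seeds give byte-identical output files.

What the generator does *not* emulate: evolutionary dynamics
(mutation/selection trajectories), per-gene amino-acid composition
variation, operonic co-location on a chromosome, sequencing noise, or
partial genome assembly. Passing the recovery tests therefore shows
that the pipeline detects the planted statistical structure at
realistic effect sizes — not that any particular real genome carries
it.

## Problem sizes and numerical choices

The test suite runs the full audit on the default 323-gene genome
(seconds) and calibrates the type-I error of the four null tests on
5,000 seeded simulations each at α = 0.01, using sample sizes where
the tests' p values are effectively continuous (n = 30 per group for
Welch, 40 pairs for Wilcoxon, 2,000 Bernoulli trials per arm for the
chi-square, 20 rows × 199 permutations for PERMANOVA). Random
k-gene combination nulls default to 1,000 draws of k = 3 without
replacement within a draw. Percentile ranks use the "fraction ≤ x"
convention (ties share ranks, maximum is 100). Report files are
written with a fixed float format ("%.10g") and sorted JSON keys so
that identical inputs and seeds produce byte-identical bytes.

## Known limitations

* ENC edge handling on very short genes diverges between published
  implementations; this package's rules are stated above and tested,
  but cross-tool comparisons on short sequences should expect ±1–2
  unit differences.
* The wobble s values are the published defaults of the standard tAI
  formulation; organism-specific re-estimated s values are not
  provided (the table is editable data).
* The prebiotic/modern amino-acid split is a literature convention,
  not an inference; class-usage conclusions inherit it.
* PERMANOVA is one-way only; no nested or multi-factor designs.
* The transcriptome budget covers CDS transcripts only (no rRNA/tRNA
  species), and "transcribed" means abundance above a configurable
  floor (default: strictly positive).
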