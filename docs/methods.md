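# Methods

`msrtk` analyses multiplexed small-RNA sequencing libraries in which
reverse transcription (RT) is primed from the RNA 3′ end, so that the cDNA
carries three kinds of information at once: where it *ends* (the RNA 3′
terminus — intact CCA, truncated CC, or an internal fragment end), where it
*starts* (RT stops at bulky modifications), and which bases were *misread*
(RT misincorporation at Watson–Crick-face methylations). The toolkit turns
alignments of such reads into per-position count matrices and the derived
biology: tRNA abundance, aminoacylation, modification signals, fragment
classes, pseudouridine calls from paired ±CMC libraries, and — from a
matched mRNA experiment — translational efficiency and its association
with codon usage.

## Read processing

Pooled paired-end reads carry an inline sample barcode (3–6 nt) at the
start of one mate and a 6-nt unique molecular identifier (UMI) at the start
of the other. Demultiplexing is an exact partition: every pair is routed to
exactly one sample (or to `unassigned`), the barcode and UMI are stripped,
and the UMI is appended to the read id (`:UMI:<seq>`). Barcode matching
defaults to zero mismatches; any nonzero tolerance requires all barcode
pairs to differ at more than twice that many positions. Adapter trimming
removes a 3′ adapter occurrence or a trailing partial match of at least
5 nt, then drops reads shorter than 15 nt. Quality trimming is deliberately
not performed: mismatches carry the modification signal and must survive.
UMI deduplication is available (`dedup_umi`, collapsing identical
gene/start/end/UMI keys) but off by default; the standard analysis carries
UMIs without collapsing.

## Pileup and positional signals

Alignments (SAM/BAM via pysam) are reduced per gene to a 5×L count matrix
(A/C/G/T calls plus deletions), insertion-start counts, and read start/end
counts. Only primary, mapped alignments count; MAPQ is ignored because the
aligner reports a single best placement among near-identical isodecoders
and MAPQ filtering would silently delete whole multi-mapped tRNA families.
CIGAR semantics: M/=/X add base calls, D adds a deletion at each deleted
reference position, I adds one insertion event at the preceding reference
position, S/H add nothing. Internally M-runs are accumulated as a coverage
counter plus explicit mismatch entries and folded into reference-base
calls in a finalization step; this is an implementation detail verified
against a naive per-base re-walk in the tests.

Two signals are derived, both 0-based internally and 1-based in reports:

* **mutation fraction**(i) = (non-reference calls + deletions) /
  (all calls + deletions). Deletions are counted in both numerator and
  denominator because they are a classic RT signature at m¹A/m²₂G;
  insertions are counted in neither. Undefined below `min_coverage`
  (default 20, which keeps triplicate comparisons stable at the
  simulator's default depth).
* **stop fraction**(i) = start(i+1) / (start(i+1) + coverage(i)). The RT
  synthesizes toward the RNA 5′ end, so a cDNA blocked by the modification
  at i has its reference-leftmost base at i+1. The fraction is undefined
  at the last position and below the same minimum denominator.

Alignments with more than 2 soft-clipped bases at the 3′ end are excluded
from end profiles (a locally aligned read could otherwise masquerade as a
CC end); the unconditional end counts are kept alongside so the count
matrix still balances exactly.

## tRNA-level metrics

**Abundance** is reported in reads per million tRNA-mapped reads (RPM), so
each sample's isodecoder rows sum to 10⁶ exactly and an isoacceptor row is
the exact sum of its members. RPM was chosen because the cross-sample
quantity of interest is composition, not sequencing depth.

**Charging**: reads whose clean 3′ end falls on the gene's terminal A are
CCA-ending (aminoacylated before periodate oxidation/β-elimination, which
removes the terminal A of uncharged tRNA); ends on the penultimate C are
CC-ending (uncharged); all other ends are excluded. Both the conventional
ratio CCA/CC and the bounded fraction CCA/(CCA+CC) are reported; the
fraction is primary in tests because it remains estimable as CC → 0.
Entities with fewer than `min_reads` (default 10) informative ends are
masked, never dropped. The β-elimination chemistry itself is assumed
upstream and not modeled.

**Changes under stress** are computed per entity against the mean of the
control replicates: ratio statistics (abundance, charging ratio) as the
mean over stress replicates of value/mean(controls), reported as fold and
log2; mutation fractions as the plain difference value − mean(controls).
Mean-of-ratios is the default (a ratio-of-means variant is behind a flag);
entities with a zero control mean are masked with a reason string.

**Fragments**: each read is assigned by its 1-based 3′-end position to one
of `<30`, `30-39` (anticodon loop), `40-49` (variable loop), `50-59`
(T loop), or `60+` (full-length). The `<30` bin exists so that the bins
always partition the reads exactly. The per-sample tRF ratio is
Σ(bins < 60)/Σ(60+). Per-bin pileups allow comparing the mutation fraction
of a site in fragments against full-length molecules.

## Pseudouridine calling (±CMC)

CMC forms an adduct at Ψ that blocks the RT, so a Ψ site shows a stop
(and often mutation) excess in the treated library. `cmc_delta` computes
per-position Δstop and Δmut (+CMC minus −CMC), defined only where both
sides reach `min_coverage` (default 50). `call_sites` thresholds the
deltas (defaults τ_stop = τ_mut = 0.10 — the choice of a "strong" signal
is a tunable, exposed as flags) and reduces threshold crossings to local
maxima within a ±1 nt window before reporting, so one site yields one
call even when the adduct stalls the RT a nucleotide off register;
coinciding stop and mutation calls merge into a single "both"-evidence
call. Raising either threshold can only remove calls. Evaluation against
a known-site list counts a site as detected when a call lies within the
same ±1 nt tolerance, and supports an exclusion list for CMC-independent
signals (e.g. hypermodified bases) so they are not scored as false
positives.

## Translational efficiency and codon usage

Transcript counts are summed per gene and normalized to RPM over
protein-coding genes only (non-coding genes are carried but never enter
the denominator). TE = polysome RPM / input RPM, computed per (condition,
replicate) for genes whose RPM strictly exceeds 100 in both fractions.
log10 TE is approximately normal, so each sample is summarized by
within-sample Z-scores; the stress response of a gene is
ΔZ = Z − mean(control-replicate Z). The well-detected set contains genes
with TE defined in every condition for at least one replicate.

Codon frequency is occurrences / protein length per transcript, over the
61 sense codons after removing a terminal stop; protein length is the
sense-codon count; multi-transcript genes take the per-codon median.
Transcripts with internal stops or non-triplet length are excluded with a
warning.

The association test splits genes into tertiles of the grouping variable
(absolute TE level, or ΔZ for stress response) by percentile rank with
equal tail sizes (n//3 in the bottom and top groups); the equal-count
rank split makes the grouping exactly antisymmetric under negation of the
variable. Per codon, top and bottom tertiles are compared by a two-sided
Wilcoxon rank-sum test; because percentile ranks are a monotone transform
of frequency, the test on raw frequencies is identical to the test on
ranks. The direction is the sign of the median difference; results with
p ≥ α (default 0.05) are "ns". No multiple-testing correction is applied
across the 61 codons by default (the conventional report uses raw
p < 0.05); Benjamini–Hochberg is available behind a flag. The rank-sum
implementation uses exact enumeration for group sizes ≤ 8 without ties
and the tie-corrected normal approximation otherwise, and is checked
against an exhaustive-enumeration oracle in the tests.

The wobble analysis groups isodecoder abundance changes by the
gene-encoded base at anticodon position 34 (T34 tRNAs read A-ending
codons; C34 only G-ending), compares groups pairwise with the same
rank-sum test, and, for every amino acid possessing both T34 and C34
isoacceptors, reports the change in the ratio of mean T34 to mean C34
fold change.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the tests assume.

* **Reference**: 17 genes of 60–95 nt (CCA included, anticodon at
  positions 34–36), containing a four-member Ser-GCT family with two C and
  two T variants at linear position 50 (the long-variable-arm position
  conventionally labelled 47d), T34/C34 wobble pairs for four amino acids,
  and one mitochondrial gene. Additional genes are appended from a pool
  when a larger set is requested.
* **tRNA reads** are 3′-anchored: gene ∼ planted abundance (flat Dirichlet
  by default); with probability `fragment_rate` (default 0.01) the 3′ end
  is drawn from a planted bin distribution, otherwise the read is
  full-length and charged with probability `charging_fraction` (default
  0.80 — a typical in-vivo aminoacylation level), ending CCA (charged) or
  CC (uncharged). The RT walk proceeds 5′-ward; at each planted
  modification it stops with p_stop, else misreads with p_mis or deletes
  with p_del (probabilities conditional on reaching/reading through, so
  the planted values are exactly what the pipeline's estimators target).
  Uniform sequencing errors (default 10⁻³) are added last. Reads are
  emitted both as truth-aligned SAM (so no external aligner is needed) and
  as barcoded, UMI-tagged FASTQ that exercises the demultiplexer. The
  default modification profile plants an m¹A58-like stop+mutation site at
  position 58 in every sufficiently long gene and m³C-like mutation-only
  sites at positions 32 and 50 of the Ser genes.
* **±CMC libraries** share one rRNA-scale gene (1800 nt; generated ending
  CCA purely to satisfy the shared reference-container invariant) with 36
  planted Ψ sites at least 5 nt apart. Stop penetrance in the +CMC
  library is drawn from 0.15–0.80 (mutation 0–0.30); the −CMC side keeps
  a 0.01 background; one site is planted with Δstop = 0.08, just below
  the 0.10 calling threshold, to represent a site that genuinely evades
  detection. Read 3′ ends are uniform; depth is parameterized as mean
  per-position coverage (default 10⁴), giving detection margins of many
  binomial SDs for all above-threshold sites at any seed.
* **mRNA counts**: 600 coding genes (plus 20 non-coding passengers) with
  codon usage drawn from a Dirichlet(2) over the 61 sense codons and CDS
  lengths of 100–500 codons. In each condition,
  log10 TE = α + β·σ·z(freq(AAA)) + N(0, σ) with σ = 0.30 (a realistic
  spread of log TE), β = 0 in control and −0.5 under stress (an effect of
  half the TE noise SD per SD of codon frequency). Input counts are
  negative binomial around a log-normal expression (mean 500, dispersion
  0.1 — typical bulk RNA-seq overdispersion); polysome counts around
  expression × TE, re-scaled to a constant library size.

Determinism: all randomness flows from one integer seed through
`numpy.random.default_rng`; identical seed and configuration give
byte-identical FASTA/FASTQ/SAM output.

### What the generator does and does not emulate

It reproduces the statistical structures the pipeline estimates —
composition, 3′-end classes, per-position stop/misread/deletion
probabilities, ±CMC contrast, codon-coupled TE with counting noise. It
does not emulate ligation or GC bias, realistic quality scores,
position-dependent fragmentation, RT processivity drift, or alignment
ambiguity between near-identical isodecoders (reads are emitted with
their true alignment). Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated generative model, not
robustness to aligner artifacts or library-preparation biases in real
data.

## Problem sizes used in tests and the acceptance script

Recovery checks run at 10⁴ reads (or mean coverage) per gene for charging
and Ψ calling, 5×10³ for modification fractions, and 1.7×10⁴ reads for
fragment/abundance checks; the codon-association type-I rate is measured
over 1000 null datasets (61 codons each) and power over 100 seeded runs
of the full generator → TE → association pipeline. Statistical tolerances
are 3 binomial SDs for planted probabilities, sampling error for ratios,
0.05 ± 0.02 for the type-I rate, and exact equality for bookkeeping
invariants (partitions, RPM sums, oracle equivalence).

## Known limitations

* Fragment 3′ ends and charging ends are inferred from alignment ends;
  heavily 3′-soft-clipped alignments are excluded rather than re-examined.
* The Ψ caller reports at most one site per ±1 nt window; two genuine
  sites 2 nt apart would merge under the default window.
* The well-detected TE gene-set size is data-dependent by construction;
  it is not an invariant.
* Sprinzl/canonical tRNA numbering is accepted as annotation input only
  (`annotate_gene`), never computed from structure.
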