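# Methods

## The model

A Sleeping Beauty (SB) transposon screen selects a phenotype from a pool of
mutagenized cells and sequences transposon–genome junctions to locate the
insertions carried by the surviving population. Two properties of the SB
system shape the whole analysis:

1. **TA-restricted, otherwise unbiased integration.** The transposase
   requires a TA dinucleotide and shows little further site preference, so
   under the no-selection null every genomic TA site is an equally likely
   insertion target. The null sample space is the genome's TA index.
2. **Pooled, non-clonal samples.** Each sequenced sample is a pool of
   unrelated clones, so co-occurrence of insertions within one cell is
   unobservable. Every unique (sample, TA position, orientation) triple is
   treated as one independent insertion event; identical positions in
   different samples are distinct events. Interactions between insertions
   that co-occur in a clone are deliberately ignored.

### The gCIS2 statistic

For a gene g with `TA_g` TA sites in its counting region, out of `TA_total`
genome-wide, and `N` total unique events, the null expectation is
`E = N · TA_g / TA_total`. The observed count `O` is compared with a
two-cell Pearson goodness-of-fit statistic,

    χ² = (O − E)²/E + ((N − O) − (N − E))²/(N − E),   1 df,

which equals the squared binomial z-score `(O − E)² / (N r (1 − r))` with
`r = TA_g / TA_total`. The p-value is the upper tail of χ²₁; an optional
continuity correction (Yates) subtracts 0.5 from |O − E| (floored at 0) in
both cells, off by default — the plain statistic is the minimal reading of
a "simple chi-squared test". Only genes with O ≥ 1 are tested; genes with
`TA_g = 0` or with E outside (0, N) are skipped and logged. The statistic
is symmetric in enrichment and depletion; depleted genes can reach
significance but are annotated `direction = depleted` and never become
candidates, since the screen selects for enrichment.

Multiple testing uses Benjamini–Hochberg step-up across all tested genes
(monotone, standard; the FDR procedure behind the original tool is not
recorded). Candidates must satisfy FDR ≤ `fdr_threshold` (default 1e-5),
be enriched, be *unique to the selected arm*, and carry a defined mechanism
prediction.

"Unique to the selected arm" is ambiguous between two readings, so both are
implemented (`control_mode`): `not_significant` (default) — the gene is not
itself a significant enrichment when the identical test is run on the
control arm; `zero_insertions` — the gene has no control-arm events at all.
The default is the more tolerant reading: control pools are smaller and a
single stray control insertion should not veto a strong selected-arm hit.

### Counting regions

A gene's counting region is the union of its transcript spans (one region
per gene id; isoform structure is ignored) extended upstream of the
transcription start by `promoter_window`, strand-aware and clamped to the
chromosome: 40,000 bp by default, the mammalian-genome convention for
capturing promoter-proximal insertions. A TA site counts for a region only
if the whole dinucleotide lies inside it; overlapping gene regions each
count shared events independently (genes are tested one at a time).
Coordinates are 0-based half-open throughout; a TA site is identified by
the offset of its T.

On the bundled toy genomes (hundreds of kb per chromosome) a 40 kb window
would cover 10–25% of the genome per gene and destroy all contrast, so the
synthetic presets analyze with a 2 kb window (`toy_config()`), keeping the
region-to-genome ratio comparable to a human gene. This is a fixture
scaling choice; the package default remains 40 kb.

### Mechanism prediction

Mutagenic SB transposons carry an internal promoter, so same-orientation
insertions can over-express the downstream gene while orientation
indifference marks plain disruption. For genes with at least
`min_insertions_for_prediction` events (default 5; below it the prediction
is NA), the count of same-sense insertions is tested with an exact
two-sided binomial test against 0.5. The rule — p < `orientation_alpha`
(default 0.05) **and** same-sense fraction f > 0.5 ⇒ over-expression,
otherwise disruption — is this package's formalization of the qualitative
"orientation bias vs randomly oriented" logic; a significant *anti-sense*
bias is reported as disruption with a warning flag, as it is an unusual
pattern worth manual inspection.

Insertion positions are normalized to u ∈ [0, 1] across the counting
region, measured from the 5' end along the gene's reading direction
(`u = (ta − region_start)/(region_length − 2)`, mirrored for minus-strand
genes), so u ≈ 0 is always the promoter side. Skewness g1 = m₃/m₂^{3/2}
and excess kurtosis g2 = m₄/m₂² − 3 use plain 1/n central moments; a
config flag switches to the small-sample adjusted estimators. The plain
estimators are defined for n ≥ 3 (the adjusted kurtosis needs n ≥ 4; both
are NA at zero variance). Positive g1 means 5' clustering; high g2 means a
tight cluster — the signature of truncation-style over-expression. Shape
values are reported only; they never enter the candidate decision. By
default positions span promoter plus gene body so promoter clusters score
positive skew; a gene-body-only mode exists.

### Null simulation

A matched null dataset replaces each observed event with a TA site drawn
uniformly **without replacement** on the same chromosome (with-replacement
duplicates would collapse under the uniqueness key anyway), preserving
per-chromosome event counts exactly; orientations are fair coin flips (the
null of the orientation test). A suite of 20 such sets is analyzed by the
full pipeline; per-set 1st/99th percentiles of per-gene g1/g2 (genes with
≥ 5 events, linear interpolation between order statistics) are averaged
across sets into the calibration bounds against which experimental shape
values are judged.

## The read-processing conventions

The junction convention is fixed package-wide and mirrored by the read
synthesizer: the residual transposon tag ends immediately 5' of the TA, so
the trimmed genomic sequence begins with the junction TA. A forward-mapped
read therefore places the TA at its alignment start; a reverse-mapped read
at its alignment end − 2. Transposon orientation is recorded as the
junction read's mapping strand; a single global `orientation_flip` covers
the opposite terminal-repeat/vector geometry. Opposite-orientation calls at
one TA are kept distinct by default (both transposon ends can yield
junctions); an optional merge collapses them to the majority orientation.

Tag matching allows `max_tag_mismatches` (default 1) over the tag prefix.
Adapter trimming removes the leftmost full-length adapter occurrence
(≤ 1 mismatch) or a terminal partial occurrence of ≥ 8 bp (mismatch
tolerated only at ≥ 10 bp); partial matches away from the read's 3' end are
not adapter evidence — this keeps chance 6-mers inside genomic sequence
from truncating reads. The built-in mapper is exact-match over both strands
and rejects ambiguous (multi-hit) reads; it is intended for toy genomes
only, and real screens enter as externally aligned SAM/BAM (primary
alignments, MAPQ ≥ 10 by default). Per-sample processing keeps an exact
read-unit attrition ledger: raw = no_tag + too_short + unmapped +
multimapped + no_ta + blacklisted + low_support + retained calls +
duplicate reads.

## The synthetic-data generator

`generate_reference` builds i.i.d.-uniform ACGT chromosomes (TA density
≈ (L−1)/16) with non-overlapping genes on random strands; defaults are
2 chromosomes × 200 kb with 40 genes of 4–15 kb. `plant_screen` adds
background events uniform over genome TA sites, split across selected
samples (control samples get background only, at matched per-sample
density), and driver events whose position is drawn from a Beta law along
the gene's counting region — Beta(1.5, 8) concentrates mass near the 5'
end, Beta(1, 1) is uniform — snapped to the nearest in-region TA, with the
gene's orientation with probability f. Events are unique per (sample,
position, orientation) by construction, and TA sites within 100 bp of a
chromosome end are never planted (a junction read there cannot carry a
mappable flank). `synthesize_reads` emits fixed-length single-end reads
(tag + genomic flank + adapter padding) with i.i.d. substitution errors;
multiplexing is represented by per-sample FASTQ files, not in-read
barcodes.

The generator's knobs map one-to-one onto the analysis assumptions
(TA-restricted placement, Bernoulli orientation, Beta positional law), so
parameter-recovery tests are well-posed. What it does **not** emulate:
chromatin or sequence-context insertion bias, PCR jackpots and duplicate
structure, local hopping (irrelevant for plasmid delivery, which has no
chromosomal donor site), paired ends, base-quality realism, or clonal
co-occurrence of insertions. Passing tests therefore demonstrate
correctness of the pipeline under its own model of the data, not
robustness to these real-data artifacts.

## Problem sizes and numerical choices

Reference study conditions used by the test suite and
`scripts/acceptance.py`, all on one CPU in a few minutes:

- **Null calibration**: default genome (2 × 200 kb, ~25k TA sites),
  N = 2,000 events, 20 matched null sets, FDR ≤ 1e-5 → zero candidates in
  every set.
- **Driver recovery**: a larger genome (4 × 500 kb, ~125k TA sites) so
  planted effect sizes of 30–60 events are detectable over 2,000
  background events: with 2 kb windows a toy gene's region holds ~0.3–0.9%
  of genome TA sites, giving E ≈ 7–21 against O ≈ E + 30…60, i.e.
  χ² ≥ ~30 at the weakest — comfortably past BH-adjusted 1e-5. (On the
  default genome the same drivers would sit at χ² ≈ 4, undetectable; gene
  region size relative to the genome, not raw event count, controls
  power.) Ten drivers (f = 0.9, Beta(1.5, 8)) per screen, five seeds:
  sensitivity ≥ 9/10 per seed with zero false positives.
- **Mechanism labels**: drivers with exactly (f, n) = (0.9, 20) and
  (0.5, 20) planted without ambient background (background in-region
  events would dilute the realized f below its nominal value), 20 seeds;
  n = 4 drivers are always NA.
- **Monte-Carlo oracle for the χ² p-value**: the resampling null re-places
  all N events uniformly over TA sites, so the in-gene count is
  Binomial(N, E/N); 10⁵ reps per configuration. The null is discrete while
  χ²₁ is continuous, so the oracle uses the mid-p estimator (ties at the
  observed statistic count one half), which centers the discrete null on
  the continuous reference. Exact-enumeration analysis shows the residual
  lattice/skew mismatch decays like 1/√E and, at mid-range p (> 0.2),
  exceeds any practical MC tolerance at all realistic E; the comparison is
  therefore made in the tail regime E ∈ [750, 1500], p ∈ [0.005, 0.1],
  where the systematic gap is below ~1.7 MC standard errors. Because 50
  independent estimates each bounded at 3σ would fail ~13% of the time
  even for a perfect oracle, the check is distributional: ≥ 48/50 within
  3 SE, all within 5 SE. The practical consequence for users: gCIS2
  p-values are accurate tail probabilities for genes with moderate-to-large
  E, and conservative-to-approximate for E below ~5, as with any
  chi-squared test on small expected counts.
- **Round trip**: 300 insertions, 3 samples, 3 error-free reads each →
  exact recovery of positions, orientations and read counts, with the
  attrition ledger summing to the raw read count.

Other numerical conventions: percentiles use linear interpolation; BH ties
and ordering follow the standard step-up with monotonicity enforcement;
candidate tables sort by (FDR, −O); all RNG is `numpy.random.default_rng`
seeded explicitly, and suite seeds are `base_seed + set_index`.

## Known limitations

- The built-in mapper is exact-match only; reads containing any error in
  the genomic portion go unmapped (use an external aligner for real data).
- No UMI handling, paired-end merging, or PCR-duplicate modeling; read
  counts are not clonality estimates.
- No isoform-aware or alternative-promoter analysis; one counting region
  per gene id.
- Tag and adapter sequences are screen-specific configuration; the bundled
  defaults are synthetic-fixture constants, not vendor sequences.
- The chi-squared p-value is approximate for genes with very small
  expected counts (E ≲ 5), the usual caveat for Pearson tests.
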