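# Methods

## Signal model

TOP-seq libraries are read-count data over a catalog of candidate
cytosines. A read's informative coordinate is its 5′ end: the tethered
oligonucleotide primes polymerase extension at the labeled cytosine, so a
correctly primed read starts exactly at the target base, with a minor tail
of starts 1–4 nt upstream (in read orientation) from imprecise priming.
The pipeline therefore:

1. enumerates candidate sites from the reference (CG cytosines on both
   strands; GCGC-embedded CGs for the lambda model system; CH cytosines
   classed CHG/CHH),
2. reduces alignments to deduplicated 5′-start events, and
3. counts events whose (contig, strand, start) exactly equals a site.

Counts are a *relative* modification signal: the chemistry gives no
absolute per-site fraction, so no beta-value-style quantity is emulated
anywhere. Regional comparison uses the h-density: per non-overlapping
180-bp window, summed site counts divided by the number of CG dinucleotide
loci in the window (unweighted: one per locus, not per strand), then
log2(x + 1).

### Coordinate conventions

All internal coordinates are 0-based; BED output is 0-based half-open; SAM
input is converted from 1-based. A minus-strand site is addressed by the
plus-axis coordinate of its cytosine (the G of the plus-strand
dinucleotide), so both strands share one axis. Offsets and "downstream"
are always in read orientation: negative = upstream of the site as
sequenced, on either strand.

### Duplicate collapse

Reads sharing contig, strand, 5′-start coordinate and aligned length are
PCR duplicates; the first in input order is kept. Aligned length is the
reference span from the CIGAR — soft/hard clips contribute to neither
start nor length, which makes the collapse exact on the simulator's
clip-free output. Strand-awareness of the key is a config switch
(default on), since 5′-end identity is strand-specific.

### Non-CG (CH) calling

Random priming can mimic low CH coverage, so a CH site is called only when
all three rules hold:

* covered (count ≥ 1) in both technical replicates;
* no CG dinucleotide begins within k nt downstream on the site's strand
  (default k = 7) — a CG that close could be the true priming target;
* present in fewer than two unlabelled control libraries ("present" =
  count ≥ 1; the exclusion is optional, default on).

Increasing k, or adding a control library, can only shrink the called set.
Reported per-site coverage is the replicate mean (sum available by
config).

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| min read length | 120 (lambda preset) / 80 (mESC preset) | nt | the two published processing presets |
| MAPQ floor | 60 (lambda) / 30 (mESC) | phred-like | uniqueness filter, inclusive bound |
| h-density window | 180 | bp | regional signal scale; window phase configurable, tiled from 0 |
| downstream-CG exclusion k | 7 | nt | guard distance for CH calls |
| offset histogram range | ±15 | nt | covers the 0/−1..−4 start structure with margin |
| signal groups | low [0,20), mid [40,60), high [80,100] | coverage-rank % | 20 %-wide bands; a narrower [40,50) middle band available (`scheme="methods"`) |
| metagene bins | 10 per element | — | gene elements: upstream 2 kb, 5′UTR, exons, introns, 3′UTR, downstream 2 kb |
| strand analysis | 60 bins, ≥20 signal bins/strand, length within [1st, 99th] pct | — | per-gene sense/antisense means, paired t per expression group |
| boundary window | 1–25 | nt each side | internal exons only; both sides must be covered |

Expression groups are zero-expression plus tertiles of the expressed
genes, computed on nonzero values only; the expression metric is
deliberately unspecified (any monotone abundance measure works).

## The simulator

The generator emulates the two validation designs:

* **Lambda-style titration** — a 50-kb uniform-composition random genome
  (≈195 GCGC loci expected, standing in for the 48.5-kb lambda reference)
  whose GCGC-context CGs all carry one hydroxymethylation level from
  {2.5, 5, 10, 20, 40} %; five libraries of 50,000 reads each.
* **mESC-like libraries** — a sparse subset (25 %) of CG sites with
  Beta-distributed levels, 5 % background, 10 % duplicate injection; the
  level map is seeded independently of the run seed so different runs are
  replicates of one truth. Control libraries are pure background.

Each read is background with probability ε (uniform start and strand,
low MAPQ) and otherwise a site read: source site ∝ h × per-site
efficiency, start = site ± offset from {0, −1..−4} (defaults 0.93, 0.03,
0.02, 0.01, 0.01), length normal (mean 150, sd 15, floor at the preset
minimum) truncated at contig ends.

**Capture-pool mode.** With the per-read model, per-site coverage is
independent of the global modification level — the sampling weights
normalise it away — so the titration response cannot appear at fixed
sequencing depth. The titration preset therefore models the physical
library: `copies` labeled genome equivalents yield
M_site ~ Binomial(copies, h·e) distinct molecules, each with one
fragmentation identity (offset, length); sequencing draws n_reads from the
pool with replacement, and repeat draws are PCR duplicates. Unique-molecule
recovery after duplicate collapse is then an increasing, saturating
function of the level — the mechanism behind the concave quadratic
titration curve — while reads stay ~99 % on-target at every level. The
preset uses 400 copies, placing the pool within a few-fold of the
sequencing depth at the top level, the regime where the saturation is
visible at this scale. Per-site efficiencies e are lognormal(0, 0.6),
seeded by the genome (a property of the site, not the run), which gives
the order-of-magnitude per-site coverage spread real libraries show and
makes technical replicates (same `library_seed`, different run seed)
strongly correlated.

What the generator does **not** emulate: sequencing errors (alignment is
out of scope; the SAM is emitted clip-free with truth coordinates),
GC/PCR amplification bias, paired ends (the protocol is unidirectional),
copy-number variation, and chromatin-correlated placement of modified
sites. Passing tests therefore demonstrate the pipeline's correctness and
calibration on idealised start-position data, not robustness to aligner
artefacts or genomic confounders.

## Numerical choices

* h-density log transform uses a +1 pseudocount so zero-coverage windows
  stay finite; windows with zero CG loci are missing (NaN), never zero,
  and are excluded from correlations. Whether correlation runs on raw or
  log2 density is the caller's choice of track; the default export is
  log2-then-correlate.
* Pearson correlation needs ≥3 shared non-missing positions and nonzero
  variance on both sides; otherwise the result is missing, not a number.
* Quadratic OLS is fit by statsmodels; adjusted R² = 1 − (1−R²)(n−1)/(n−3)
  (p = 2 predictors). A constant response returns slope 0, R² = 0 rather
  than an undefined ratio. Fewer than 4 points or fewer than 3 distinct
  levels is an error (collinear design).
* Fisher's exact test: odds ratio is the cross-product ratio (a·d)/(b·c);
  any zero cell switches to the Haldane (+0.5) estimate and flags the
  result degenerate; p-values are two-sided exact.
* Signal-group bands are rank-based with stable ties (catalog order), so
  counts 1..10 give low {1,2}, mid {5,6}, high {9,10}; an all-equal table
  is flagged degenerate.
* Paired t-tests with all-zero differences report (t = 0, p = 1) by
  convention; equal nonzero differences (zero variance) report p = 0.
* Metagene bin edges are floor(len·j/bins); elements shorter than the bin
  count are skipped with a warning; minus-strand genes are traversed
  5′→3′ by reversing the bin order.
* Exon–intron boundaries: offsets −25..−1 and +1..+25 in gene orientation
  with no offset 0 — a site on the last exonic base is −1, on the first
  intronic base +1, so a CG straddling the junction lands on the exonic
  side. Side averages are means over covered sites per boundary; the test
  pairs exon-side vs intron-side across boundaries (a per-offset profile
  is also produced for curve plots).
* Nearest-site offset ties (equidistant sites up- and downstream) resolve
  to the upstream (negative) offset, matching the upstream bias of the
  priming chemistry.

## Design choices made where the design was open

* GCGC motifs are counted with overlaps (restriction-site convention);
  each occurrence contributes its internal CG pair, deduplicated at the
  site level.
* N bases break motifs and context windows: no site whose defining bases
  include an N is emitted.
* TSS/TES for promoter/downstream regions come from the gene span
  (outermost transcript); UTRs are unions over transcripts, derived from
  CDS where UTR features are absent. Enhancer classes do not exclude
  promoter overlaps.
* Intergenic space is ≥50 kb from any protein-coding gene span, measured
  from span boundaries in both directions.
* No multiple-testing correction is applied by default (raw p-values are
  reported); a flag is available downstream.
* The acceptance-scale study sizes (50-kb genome, 50,000 reads, 200-gene
  layouts, 200-replicate calibration runs) are chosen so each analysis
  completes in seconds while the monitored statistics (medians,
  correlations, KS uniformity) are well inside their asymptotic regimes.

## Known limitations

* Absolute 5hmC fractions are out of reach by construction; cross-library
  comparison should use h-density, and CNV correction is out of scope.
* Alignment is delegated: the pipeline consumes SAM/BAM from any aligner
  and trusts its MAPQ semantics.
* The CH metagene profile is deliberately not computed — called CH sets
  are too sparse for a stable profile at realistic scales.
* Published genome-scale figures (millions of CG calls, tens of thousands
  of CH calls) require the original libraries; the package reproduces the
  *behaviour* of the method on synthetic data and provides the interfaces
  (region totals, per-contig correlation) for comparisons against external
  enrichment tracks.
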