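# Methods

`snortkit` implements, as a tested desk-scale pipeline, the
computational characterisation of the cytoplasmic dyskerin (DKC1) RNA
interactome: identification of snoRNA-retaining transcripts (snoRTs) from
annotation, dual-contrast RIP-seq target calling, H/ACA-box motif
scanning, pseudouridylation-overlap and guide-pocket analysis, and
eCLIP-based binding classification. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## snoRT identification

A snoRT is an mRNA isoform whose mature (exonic) sequence fully contains
a snoRNA that, in a sibling isoform of the same gene, lies inside an
intron — i.e. the isoform retained a snoRNA-carrying intron. Rules:

* Coordinates are 0-based half-open internally; GTF is converted at I/O
  (1-based inclusive on disk), BED is native.
* Containment requires the **full** snoRNA interval inside the
  transcript's exonic coverage on the same chromosome and strand.
  Partial overlaps are not snoRTs: only a complete snoRNA sequence can
  act as a pseudouridylation guide.
* The "retained relative to a spliced sibling" check applies when the
  gene has sibling isoforms; single-isoform genes fall back to plain
  exonic containment, because annotations of non-canonical isoforms are
  incomplete. The sibling requirement can be disabled
  (`require_sibling_intron=False`) to reproduce a biotype-only reading of
  intron retention.
* scaRNAs carry their box sub-class (`SCA_HACA` / `SCA_CD`) and are
  classified like H/ACA or C/D snoRNAs where the distinction matters.

Target sets are partitioned with a fixed precedence — snoRNA/scaRNA
biotype, H/ACA snoRT, other (C/D-only) snoRT, protein-coding, remaining —
so the five categories are disjoint and complete. Percentages are
rounded half-up to one decimal (ties away from zero), the conventional
reporting style for category shares.

## RIP enrichment and target calling

The experimental design is RIP / IgG / INPUT with replicates (five by
default). A feature is a dyskerin target iff it is significantly
enriched (BH-adjusted p ≤ α, log2 fold-enrichment > 0) in RIP vs INPUT
and **not** significantly enriched in IgG vs INPUT. "Not enriched in
IgG" means `NOT (padj ≤ α AND log2fc > 0)`: an IgG *depletion* signal
does not disqualify a target. α defaults to 0.05. Enrichment with a
negative fold change is biologically meaningless for an IP, hence the
explicit sign requirement.

The count test is internal:

* **Size factors**: median-of-ratios against a geometric-mean
  pseudo-reference restricted to features with nonzero counts in every
  sample. The median is taken in linear space.
* **Dispersion**: per-feature pooled within-group method-of-moments
  estimate on normalised counts, with the Poisson term corrected for
  normalisation (`Var(K/s) = μ/s + αμ²`); a mean–dispersion trend
  `α(μ) = a0 + a1/μ` fitted by least squares across features; the
  gene-wise estimate is bounded to an 8-fold band around the trend and
  averaged with it on the log scale (equal weights).
* **Wald test**: per-feature two-group NB GLM with log link and size
  factors as offsets, fitted by IRLS (vectorised over features; the 2×2
  weighted normal equations have a closed form). The Wald statistic for
  the group coefficient is referred to a t distribution with
  `df = 3·(S−2)` where S is the number of samples in the contrast. The
  moderation argument: squeezing the log dispersion halfway toward a
  trend estimated from thousands of features multiplies the effective
  precision of the dispersion estimate, so the df lies between the
  empirical-Bayes bound `2(S−2)` and the variance-matching bound
  `4(S−2)`; the midpoint was validated by null Monte-Carlo (empirical
  size ≈ 0.051 at nominal 0.05, inside the 99% binomial interval at both
  α = 0.05 and α = 0.01 on 2000 features).
* **Reported log2fc**: log2 ratio of normalised group means with a
  pseudo-count of 0.5 per group, so group-exclusive features stay
  finite. The test statistic uses the GLM coefficient.
* **Independent filtering**: features with mean normalised count < 1
  across the contrast's samples are excluded from the BH family (padj is
  NaN); this stabilises the FDR at desk scale. All-zero features get NaN
  p as well. Each contrast (and each analysis level) is its own BH
  family.
* Features with identical counts under identical scaling carry no
  signal and are forced to p = 1.

The "median enrichment" summary counts how many members of a subset
(e.g. the H/ACA snoRTs) have log2fc strictly above the median log2fc of
*all* targets; ties at the median count as not-above.

## H/ACA box scanning

H/ACA box snoRNAs carry a degenerate H box (consensus ANANNA) in the
hinge between the two hairpins and an ACA box 3 nt from the 3′ end.
Because ANANNA is highly degenerate and ACA is only 3 nt, these motifs
are scanned directly by IUPAC consensus rather than with a PWM model:

* Sense strand only; DNA input is transliterated T→U (logged once);
  an N in the pattern matches any base, an N in the sequence matches
  nothing; overlapping occurrences are reported.
* **Distance** between the boxes is the gap length
  `aca_start − h_end`; a pair is plausible when `10 ≤ d ≤ 300`. The gap
  measure is the most conservative reading of "distance between the
  motifs", and is stated in the CLI help.
* For each H box only the nearest qualifying downstream ACA is reported
  (one pair per H box) to avoid quadratic output; `all_pairs=True`
  (CLI `--all-pairs`) lifts this.
* No p-value model is attached to consensus hits.

PWMs (read from MEME minimal text via Biopython, RNA or DNA alphabet)
are compared by the best Pearson correlation of flattened aligned
columns over all ungapped offsets with ≥ 4 overlapping columns, sense
orientation only; the conventional reporting threshold of r > 0.5 is
applied by the caller.

## Pseudouridylation overlap and guide matching

Over-representation of known-pseudouridylated transcripts among targets
is a one-sided binomial test: with k of n targets in a catalogue that
covers K of N transcripts, `p_upper = P(X ≥ k)` for
X ~ Binomial(n, K/N), computed through the regularised incomplete beta
(scipy). The binomial model (rather than the hypergeometric) treats the
n targets as independent draws against a fixed background frequency,
appropriate when n ≪ N. Agreement with an exact integer-arithmetic
summation oracle is 1e-12 relative down to the limit of double
precision (~1e-300; deeper tails underflow jointly).

The guide matcher is a deliberate simplification of hairpin-model
screens such as snoGPS — no secondary-structure scoring, no hairpin
prediction; the two antisense elements of a pseudouridylation pocket
are taken from annotation (or planted by the generator):

* The 5′ flank of the Ψ pairs with the pocket's 3′ element and the 3′
  flank with the 5′ element, antiparallel; the longest contiguous
  duplex per side is found by dynamic programming; G·U wobble counts as
  a full pair.
* The ΨN dinucleotide stays unpaired, as in the canonical H/ACA
  internal loop: the Ψ itself is excluded from the flanks by
  construction, and the base immediately 3′ of it (the first base of
  the 3′ flank) is excluded from pairing.
* Thresholds: each side ≥ 3 bp and total ≥ 9 bp (`min_side`,
  `min_total`), approximating canonical H/ACA duplex lengths; both are
  exposed in configuration. With wobble pairing, random-sequence false
  matches at these thresholds are common when pockets and flanks are
  long (tens of percent per pair at 7-nt pockets / 10-nt flanks, ~5%
  at 6/6), which is why the generator controls the unguided background
  explicitly (below) and why these thresholds are validated only
  against synthetic ground truth, never against external screen
  counts.

A matched site is "covered" when its guide snoRNA is itself in the
target set — either as its own (snoRNA-biotype) transcript or inside a
target snoRT.

## eCLIP cross-classification

eCLIP peaks mark direct protein–RNA contacts. A target "has coverage"
when ≥ 1 peak overlaps its exonic span by ≥ 1 bp (default); an
alternative mode requires a covered fraction of the exonic span
(default c = 0.05), and an intron-restricted mode assesses snoRT
coverage only over the retained region. Categories, in order:
snoRNA/scaRNA with coverage → `direct_snoRNA`; snoRT with coverage →
`direct_snoRT`; any other covered target → `direct_other`; no coverage
but ≥ 1 binding-consensus occurrence → `motif_supported`; otherwise
`indirect` (e.g. tethered through a guide snoRNA). Peak overlap is
stranded, since eCLIP libraries are strand-specific.

## Synthetic data generator

The generator emulates the statistical structure every stage assumes,
with full ground-truth labels, deterministically (byte-identical files
for a fixed seed).

Defaults (`SimulationConfig`): seed 20220822; 300 genes on two
chromosomes, alternating strands, three exons each (150–400 bp exons,
250–800 bp introns); 20% of genes host a 130-nt intronic snoRNA (80%
H/ACA, 10% C/D, 10% scaRNA-H/ACA) and express a retained-intron isoform
with probability 0.8; 10% of non-host genes are lncRNAs (populating the
"remaining" biotype category). Planted H/ACA snoRNAs carry an ANANNA H
box at position 55, an ACA ending 3 nt from the 3′ end (gap ≈ 63,
inside the plausible window), and two 7-nt pocket elements recorded in
the annotation sidecar.

Counts are NB with a single dispersion (0.1), log10-uniform base means
over 1–1000, and log-normal (σ = 0.2) per-sample library factors to
exercise normalisation; 5 replicates per condition. The 60 true targets
(40% snoRTs, 30% snoRNA transcripts, 30% protein-coding) are multiplied
by 2^3 in RIP only; IgG artifacts (5% of features) are enriched in both
RIP and IgG and must be rejected by the dual-contrast rule. Target base
means are drawn from the upper decades (10–1000): RIP-enriched
transcripts are, by the nature of the assay, detectably expressed.

The Ψ catalogue has 30 sites on protein-coding transcripts (60% on
targets); 60% of sites are guided: their flanks are reverse complements
of a planted pocket, with the planted guide always drawn from the
in-target snoRNA pool so that guide coverage is exact by construction.
Unguided flanks are rejection-sampled against **all** pockets so they
match nothing at the default thresholds — without this, wobble-tolerant
matching against ~50 pockets would produce spurious matches for most
random flanks. Peaks (60 bp) are placed over 90% of targets; for host
genes where both the snoRNA and its snoRT are targets the peak decision
is drawn once for the pair (a peak over the snoRNA covers both),
keeping planted binding labels consistent with observable overlap.
Uncovered coding targets are split between `motif_supported` (a 10-nt
consensus motif is planted in exon 2; all accidental genomic
occurrences of the motif are mutated away first) and `indirect`.

What the generator does **not** emulate: read-level data (no FASTQ, no
alignment artifacts), realistic genome composition or gene structure,
overdispersion heterogeneity across features, partial intron retention,
expression-coupled biases between conditions, or guide–target pairs
embedded in real secondary structure. Passing the synthetic recovery
tests therefore demonstrates the correctness of the implemented rules
and the calibration of the count test under its own model — not
performance on real sequencing data.

## Pipeline and validation sizes

The `run` pipeline executes annotation → enrichment → target calling →
partition → motif scan → Ψ/guide analysis → eCLIP classification (the
last only when peaks are provided), writes per-stage TSVs with stable
column order, and emits one JSON report validated against a shipped
structural schema. All thresholds (α, distance window, guide thresholds,
coverage rule) live in a single YAML config; CLI flags override config
keys; logging goes to stderr.

Validation problem sizes were chosen to make every statistical check
sharp while keeping the whole suite in seconds: 2000 features for null
calibration (99% binomial interval half-width ≈ 0.013 at α = 0.05),
200 planted features for power, 100 × 2-kb sequences for the scanner
oracle, the full k = 0…701 grid for the binomial oracle, and the
generator defaults (≈ 410 transcripts × 15 samples) for end-to-end
recovery.

## Known limitations

* The NB test's df moderation is calibrated for the two-group design
  with ≥ 2 replicates per condition; it is not a general-purpose GLM.
* The guide matcher's thresholds are only as discriminative as the
  pocket annotations supplied; with long flanks and wobble pairing the
  random-match background is substantial.
* The sibling-isoform retention check depends on the completeness of
  the supplied annotation; genes whose spliced isoform is missing fall
  back to plain containment.
* Consensus scanning is sense-strand only by contract; reverse-strand
  occurrences are invisible by design.
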