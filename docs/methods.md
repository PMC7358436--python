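# Methods

`mosscharter` implements the post-variant-calling half of an RNA-seq SNP
charting workflow for a haploid, predominantly selfing moss maintained as
laboratory accessions and pedigrees. It consumes per-sample single-sample
VCFs (the output of a standard HaplotypeCaller-style pipeline), a reference
genome FASTA, a GFF3 gene annotation, and per-position depth tables. This
note records the models, the defaults and why they were chosen, and what
the synthetic cohorts do and do not demonstrate.

## Variant filtering

Calls pass through up to four stages:

1. **Quality pre-filter** (optional, `hq_prefilter`): genotype quality
   strictly above 90 and site QUAL at or above the sample's own 90th QUAL
   percentile (linear interpolation over that sample's records). The
   percentile is per-sample because library depth varies by orders of
   magnitude across RNA-seq experiments; a global QUAL cutoff would encode
   depth, not confidence. The "alternative nucleotide quality" of the
   upstream tooling is housed as the site QUAL column; the percentile rule
   is one reading of an ambiguous convention and is therefore exposed in
   `FilterConfig` rather than hard-wired.
2. **Read-coverage filter**: depth DP >= 9, alt-supporting reads AD >= 7,
   and allele fraction AD/DP strictly greater than 0.77. These values are
   the spike-in calibration point: synthetic spike-in transcripts carry no
   true variants, so every call on them is a sequencing or mapping error,
   and the thresholds are the loosest triple at which essentially no
   spike-in call survives (~1% false positives at the DP = 9 floor; a floor
   of 10 costs real sensitivity). The allele-fraction bound exploits
   haploidy: a true haploid variant should be supported by nearly all
   reads, so fractions near 0.5 signal paralogous mapping or error.
   Records missing DP or AD fail closed.
3. **Sample-support filter**: a site, identified as (chrom, pos, alt), must
   be called in at least three samples of the cohort. Support is counted
   across the whole cohort rather than within experiments: replicate
   triplicates motivate the value 3, but the rule is cohort-wide.
4. **Indel removal**: downstream encoding, effect classification, and RFLP
   design operate on single-base substitutions.

Monotonicity (raising any threshold never enlarges the surviving set) and
idempotence of the pipeline are enforced by property tests.

`ploidy_compare` contrasts haploid- and diploid-mode call sets of the same
sample by call count (ratio of n=1 to n=2 calls) and reports the fraction
of heterozygous diploid genotypes. On a truly haploid organism the diploid
caller inflates the call set with spurious heterozygous calls, largely
from near-identical paralogs, so a ratio well below 100% with a moderate
het fraction is the expected haploid signature.

## Exclusive (diagnostic) panels

The presence matrix is call-based: "absent" means "no call at that site",
not "reference-confirmed"; low-coverage absence is not distinguished. An
accession-exclusive site must be supported by **strictly more than 90%**
of the accession's samples and by **zero** samples of any other accession
(with 10 samples, 9 supporters do not qualify). The read-coverage filter is
deliberately not applied upstream of accession-panel extraction — sample
support substitutes for read support, which keeps low-coverage libraries
usable — while pedigree panels are extracted after coverage and support
filtering because pedigree signal is far weaker. Pedigree panels take the
top five candidate sites ranked by supporting-sample count (ties broken by
chromosome, then position, for determinism); candidates must be present in
exactly one pedigree and, by default, absent from every other accession.
Blind samples are assigned to the accession whose panel they overlap most.

## Clustering

Two encodings of the filtered variants:

- an **artificial alignment** with one column per SNP site (sample's alt
  base if carried, reference base otherwise; indels excluded), compared by
  uncorrected p-distance. p-distance is the plain default of the
  distance-network tools this view targets; at the SNP densities involved,
  multiple-hit corrections are irrelevant.
- a **0/1/2 matrix** (reference 0, SNP 1, indel 2) compared by Euclidean
  distance and summarized by a 3-component PCA (centered SVD; each
  component's sign fixed by making its largest-magnitude loading positive).

Trees are built by classical neighbor joining (Saitou–Nei), implemented
natively: negative branch lengths are clamped to zero, and ties in the
Q-matrix resolve to the lowest index pair, making output deterministic.
When per-sample covered-base-pair totals are supplied, each leaf's terminal
branch is multiplied by max(covered bp)/covered bp(sample) — a coverage
correction that stops poorly covered samples from appearing artificially
close to the reference. Tests cross-check the implementation against
scikit-bio's neighbor joining and verify exact reconstruction of random
6-taxon additive trees.

## Normalization and cohort statistics

- **Coverage normalization** divides covered base pairs (positions with
  depth >= 9, the same floor as the coverage filter) by the SNP count,
  reported as "one SNP per X bp". Zero SNPs is reported as "no SNPs", not
  infinity; zero covered positions is an error.
- **Read-count regression** is ordinary least squares of SNP count on read
  count (a constant SNP count returns R² = 0 by convention).
- **Per-chromosome enrichment** builds, for each chromosome, the 2x2 table
  of base pairs with/without SNPs on that chromosome versus all others
  pooled, applies a two-sided Fisher exact test, and corrects across
  chromosomes by Benjamini–Hochberg (q <= 0.05 flagged).
- **Hotspots** tile each chromosome into non-overlapping 100-kbp windows
  (1-based, final partial window kept). No fixed count threshold exists
  for "hotspot", so the default is the 95th percentile of the group's
  non-empty window counts, overridable; cross-group sharing requires exact
  window identity.
- **Observed mutation rate** = exclusive-SNP delta between two dated
  snapshots of a pedigree / (covered bp x elapsed years). Conventions for
  per-year rates vary between studies; this definition is the simplest
  reading and is documented as this package's convention.

## Effect classification and selection screen

Each SNP yields one effect call per overlapped gene. CDS substitutions are
translated with the standard nuclear codon table on the coding strand
(strand-aware complementation); precedence is start_change (any change in
the annotated start codon) > stop_change (a stop created or destroyed) >
synonymous/non-synonymous. Intron positions within two bases of either
intron end are splice_region (more specific than intron); exon non-CDS is
utr; positions outside every gene span but within a configurable 1,000-bp
flank are upstream/downstream by strand, else intergenic. The flank width
is a convention, not a measurement, hence configurable. A brute-force
full-CDS retranslation oracle checks the classifier on hundreds of random
coding SNPs, and a reverse-complement metamorphic test checks strand
handling.

The selection screen treats per-sample synonymous counts as a Ks proxy and
non-synonymous counts as a Ka proxy (count ratios, not per-site rates —
per-site normalization is out of scope). Across samples it fits OLS of Ka
on Ks and classifies each sample against the 99% **prediction** band of
the regression: below = negative (purifying) selection, above = positive
selection, inside = neutral. A prediction band, not a confidence band, is
used because individual samples are being classified against the scatter
expected for a new observation.

## RFLP assay design

Recognition sites are scanned IUPAC-aware on both strands (palindromic
sites reported once; `N` in the sequence never matches). Digestion cuts
after `match_start - 1 + cut_offset` on top-strand matches; reverse-strand
matches of non-palindromic sites cut at `match_start - 1 + site_len -
cut_offset`. Fragments of a linear amplicon are the gaps between sorted
unique cut positions and always sum to the amplicon length. Candidate
assays require a 6- or 8-nt site flipped by the variant allele, at most
one additional cut of the same enzyme within +/- 2 kbp (so the gel pattern
stays interpretable), and an amplicon of 700–1,400 bp containing the SNP;
fragments under 50 bp are reported but flagged as effectively invisible on
a standard agarose gel. The shipped enzyme table covers common 5/6/8-bp
cutters (NdeI, SwaI, XbaI, EcoRI, HinfI, ...) and a TSV loader accepts
arbitrary (name, site, cut offset) tables; enzyme buffer/temperature
practicalities are not modeled.

## Synthetic cohorts

The generator builds a small multi-chromosome genome with 3-exon genes
(UTR stubs, valid start/stop codons, CDS length divisible by 3 — introns
exist so splice regions are testable), spike-in contigs, per-sample VCFs,
and depth tracks. Defaults describe the emulated study design: five
accessions (Gd, Re, Ka, Vx, Wi) with per-accession exclusive-SNP counts in
a 1:2:5:10:12 gradient mirroring genetic distance tracking geographic
distance; six samples per accession in two pedigrees of three (three
samples per pedigree, so pedigree-private variants survive the
sample-support filter, as in the real workflow where pedigree panels are
extracted after filtering); a handful of universal SNPs; 10% indels; ten
error calls per sample plus spike-in artifact calls; mean depth 30 with
10% of positions below the depth floor. The diploid-style encoding of each
sample adds 53% extra heterozygous calls, placing the haploid/diploid call
ratio at the ~65% level typical of a haploid organism run through a
diploid caller.

True variants are drawn to satisfy DP >= 9, AD >= 7, AD/DP > 0.77 in every
carrier sample; error calls draw either DP in 3–8 or allele fraction
<= 0.7. Filter recovery (100% true SNPs kept, 0% errors kept) is therefore
a consequence of the construction — the tests prove the filter implements
its definition, not that the thresholds are optimal on real data. Likewise
the generator plants no overlap between groups' exclusive variants, so
perfect panel precision/recall demonstrates correctness of the extraction
logic only. What the synthetic data does **not** emulate: read-level
errors (no FASTQ), mapping bias, shared polymorphism between accessions,
linkage, paralog-driven heterozygosity, or realistic site-frequency
spectra. Cohort-scale figures from real datasets (per-accession SNP
totals, SNPs-per-bp densities) require hundreds of samples and are not
reproduced at this scale.

Problem sizes used by the test suite and the acceptance script — 3
chromosomes of 20 kb, 24 genes, 30 samples, 20 seeded replicates for the
filter-calibration and clustering-recovery rates — were chosen so the full
suite completes in well under a minute while keeping every rate estimate
over hundreds to thousands of planted events.

## Numerical conventions

All coordinates are 1-based inclusive (VCF/GFF3 convention); BED output
converts to 0-based half-open at the boundary. Multi-allelic VCF lines are
split per alt allele with per-allele AD. QUAL percentiles use linear
interpolation. Newick branch lengths are written with 12 significant
digits so additive distances round-trip. All randomness flows from
explicit seeds; identical config + seed produces byte-identical output
files.
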