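# Methods

This note records the models, conventions, parameter choices and known
limits of the `xrcompare` pipeline, in the order data flows through it.

## Coordinates and read handling

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and show-coords tables (1-based inclusive, reverse orientation encoded by
a query start greater than its end) are converted at the I/O boundary
only.  Duplicate read removal keys on (chrom, start, end), mirroring a
coordinate-keyed `sort -u`; this collapses opposite-strand reads at
identical coordinates, and a `strand_aware` flag widens the key for
libraries where that matters.  Adapter trimming matches the adapter's
prefix before its first `N` run, leftmost position first, allowing 10 %
mismatches at overlaps of at least 3 nt — the common behaviour of 3′
adapter trimmers, without their full alignment machinery.

## Excised-oligomer statistics

The length histogram uses exact `end − start`.  The frequency matrix is
computed on one length class at a time (default 26 nt, the predominant
excision product); off-length or non-ACGT sequences are excluded with a
logged count.  Sequences are always oriented 5′→3′ of the excised strand
(reverse-complemented on minus-strand intervals), so the pyrimidine
enrichment at positions 19–21 — the lesion sitting 6–8 nt from the 3′
incision — appears at fixed columns.

## One-to-one homolog extraction

Three filters, in order:

1. *Thresholds.* Both ref and query lengths ≥ 400 bp and identity ≥ 80 %,
   inclusive on both boundaries.  Requiring both sides to pass the length
   filter is the conservative reading when alignments contain indels.
2. *Chaining.* Within each (ref chrom, query chrom, orientation) group,
   the maximum total-ref-length subset of segments that is pairwise
   non-overlapping and co-linear in both genomes (order reversed for
   inverted groups), found by weighted longest-increasing-subsequence
   dynamic programming over segments sorted by ref start; score ties break
   toward the smaller ref start so output is deterministic.  Group sizes
   here are small, so the O(n²) DP is exact and cheap.
3. *One-to-multiple removal.* Any pair whose region overlaps (≥ 1 bp,
   strand-blind) another pair's region in either species is removed along
   with its overlap partners, because the true ortholog among co-orthologs
   cannot be identified.  The survivors are mutually disjoint within each
   species.

Genome fraction is the summed region length over genome length per
species, in percent.

## Simulated-read null model

Excised oligomers are sequence-biased, so raw counts over regions confound
repair activity with base composition.  The null model draws candidates
uniformly over (region, offset, strand) — every valid L-mer start equally
likely — fetches error-free genomic sequence, scores each candidate by the
sum of log per-position frequencies under the real library's matrix
(floored at 1e−6 so empty cells cannot produce −∞; identical ranking to
the product of frequencies), and keeps the best-scoring N with
deterministic tie-breaking.  The candidate pool defaults to 3× the
selection size so selection is meaningful.  Sequencing-error and quality
models are deliberately omitted: downstream use is positional counting
only.  The selected set's frequency matrix moves strictly closer
(Frobenius norm) to the target matrix than the pool's — the mechanism by
which real/simulated RPKM ratios cancel composition bias — and this is
asserted in the test suite.

## TS/NTS metagene profiles

Genes closer than 20 kb (body-to-body, any strand; overlap counts as
distance 0) to another gene are removed pairwise, so opposing strand
signals from neighbours cannot cancel.  Around each TSS and TES, ±10 kb is
divided into 100-bp bins oriented in transcription direction.  A read is
assigned to at most one bin per gene window by its midpoint — the one-bin
rule that keeps pooled counts conservative.  A read mapping opposite to
the gene's annotated strand is transcribed-strand (TS, template) repair;
this convention is centralized in one place with a `--flip-ts`-style
escape hatch at the API level (swap the comparison).  Pooled bin counts
become RPKM using the bin's effective length (truncated at chromosome
ends) and the full sample's mapped-read total, and are divided by the RPKM
of the same reads repositioned uniformly at random (chromosome chosen by
length, strand redrawn).  Shuffled bins with zero reads are floored at the
one-read-equivalent RPKM; this only matters at low depth and is logged.
Per-gene TS/NTS ratios over the TSS-downstream 10-kb window (genes with
zero NTS reads excluded, logged) feed a two-sided Mann-Whitney U test
between species; the per-gene ratio is the only unit that yields
meaningful medians.

## Cross-species comparison

Per homolog pair and species, XR, simulated and RNA RPKM are computed with
≥ 1 bp strand-blind overlap counting (a read straddling a boundary counts
once per region) against the full-sample totals; normalized repair is
XR/simulated RPKM.  Pairs with zero XR, RNA or simulated reads in either
species are dropped pairwise.  The headline statistic is Pearson
correlation of log10 normalized repair (the scale on which the signal is
approximately normal; Spearman available as a sensitivity option).  The
expression-quartile bootstrap splits regions into rank-based quartiles of
each species' RNA RPKM separately (stable order breaks ties, sizes within
one), resamples each quartile with replacement at its own size 10 times,
and records the correlation per resample.  PCA of region × sample counts
uses median-of-ratios size factors followed by log2(x+1) as the variance
stabilization — a deliberate approximation whose downstream use (cluster
topology) is insensitive to the exact transform — then full-SVD PCA with a
fixed sign convention (largest-magnitude loading positive).

## The synthetic world

The generator emulates exactly the structures the analysis assumes:

* **Genomes.** i.i.d. uniform ACGT per species (chromosomes `h*` vs `m*`
  to catch name collisions), except homologous regions, which are copied
  between species with a planted per-site mutation count so realized
  identity is *exactly* the recorded value, uniform over [75 %, 98 %] so
  the 80 % filter genuinely bites.  Inverted regions (10 % by default) are
  reverse-complemented and placed in reverse order so they form valid
  inverted chains.  10 % of regions get a second, independently mutated
  ref-side copy on a *different* chromosome — a planted one-to-multiple
  relationship that survives chaining and must be caught by the
  one-to-one filter.
* **Genes.** Log-normal expression (σ = 1) shared across species;
  strands random; placement in index order on both species so homolog
  pairs are co-linear by construction.
* **Repair intensities.** Per-region log-normal with a shared-factor
  construction, `log λ_s = √ρ·z₀ + √((1−ρ)·v)·z_s`, giving cross-species
  Pearson correlation ρ on the log scale when v = 1.  With expression
  coupling on, v shrinks (default 0.25) for regions hosted by
  above-median-expression genes, so highly expressed quartiles have higher
  correlation by construction.  Coupling is off in the default config so
  plain ρ recovery is unconfounded.
* **Reads.** XR reads are a three-part mixture (region reads weighted by
  λ·length so region RPKM ∝ λ; genic reads weighted by expression with
  the TS strand chosen at odds a : 1, defaults 2.0 and 2.3 for the two
  species; uniform background).  Lengths follow a fixed distribution on
  16–30 nt with mode 26.  Read sequences get positions 19–21 overwritten
  from a pyrimidine-enriched damage matrix (reads ≥ 21 nt); the bias lives
  in the reads, not the genome.  RNA reads fall uniformly within gene
  bodies on the gene strand, genes drawn proportional to expression.

Scenario presets pin the study conditions used by the validation suite:
`tcr_world_config` (300 genes, all ≥ 21 kb apart on a 9-Mb genome, 85 %
genic reads — the spec's defaults pack 1,500 genes into 5 Mb, which is too
dense for 20-kb isolation, so metagene analyses use this preset),
`correlation_world_config` (500 gene-hosted regions, ~500 XR reads per
region, no duplications) and `expression_coupled_world_config` (ρ = 0.7 with coupling
0.25).  The ten-sample count design layers log-normal factors — shared
base, cell-type (fibroblast vs an independent lymphocyte landscape, SD
0.8), damage type (SD 0.5), species (SD 0.15), replicate noise (SD 0.05) —
and draws Poisson counts, reproducing the expected topology: cell types
separate first, then damage types, then species, with replicates tightest.
Because the species axis is the third/fourth variance direction, replicate
pairing is checked in a 4-component PC space while the outgroup check uses
PC1–PC2.

**What the synthetic world does not emulate:** chromatin domains,
replication timing, mappability structure, indel-containing alignments,
sequencing errors, and damage-site chemistry.  Passing tests therefore
demonstrate that the *algorithms* recover planted structure under the
model's assumptions, not that real libraries satisfy those assumptions.

## Numerical conventions and degenerate inputs

Scoring floor 1e−6; shuffled-RPKM floor one read-equivalent; selection,
chaining and PCA all carry deterministic tie-breaking; every stochastic
function takes an explicit seed and identical config + seed reproduces
byte-identical output files.  Empty inputs error early with specific
messages (no reads, no scorable candidates, quartiles below 3 regions,
constant count matrices, zero-variance correlation inputs).

## Problem sizes in the validation suite

The validation suite runs at desk scale: worlds of 5–9 Mb per species,
100k–300k reads per sample, simulated-null selections of 60k reads from
3× pools, and 20-seed Monte-Carlo loops for the statistical recoveries.
Recovered values carry the expected small attenuations — pooled TS/NTS
slightly below the planted odds because of the 15 % uniform background,
correlation R a few points below planted ρ because of Poisson counting
noise — and the acceptance bands account for exactly these effects.
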