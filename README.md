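# xrcompare

Comparative genome-wide analysis of nucleotide excision repair between two
species, from XR-seq data.

## The problem

XR-seq (eXcision Repair sequencing) captures the ~26-nt oligomers that the
nucleotide excision repair machinery cuts out around bulky DNA lesions
(UV photoproducts such as CPDs and (6–4)PPs), giving a genome-wide,
single-nucleotide map of where repair happens.  Comparing such maps between
two species asks whether the *distribution* of repair over the genome —
largely set by transcription and chromatin — is conserved, independently of
each species' overall repair *rate*.  Doing that honestly requires solving
four problems this package implements:

1. **Excised-oligomer statistics** — the read-length distribution (modal
   length 26 nt) and the position-specific nucleotide frequency matrix
   `f[p][b]`, whose pyrimidine enrichment at positions 19–21 reflects the
   fixed incision distance 3′ of the lesion (`readstats`).
2. **One-to-one homologous regions** — from a whole-genome alignment
   coordinate table: keep segments ≥ 400 bp on both sides with ≥ 80 %
   identity, reduce each (ref chrom, query chrom, orientation) group to its
   longest mutually consistent chain (maximum-weight co-linear subset via
   dynamic programming), and remove every region that aligns to multiple
   places in the other genome (`homology`).
3. **A simulated-read null model** — candidate reads drawn uniformly from
   the homolog regions are scored by
   `score(s) = Σ_p log f[p][s_p]`
   against the real library's frequency matrix and the best-scoring *N*
   kept; dividing real by simulated RPKM per region cancels the sequence-
   composition bias of excised oligomers (`xrsim`).
4. **The comparative statistics** — shuffle-normalized TS/NTS metagene
   profiles in 100-bp bins over ±10 kb around TSS/TES of genes ≥ 20 kb from
   any neighbour, with a Mann-Whitney U test on per-gene TS/NTS ratios
   (`repair_profiles`); Pearson correlation of log10 normalized repair
   across homolog pairs, an expression-quartile bootstrap of that
   correlation, and sample-clustering PCA of variance-stabilized region
   counts (`comparative`).

Throughout, RPKM = count / ((length/1000) · (total mapped reads/10⁶)), and a
read on the strand *opposite* a gene's annotated strand reports
transcribed-strand (TS, template) repair.

A first-class synthetic-data module (`synthetic_data`) generates two toy
"species" — genomes, genes with shared expression, homologous regions with
correlated log-normal repair intensities, planted one-to-multiple
duplications, and XR-seq/RNA-seq reads with a known TS:NTS odds ratio — so
every stage of the pipeline can be tested against recoverable ground truth
without any external download.

## Worked example

```python
import numpy as np
from xrcompare import (
    build_world, extract_homologs, genome_fraction, length_distribution,
    region_signals, repair_correlation, simulate_null_reads,
    simulate_rna_reads, simulate_xr_reads,
)
from xrcompare.synthetic_data import correlation_world_config, default_damage_bias

world = build_world(correlation_world_config(rho=0.8, seed=1))
pairs = extract_homologs(world.segments())
frac = genome_fraction(pairs, world.chrom_sizes)
print(f"{len(pairs)} one-to-one homolog pairs "
      f"({frac['a']:.2f}% / {frac['b']:.2f}% of each genome)")

reads, bias = {}, default_damage_bias()
ss = np.random.SeedSequence([1, 271]).spawn(6)
for i, sp in enumerate(("a", "b")):
    regions = [p.region_a if sp == "a" else p.region_b for p in pairs]
    reads[sp] = {
        "xr": simulate_xr_reads(world, sp, seed=ss[3 * i]),
        "rna": simulate_rna_reads(world, sp, seed=ss[3 * i + 1]),
        "sim": simulate_null_reads(regions, world.genome(sp), bias,
                                   60_000, seed=ss[3 * i + 2]),
    }
dist = length_distribution(reads["a"]["xr"])
print(f"modal excised-oligomer length: {max(dist, key=dist.get)} nt")

sig_a, sig_b = region_signals(pairs, reads["a"], reads["b"])
res = repair_correlation(sig_a, sig_b)
print(f"cross-species repair correlation: R = {res.r:.2f} "
      f"(n = {res.n} regions, p = {res.p_value:.2g})")
```

prints

```
400 one-to-one homolog pairs (21.66% / 21.66% of each genome)
modal excised-oligomer length: 26 nt
cross-species repair correlation: R = 0.76 (n = 400 regions, p = 3e-75)
```

The world was built with a planted cross-species log-intensity correlation
of ρ = 0.8 over 500 regions; 400 pairs survive the 80 %-identity filter,
and the measured R ≈ 0.76 recovers the planted value up to Poisson counting
noise.  The genome fraction is large only because this toy genome is 5 Mb;
on real mammalian genomes the same filters retain ~1 % of each genome.

## Command line

The same stages are exposed as `xrcompare <subcommand>` with subcommands
`simulate-world`, `readstats`, `homologs`, `xrsim`, `tcr-profile`,
`compare` and `pca`, plus global `--config` (YAML key-value file),
`--seed`, `--log-level` and `--out-dir`.  For example:

```bash
xrcompare --seed 3 --out-dir world simulate-world --preset correlation
xrcompare --out-dir out homologs --coords world/alignment.coords \
    --genome-size-a 5000000 --genome-size-b 5000000
xrcompare --out-dir out readstats --bed world/xr_a.bed --fasta world/genome_a.fa
```

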