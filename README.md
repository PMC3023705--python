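# rrlsnp

SNP discovery and comparative genome analysis for species **without a draft
genome**, built around the reduced-representation library (RRL) strategy:
digest pooled DNA from a panel of individuals with a frequent-cutting
restriction enzyme, sequence a gel-excised size window at usable depth, call
pooled SNPs from the read pileups, and borrow a divergent relative's assembly
to see where the markers live.  The package was developed around the
white-tailed deer (*Odocoileus virginianus*), which — like most wildlife
species — has no assembly of its own but a well-assembled relative (cattle)
against which contigs can be anchored.

It is aimed at conservation and population genomicists who need a tested,
scriptable version of each step, plus a synthetic-data generator that makes
the whole pipeline verifiable without any sequencing data.

## What it computes

**In-silico digestion** (`rrl_digest`).  Complete digestion at every
IUPAC-matched recognition site (AluI, AG^CT, by default), inclusive size
selection (350–400 bp by default), and the analytic fragment-length law for
an i.i.d. genome: the spacing between site occurrences is the first-passage
time of the site's prefix automaton, with geometric tail `P(L = k) ≈ p(1−p)^{k−1}`,
`p` the per-position site probability.

**Pooled SNP calling** (`snp_caller`).  Reads are gated at an aligned
fraction ≥ 0.90 and identity ≥ 0.90; a base supports a variant only under the
Neighborhood Quality Standard (NQS): central Phred ≥ 20, mean quality ≥ 15
over an 11-bp window, and ≤ 2 gap/mismatch discrepancies in that window
(central base excluded).  A column with NQS-filtered depth `d` (3 ≤ d ≤ 1000)
is called when a non-consensus allele has frequency ≥ 10% **or** count ≥ 3.
Pooled minor allele frequency is `MAF = c₂/d` with `c₂` the second-largest
allele count.  Calls carry homopolymer-proximity and clustering flags and a
coverage × minor-allele-count stratification.

**Comparative overlay** (`comparative_overlay`).  BLAST outfmt-6 hits with
E ≤ 1e-50 classify each contig as *unique* (one merged position on one named
chromosome), *informative* (one chromosome, ≤ 3 positions, optionally plus
one chrUn scaffold with ≤ 3 positions), *uninformative*, or *no hit*.
Uniquely anchored contigs project their SNPs into chromosome coordinates
(strand-aware, exactly invertible), giving per-chromosome densities
(unweighted mean ± sample SD across chromosomes) and SNP hotspots.

**Validation extrapolation** (`validation_extrapolation`).  Assay a sample
from each discovery stratum (coverage × minor allele count), drop assays that
fail genotype-clustering QC, and predict each stratum's true-SNP count as
`round_half_up(total_putative × validated/passing)`.  The shipped white-tailed
deer panel (six strata, 78 assays; a 38-assay mitochondrial panel) reproduces
the published-style totals: predictions 6791, 1951, 497, 648, 198, 363 from
10,739 putative SNPs → **10,448 nuclear**, mean class validation rate
**89.8%**, mitochondrial rate 28/38 = 74%, genome-wide **10,476**.

**Median-joining networks** (`haplotype_network`).  The
minimum-spanning-network of condensed haplotypes, augmented with quasi-median
vectors (tolerance ε, per-site weights), pruned of medians with degree < 3,
exportable as DOT / GraphML / TSV.  A brute-force Dreyfus–Wagner Steiner
oracle (`steiner`) verifies optimality on small binary instances.

**Synthetic data** (`synthetic_data`).  Equimolar pools of diploid
individuals (default 16), planted diallelic SNPs with binomially realized
pool frequencies, 454-style reads (~236 bp, substitution + homopolymer-indel
errors with degraded base qualities), truth SAM alignments, and BLAST hit
tables with independently derived classification truth.

## Worked example

```
$ rrlsnp simulate --genome-length 50000 --snp-density 4 --depth 50 --seed 11 --out-dir sim
199 variants, 11619 reads -> sim
$ rrlsnp call --sam sim/truth.sam --ref sim/reference.fa --out calls.vcf
183 putative SNPs -> calls.vcf
```

The simulator planted 199 diallelic SNPs in a 16-diploid pool and emitted
error-free 50X reads; the caller recovered 183 of them (the rest fall below
the 3X/10%-or-3 support rule in the realized reads — e.g. a 0.05-frequency
allele drawn by only two reads) and called nothing anywhere else.  A call in
`calls.vcf` looks like

```
ref1	520	.	T	G	.	HOMOPOLYMER	DP=50;AC=39,11;MAF=0.22
```

i.e. at reference position 520 (1-based), 11 of 50 NQS-passing reads carry G
(estimated pooled MAF 0.22), and the site sits near a homopolymer run, so it
would be excluded from assay candidates.

```
$ rrlsnp validate-extrapolate --mito-validated 28 --out table1.tsv
nuclear predicted 10448, genome-wide 10476 (mean class rate 89.8%)
```

runs the extrapolation engine on the shipped deer validation panel:
10,448 = Σ round_half_up(totalᵢ × rateᵢ) over the six strata, plus the 28
validated mitochondrial SNPs.

```
$ rrlsnp network --haplotypes haps.tsv --out net.dot
3 haplotypes, 1 median vectors, 3 links -> net.dot
```

three haplotypes pairwise two mutations apart yield one inferred median
vector joining them in a star (total length 3 instead of the spanning-tree 4).

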