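# Methods

This note records the models, parameter choices and numerical conventions
behind each module, what the synthetic data does and does not emulate, and
the known limitations.

## Coordinates and formats

All internal coordinates are 0-based half-open.  Conversions happen only at
format boundaries: VCF and BLAST tabular are 1-based inclusive, BED output is
0-based half-open, SAM goes through pysam.  BLAST minus-strand hits
(`sstart > send`) are normalized to ascending intervals with the strand
recorded.

## In-silico digestion

Digestion is modeled as complete: every recognition-site occurrence is cut
(the enzyme was chosen in the underlying protocol precisely for its ability
to digest the template fully), so partial-digestion probabilities are not
modeled.  Site matching is IUPAC-aware on the site side; ambiguous bases in
the *sequence* (N etc.) never match, which is the conservative choice for
masked or low-quality reference stretches.  Palindromic sites are scanned on
one strand; non-palindromic sites are also scanned as their reverse
complement with the cut offset mirrored.  Size selection uses inclusive
bounds (default 350–400 bp): gel excision is approximate in reality, so the
boundary convention is explicit and configurable rather than implied.

The analytic fragment-length law used for checking: under an i.i.d. base
model, the spacing between consecutive site occurrences is the first-passage
time of the site's KMP prefix automaton from its post-match state.  This is
exact (it reproduces the impossibility of spacings shorter than the site and
the small short-range correlations of overlapping windows) and converges to
the geometric law `p(1−p)^{k−1}` in the tail.  The empirical histogram of a
seeded 10 Mb uniform-composition genome agrees with this law within 3
standard errors in every 100-bp bin (checked up to 1.5 kb; ~39,000
fragments).

## Synthetic pooled data

The generator emulates the laboratory design the pipeline targets:

- **Pool**: 16 diploid individuals by default, equimolar; reads sample
  haplotypes uniformly.  Haploid mode (`ploidy=1`) covers organellar data.
- **Planted SNPs**: diallelic, at a configurable density (variants/kb).  The
  pool allele count at each site is drawn binomial(2n, MAF); sites drawn at
  count zero are discarded because an allele absent from the pool is
  undiscoverable.  The realized truth frequency is count/2n, and the carriers
  are explicit haplotype indices, so read-level truth is exact.
- **MAF distribution**: the default is uniform on [0.05, 0.5].  The true
  allele-frequency spectrum of the motivating dataset is unknown (only
  pool-level averages near 0.27–0.28 were estimated); uniform(0.05, 0.5) has
  mean 0.275, spans rare-but-discoverable to balanced alleles, and is
  exposed as configuration (`("uniform", lo, hi)` or `("point", p)`).
- **Reads**: single-end, mean 236 bp (SD 40), matching long-pyrosequencing
  read lengths; starts uniform within a fragment; fragments shorter than the
  read become full-fragment reads.  Substitution errors are i.i.d. per base;
  homopolymer indels occur once per run of length L ≥ 3 with probability
  `rate × (L−2)` capped at 0.5 — a simple monotone proxy for
  flow-space undercall/overcall, not a flowgram model.  Base qualities decay
  mildly 5′→3′ (mean 33 → 25, SD 3); **error bases get degraded qualities**
  (mean 10, SD 3, capped at 25), reproducing the quality/miscall correlation
  that makes quality-aware filtering meaningful.  Real 454 data additionally
  shows context-dependent error bursts and multi-base homopolymer slippage
  that this model does not attempt; conclusions from passing tests are about
  the calling logic, not about real-data error rates.
- **Alignments**: truth SAM records are emitted directly from the simulator
  (positions and CIGARs known exactly), so the caller is tested in isolation
  from any mapper.
- **BLAST fixtures**: hit tables are realized from per-contig placement
  plans; the intended multiplicities are non-overlapping by construction, so
  the plan itself (not the emitted rows) yields an independent truth status
  for the overlay classifier.

Determinism: every generator consumes a single `numpy` Generator seeded from
its model; identical seeds give byte-identical FASTA/FASTQ/SAM/TSV.

## NQS SNP calling

Caller defaults follow the strict reference-assembly parameterization:
aligned-fraction and identity gates at 0.90; NQS with central quality ≥ 20,
window 11 bp, window mean quality ≥ 15, and at most 2 discrepancies; depth
window 3–1000; support rule "frequency ≥ 10% **or** count ≥ 3".

Interpretations the thresholds do not pin down, with the conventions used:

- The support rule is a disjunction; a conjunction would make the count
  branch redundant at depths ≤ 30.
- The NQS discrepancy count excludes the central base (the candidate variant
  must not disqualify its own neighborhood); a gap run counts once however
  long; insertion events count once at their anchor position.  The window is
  truncated at read ends and the mean quality is taken over available bases.
- The window mean is the arithmetic mean over the full (available) window,
  central base included.
- The column consensus is the majority allele of the NQS-filtered column,
  ties broken in fixed base order A<C<G<T (vote-based conflict resolution).
- Homopolymer proximity (candidate-exclusion flag, not a calling filter):
  a single-base run of length ≥ 4 overlapping ±5 bp of the site.  Both
  thresholds are choices, exposed as arguments.
- Clustering flag: another call within 11 bp (the analysis window) on the
  same contig.

The pileup accumulator is vectorized per read; the scalar per-position NQS
predicate is kept as the reference semantics and the two are asserted
identical in the test suite.  Indel calling, genotype likelihoods and base
recalibration are out of scope: the pool yields allele frequencies, not
genotypes.

## Comparative overlay

A "chromosomal position" is a cluster of subject-overlapping HSPs (≥ 1 bp
overlap merges; a merge gap is configurable, 0 by default, the most
conservative reading).  Classification: ≥ 2 named chromosomes or ≥ 2 chrUn
scaffolds → uninformative; one named chromosome with ≤ 3 positions →
informative (unique when exactly one position and no chrUn partner); one
named chromosome (≤ 3 positions) plus exactly one chrUn scaffold (≤ 3
positions) → informative; a single chrUn scaffold alone with ≤ 3 positions
also anchors informatively but never uniquely and is never projected.
chrUn-ness is a configurable name pattern (default prefix `chrUn`,
case-insensitive), so no assembly's naming is hard-coded.

Projection uses the best-scoring HSP of a unique placement: plus strand
`chrom = s_lo + (offset − q_lo)`, minus strand mirrored within the subject
interval; offsets outside the aligned query interval are reported
unprojected.  The mapping is exactly invertible and the round-trip is tested
on both strands.

Density summaries count unique placements only (the mode shown by default;
hit-level counts are also emitted by the parser since raw-HSP vs merged
counts are both of interest).  The overall density is the **unweighted
per-chromosome mean ± sample SD** (ddof=1); the estimator is a choice —
the cross-chromosome dispersion quoted in this literature implies an
unweighted mean, but the exact estimator is typically unstated — and is
recorded in the output metadata.

## Validation extrapolation

Each stratum's prediction is `round_half_up(total × validated/passing)`.
Round-half-up is a documented choice: all reference rows are consistent with
it, and the three fractional cases (648.33, 198.33, 363.22) agree between
half-up and floor — a regression test asserts this so a silent rounding
change is caught.  The headline mean validation rate is the **unweighted mean
of per-class percentage rates** (89.8 on the shipped panel); the pooled rate
(validated/passing = 63/69 = 91.3) is also emitted but is not the headline.
Strata without QC-passing assays get no prediction and are excluded from
totals with a warning — extrapolating from zero information would be
arbitrary.  The genome-wide figure is defined as nuclear predicted + validated
organellar count (10,448 + 28 = 10,476 on the shipped panel); the two
figures are one identity, not independent estimates.  The "% of all"
column's denominator (all putative SNPs at 3–150X in single-hit contigs) is
dataset-specific and only filled in when supplied.

Candidate selection draws from uniquely placed contigs only, excludes
homopolymer-proximal and clustered calls, takes at most one SNP per contig,
and cycles chromosomes so none repeats before every represented chromosome
has a candidate; selection is deterministic under a seed.

## Median-joining networks

Links: a pair of sequence types is feasible when its weighted Hamming
distance is within ε of the threshold at which its two clusters first connect
(Kruskal sweep); ε = 0 gives exactly the union of all minimum spanning trees.
Medians: for every feasible link (u, v) and every third type w, the
coordinate-wise median (quasi-median with product expansion where all three
states differ, capped at 243 vectors) is a candidate; per round, candidates
with minimal connection cost `d(u,m)+d(v,m)+d(w,m)` are added, to a fixed
point (iteration cap 100, error on overrun).  Unsampled vectors with fewer
than three neighbours are then pruned, links recomputed after each removal
round.  Defaults ε = 0 and uniform weights match common practice; ties among
equal-cost links resolve lexicographically on the node state vectors, which
makes the construction order-independent (asserted under input permutation).

The network's *parsimony length* is defined as the exact minimal Steiner tree
**within the network graph** connecting the observed haplotypes, with median
vectors as optional junctions (Dreyfus–Wagner over the graph metric).  An
MST over all nodes would overstate the length whenever superfluous medians
survive pruning.

Two verification regimes, both against an independent brute-force
Dreyfus–Wagner Steiner oracle on the binary hypercube:

- ε = 0 (the default): exhaustively optimal on every haplotype subset of
  size ≤ 5 over 4 binary sites (6,868 instances), and the network always
  embeds an MST of its node set.
- ε ≥ instance diameter: the regime in which the construction provably
  retains every most-parsimonious connection.  Random 5-haplotype × 6-site
  instances are checked here, because at ε = 0 the greedy median selection
  can drop a needed median vector on rare topologies (observed on ~0.4% of
  random instances: an optimum requiring three median vectors of which the
  greedy pass finds two).  This mirrors the method's own guidance that
  parsimony guarantees hold "for sufficiently large ε".

Missing states are rejected rather than imputed — the intended inputs are
complete genotype tables over validated sites.

## Problem sizes in tests and the acceptance script

Simulation scales were fixed in advance as the smallest sizes that exercise
each claim: caller properties use a 50 kb genome at 4 SNPs/kb (~200 planted
SNPs, the size of the validation panels this design yields) at 50X; the
digestion law uses a 10 Mb genome (~39,000 fragments, enough for 3-SE bin
resolution); the overlay uses 1,000 contigs spanning every rule branch; the
Steiner comparison is exhaustive on the 4-site hypercube and sampled (150
seeded draws) for 5 × 6 instances, since the full 5 × 6 space (~7.6 million
subsets) is redundant with the exhaustive 4-site closure for rule coverage.

## Known limitations

- No flowgram-level 454 simulation, adapter/library chemistry, or diploid
  phasing; the pool model assumes exactly equimolar individuals.
- The caller emits SNPs only (no indels) and treats the supplied contig as
  the consensus; assembly itself is out of scope, as are repeat masking and
  running BLAST (alignments and hit tables are consumed, not produced).
- Validation assays are modeled only by their outcomes (pass QC / validated);
  no primer design or clustering chemistry.
- Density figures depend on the placement mode (unique vs all informative)
  and the estimator convention above; both are recorded in output metadata so
  numbers are comparable across runs.
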