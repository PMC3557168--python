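# Methods

## Scope and model

`rrlsnp` implements SNP discovery for near-homozygous (inbred, self-pollinated)
material sequenced through reduced-representation libraries (RRL): a restriction
digest with fragment size selection concentrates read depth on a reproducible
few percent of the genome, and candidate substitutions are called per genotype
from pileup columns against a reference assembly. Validation uses
genotyping-by-sequencing (GBS) of a biparental recombinant inbred line (RIL)
population: a real SNP between the two parents must segregate among the lines.

Because the material is assumed homozygous, there is no genotype-likelihood
model: the caller is a consensus-versus-reference test armored by a filter
stack. This is deliberate — the contribution is the filter stack and the
segregation validator, not a probabilistic caller — and it means heterozygous
sites are *rejected* (by the consensus-ratio filter), not called.

## The filter stack

At each covered site the consensus is the most frequent base call; a tie
yields no call (an explicit rule rather than arbitrary tie-breaking — ties
can only arise at even depth and would fail the ratio filter anyway). A
candidate exists when the consensus differs from the reference base
(reference-N sites are skipped). A candidate passes iff all of:

| filter | default | meaning |
|---|---|---|
| minimum depth | ≥ 3 reads | minimal replication of the observation |
| maximum depth | X̄ + 2s | guards against collapsed repeats / paralogs; X̄ and s (population SD) are estimated per genotype over its covered positions |
| consensus base ratio | ≥ 0.9 | near-fixed allele; rejects heterozygous and mixed-mapping sites |
| site quality | ≥ 20 | mean Phred base quality of consensus-supporting calls, capped by the RMS mapping quality when per-read mapping qualities are present |
| homopolymer context | run ≥ 3 | candidate inside or immediately abutting a reference homopolymer run |
| adjacency | gap < 2 bp | both members of a close pair removed, transitively through chains |

Two of these needed interpretation:

* **Site quality.** The original pipeline consumed a SNP quality emitted by an
  early SAMtools consensus caller whose exact formula is not reproducible
  here. The proxy — mean base quality of supporting calls, capped by RMS
  mapping quality — keeps the same intent (both base-call and placement
  confidence must clear 20) and is configurable (`CallerConfig.min_quality`).
* **Adjacency.** "Removal of very close SNPs" does not say whether one or
  both members go. Both are removed, and removal propagates through chains
  (positions 100, 102, 104 at min-gap 2 all go): the symmetric rule has no
  order dependence.

The depth statistics are computed over *covered* positions only (depth ≥ 1):
uncovered genome tells nothing about mapping depth, and in an RRL experiment
most of the genome is deliberately uncovered. The population (divide-by-n)
standard deviation is used so X̄ + 2s is a plain descriptive cutoff.

The GBS caller reuses the same thresholds per RIL, with one difference: a
consensus equal to the reference is a valid (reference-parent) call.

## Locus classification in the RIL population

With parental alleles (a₁, a₂) and per-RIL calls:

* **validated** — each parental allele carried by ≥ 2 RILs
  (`min_minor_lines`, configurable). A single discordant line can be a
  sequencing artifact, hence the floor of 2. Segregation is direct evidence,
  so no quorum of informative lines is required on this branch.
* **non_validated** — at least ⌊0.9·N⌋ informative calls (86 of 96) but no
  segregation. An allele seen in fewer than `min_minor_lines` lines is
  treated as noise: it neither proves segregation nor blocks this verdict.
* **ineligible** — everything else (too little information to decide).

The validation rate is reported over eligible loci only. Alleles matching
neither parent are tallied separately and excluded from both parental counts.
The quorum uses the floor because 0.9 · 96 = 86.4 and the operative published
threshold is "86 or more lines".

## Coverage summaries

* **Genome equivalents (X)** = total sequenced bases / estimated genome size
  (default 370 Mbp). This is raw coverage, not mapped coverage.
* **MCP / MRD** are computed in bins laid over the *concatenated* reference
  (contigs abutted in file order), default bin 0.5 Mbp. MCP divides covered
  positions by the bin's actual width — the final short bin is reported at
  its true width, never padded. MRD averages depth over covered positions
  only; an uncovered bin reports MRD 0 with a covered-flag false. The MCP
  denominator therefore reflects the assembly actually loaded, which is
  distinct from the (configurable) genome-size constant used for X.

## The simulator

The simulator emulates the study conditions end to end and is the source of
every test fixture:

* **Reference**: i.i.d. bases at a configurable GC fraction (default 0.38,
  a typical plant nuclear value), split into equal contigs.
* **Digest**: every (possibly overlapping) occurrence of the enzyme motif is
  cut; default TTAA with the cut one base in (T^TAA, standard MseI
  enzymology — the published protocol names the enzyme, not the offset,
  which shifts fragment lengths by ±1 only). Fragments of 350–425 bp
  (inclusive) are "excised". On a random 1 Mbp genome this selects roughly
  5–7% of positions, reproducing the genome-reduction character of an RRL.
* **Variants**: per-position Bernoulli implants per genotype
  (substitutions only; the pipeline does not call indels). Optional
  constraints — restriction to selected fragments, exclusion of homopolymer
  contexts, minimum 3 bp spacing — make every implant recoverable by the
  caller *by construction*; truth flags record which constraints each
  variant satisfies.
* **Pileups**: reads are not modeled individually; per-site depth is drawn
  from a gamma-Poisson (negative-binomial) model with configurable mean and
  overdispersion (`depth_dispersion=0` gives constant depth, used by the
  exact-recovery tests so no site falls below the depth minimum or above
  X̄ + 2s). Each call flips to a uniformly chosen different base with
  probability `base_error_rate`; qualities are Gaussian (mean 35, sd 3)
  clipped to [2, 41]. The digest is performed on the reference and the
  fragment set shared across genotypes so truth bookkeeping stays exact;
  per-genotype digests would differ only where an implant hits a motif.
* **RIL population**: default 96 lines, five selfing generations after F1
  (F6), so a locus stays residually heterozygous with probability
  (1/2)⁵ = 3.125%. Loci are inherited independently (no linkage map);
  heterozygous loci emit a 50:50 allele mixture which the homozygous caller
  rejects on the consensus ratio — they surface as missing calls, as in real
  GBS data.

What the simulator does **not** model: per-cycle quality decay, adapter and
duplicate artifacts, alignment errors (input is already pileup columns),
linked loci, and mapping-coverage autocorrelation beyond what fragment
structure induces. Passing the recovery tests therefore demonstrates the
correctness of the calling/filtering/validation logic under the stated error
model, not performance on real alignments.

## Numerical choices

* Consensus ratios and site qualities are quantized to 4 decimal places at
  candidate creation so TSV and VCF round-trips (the latter through float32
  FORMAT fields) are exact.
* All randomness flows from explicit seeds; a top-level seed is split per
  stage via `numpy.random.SeedSequence.spawn`. Identical seeds give
  byte-identical emitted files.
* Internal coordinates are uniformly 0-based half-open; external formats
  keep their native conventions, converted only at I/O boundaries.
* Pileup parsing resolves `.`/`,` to the reference base, strips `^`+qual and
  `$`, skips indel runs entirely, and counts `*` toward site depth but not
  toward base calls (its quality character is consumed and dropped). The
  declared depth column is reconciled to the parsed symbol count.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the simulator at desk scale:
genomes of 0.05–0.7 Mbp, 2–3 genotypes, 500-locus RIL experiments with 96
lines, and ≥ 10⁴ loci for the residual-heterozygosity check. These sizes give
the statistical properties being asserted (law-of-large-numbers bounds,
binomial intervals) comfortable margins while keeping any single test under a
minute. Genome-scale counts from the original study (tens of thousands of
SNPs from hundreds of millions of reads) depend on the raw archive data and
are out of scope; the published summary arithmetic is instead recomputed
directly from the printed table inputs.

## Known limitations

* No indel or heterozygote calling — out of scope by design.
* Gene-model input supports `gene`/`mRNA`/`CDS` with one level of Parent
  indirection; exotic GFF3 (multi-level, discontinuous features with shared
  IDs beyond CDS) is not handled.
* The published per-region discovery rates ("one SNP per 34,888 bp genic")
  cannot be reconciled with the printed counts under any single denominator;
  the characterizer reports rates from its own measured partition lengths
  (union of gene intervals vs the remainder) and does not attempt to
  reproduce those two printed numbers.
* `validate` loads RIL observations keyed by locus into memory; populations
  of ~100 lines by ~10⁴ loci are fine, biobank scale is not the target.
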