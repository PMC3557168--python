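# rrlsnp

SNP discovery from **reduced-representation libraries** (RRL) with
**genotyping-by-sequencing** (GBS) validation, for inbred, essentially
homozygous material such as self-pollinated crop genotypes.

An RRL concentrates sequencing depth on a reproducible few percent of a
genome: genomic DNA is cut with a frequent restriction enzyme (MseI, T^TAA),
fragments in a narrow size window (350–425 bp) are excised, and the resulting
libraries are sequenced and mapped to a reference assembly. `rrlsnp`
implements the downstream analysis:

* a **pileup-based multi-genotype SNP caller**: at every covered site the
  consensus base is compared with the reference, and a candidate passes only
  if it clears the full filter stack —
  depth ≥ 3, depth ≤ X̄ + 2s (per-genotype mean mapped depth plus two
  standard deviations, a repeat/paralog guard), consensus base ratio ≥ 0.9,
  site quality ≥ 20, no homopolymer run ≥ 3 containing or abutting the site,
  and no second candidate within 2 bp;
* **coverage and density summaries**: genome equivalents
  (X = total bases / genome size), and per-0.5-Mbp-bin mapping coverage
  percentage (MCP), mapped read depth (MRD) and SNP counts over the
  concatenated reference;
* a **SNP characterizer**: transition/transversion classes, genic /
  intergenic / CDS partition from gene models, cross-genotype sharing
  profile, discovery rates (SNPs per Kbp);
* a **GBS validator** for biparental recombinant inbred line (RIL)
  populations: a candidate is *validated* when both parental alleles
  segregate among the lines (each carried by ≥ 2 RILs), *non-validated* when
  ≥ 86 of 96 lines are informative but only one parental allele appears, and
  *ineligible* otherwise;
* a **simulator** that generates all of the above from scratch — reference,
  in-silico MseI digest with size selection, implanted genotype variants,
  negative-binomial depth / base-error pileups, and an F6 RIL population
  with (1/2)⁵ = 3.125 % residual heterozygosity — with exported truth sets.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a small experiment (200 kb genome, 2 genotypes, error-free reads at
uniform depth 10, 96 RILs), then discover, characterize and validate:

```bash
cat > sim.yaml <<EOF
genome_length: 200000
n_contigs: 2
n_genotypes: 2
snp_density: 0.002
depth_dispersion: 0.0
base_error_rate: 0.0
n_rils: 96
seed: 42
EOF

rrlsnp simulate --config sim.yaml --outdir sim
# simulated 47 truth variants -> sim

rrlsnp discover --reference sim/ref.fa \
    --pileup GT1=sim/GT1.pileup --pileup GT2=sim/GT2.pileup \
    --out snps.tsv --stats stats.tsv
# 46 SNPs -> snps.tsv

rrlsnp characterize --snps snps.tsv --reference sim/ref.fa --out report.json
# 46 SNPs: 21 transitions, 25 transversions (Ts/Tv 0.84),
# 0 genic / 46 intergenic, 0 in CDS

rrlsnp validate --snps snps.tsv --ril-matrix sim/ril_calls.tsv \
    --out validation.tsv --summary summary.json
# 22/22 eligible loci validated (100.0%)
```

The 47 implanted variants become 46 SNP records because one position carries
a variant in both genotypes and records are merged by location — the table's
genotype column lists both. The RIL matrix only segregates for the first
genotype's variants, so the second genotype's loci are ineligible
(monomorphic, reference-only) and the 22 eligible loci all validate. With
error-free reads the recovery is exact: every truth variant is called and
nothing else is (`sensitivity 1.0, FDR 0.0`); the depth statistics table
shows the X̄ + 2s cutoff per genotype:

```
genotype  mean_depth  sd_depth  max_depth_cutoff  n_covered_positions
GT1       10.0000     0.0000    10.0000           13573
GT2       10.0000     0.0000    10.0000           13573
```

Note the RRL character: only 13,573 of 200,000 positions (~7 %) are covered —
the size-selected MseI fragments.

The same operations are available as a library:

```python
from rrlsnp import SimConfig, simulate_experiment, discover_snps

exp = simulate_experiment(SimConfig(genome_length=200_000, seed=42))
snps, stats, candidates = discover_snps(
    {g: exp.pileup(g) for g in exp.genotype_sequences}, exp.reference
)
```

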