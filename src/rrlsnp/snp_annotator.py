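"""Characterization of a filtered SNP set.

Covers base-change classification (transition A<->G / C<->T versus
transversion), genomic region classes from gene models (genic / intergenic,
with a CDS flag), the cross-genotype sharing profile, and discovery-rate
summaries (SNPs per Kbp, bp per SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import GeneModelSet, ReferenceGenome
from .records import SNPRecord

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else
    'transversion'."""
    if ref_allele not in "ACGT" or alt_allele not in "ACGT":
        raise ValueError(f"alleles must be A/C/G/T, got {ref_allele!r}/{alt_allele!r}")
    if ref_allele == alt_allele:
        raise ValueError("alleles must differ")
    return "transition" if {ref_allele, alt_allele} in _TRANSITIONS else "transversion"


def tstv_ratio(transitions: int, transversions: int) -> float:
    if transversions == 0:
        return float("nan") if transitions == 0 else float("inf")
    return transitions / transversions


def annotate_region(snp: SNPRecord, gene_models: GeneModelSet) -> SNPRecord:
    """Fill region_class / cds_flag / substitution_class in place.

    A SNP is genic iff its position falls inside any gene interval; the CDS
    flag marks positions inside coding intervals.  Contigs absent from the
    annotation are intergenic by definition (an empty annotation renders the
    whole genome intergenic).
    """
    pos0 = snp.position - 1
    genic = gene_models.is_genic(snp.contig_id, pos0)
    snp.region_class = "genic" if genic else "intergenic"
    snp.cds_flag = genic and gene_models.is_cds(snp.contig_id, pos0)
    snp.substitution_class = classify_substitution(snp.ref_allele, snp.primary_alt)
    return snp


def sharing_profile(snps: Iterable[SNPRecord], n_genotypes: int) -> dict[int, int]:
    """Histogram over k = 1..n of SNPs present in exactly k genotypes."""
    hist = {k: 0 for k in range(1, n_genotypes + 1)}
    for s in snps:
        k = len(s.presence_set)
        if not 1 <= k <= n_genotypes:
            raise ValueError(f"presence-set size {k} outside 1..{n_genotypes}")
        hist[k] += 1
    return hist


def snp_rate(snp_count: int, region_length_bp: int) -> tuple[float, float]:
    """(SNPs per Kbp, bp per SNP) over a region; bp/SNP is NaN for 0 SNPs."""
    if region_length_bp <= 0:
        raise ValueError("region length must be positive")
    per_kbp = 1000.0 * snp_count / region_length_bp
    bp_per = region_length_bp / snp_count if snp_count else float("nan")
    return per_kbp, bp_per


@dataclass
class CharacterizationReport:
    total_snps: int
    transitions: int
    transversions: int
    tstv_ratio: float
    genic: int
    intergenic: int
    cds: int
    multiallelic_sites: int
    sharing: dict[int, int]
    snps_per_kbp: float
    bp_per_snp: float
    genic_snps_per_kbp: float
    intergenic_snps_per_kbp: float
    per_genotype: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.transitions + self.transversions == self.total_snps
        assert self.genic + self.intergenic == self.total_snps
        assert sum(self.sharing.values()) == self.total_snps

    def as_dict(self) -> dict:
        return {
            "total_snps": self.total_snps,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "tstv_ratio": self.tstv_ratio,
            "genic": self.genic,
            "intergenic": self.intergenic,
            "cds": self.cds,
            "multiallelic_sites": self.multiallelic_sites,
            "sharing": {str(k): v for k, v in self.sharing.items()},
            "snps_per_kbp": self.snps_per_kbp,
            "bp_per_snp": self.bp_per_snp,
            "genic_snps_per_kbp": self.genic_snps_per_kbp,
            "intergenic_snps_per_kbp": self.intergenic_snps_per_kbp,
            "per_genotype": self.per_genotype,
        }


def characterize(
    snps: Sequence[SNPRecord],
    gene_models: GeneModelSet,
    reference: ReferenceGenome,
    genotypes: Sequence[str] | None = None,
) -> CharacterizationReport:
    """Assemble the full characterization of a SNP set.

    Region denominators for the per-region rates come from the supplied gene
    models over the loaded reference: genic length is the union of gene
    intervals, intergenic the remainder.  The per-genotype breakdown counts a
    shared SNP once per genotype carrying it.
    """
    for s in snps:
        if s.region_class is None or s.substitution_class is None:
            annotate_region(s, gene_models)
    if genotypes is None:
        genotypes = sorted({g for s in snps for g in s.presence_set})
    n_gt = max(len(genotypes), 1)

    ts = sum(1 for s in snps if s.substitution_class == "transition")
    tv = len(snps) - ts
    genic = sum(1 for s in snps if s.region_class == "genic")
    cds = sum(1 for s in snps if s.cds_flag)
    multi = sum(1 for s in snps if s.is_multiallelic)
    sharing = sharing_profile(snps, n_gt) if snps else {k: 0 for k in range(1, n_gt + 1)}

    genic_len = gene_models.genic_length()
    total_len = reference.total_length
    intergenic_len = max(total_len - genic_len, 0)
    per_kbp, bp_per = snp_rate(len(snps), total_len)
    genic_rate = snp_rate(genic, genic_len)[0] if genic_len else float("nan")
    inter_rate = (
        snp_rate(len(snps) - genic, intergenic_len)[0] if intergenic_len else float("nan")
    )

    per_genotype: dict[str, dict[str, int]] = {}
    for gt in genotypes:
        mine = [s for s in snps if gt in s.presence_set]
        g = sum(1 for s in mine if s.region_class == "genic")
        per_genotype[gt] = {
            "identified": len(mine),
            "intergenic": len(mine) - g,
            "genic": g,
            "cds": sum(1 for s in mine if s.cds_flag),
        }

    report = CharacterizationReport(
        total_snps=len(snps),
        transitions=ts,
        transversions=tv,
        tstv_ratio=tstv_ratio(ts, tv),
        genic=genic,
        intergenic=len(snps) - genic,
        cds=cds,
        multiallelic_sites=multi,
        sharing=sharing,
        snps_per_kbp=per_kbp,
        bp_per_snp=bp_per,
        genic_snps_per_kbp=genic_rate,
        intergenic_snps_per_kbp=inter_rate,
        per_genotype=per_genotype,
    )
    report.validate()
    return report
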