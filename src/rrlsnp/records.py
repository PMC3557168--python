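"""Shared record types exchanged between the caller, annotator and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SNPRecord:
    """A filtered substitution SNP merged across genotypes.

    One record per (contig, position).  ``alt_alleles`` maps each genotype in
    which the candidate passed every filter to the consensus base observed in
    that genotype; different genotypes may carry different alternate bases
    (multi-allelic site).  ``depth``/``consensus_ratio``/``quality`` are kept
    per genotype, aligned with ``alt_alleles``.

    ``position`` is 1-based and contig-local, matching pileup/VCF conventions.
    Annotation fields (``region_class``, ``cds_flag``, ``substitution_class``)
    are filled in by the annotator and default to None until then.
    """

    contig_id: str
    position: int
    ref_allele: str
    alt_alleles: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    consensus_ratio: dict[str, float] = field(default_factory=dict)
    quality: dict[str, float] = field(default_factory=dict)
    region_class: str | None = None  # "genic" | "intergenic"
    cds_flag: bool | None = None
    substitution_class: str | None = None  # "transition" | "transversion"

    @property
    def presence_set(self) -> frozenset[str]:
        return frozenset(self.alt_alleles)

    @property
    def primary_alt(self) -> str:
        """Alternate base of the first genotype in insertion order.

        Used for substitution classification when genotypes disagree; the
        number of such multi-allelic sites is reported separately.
        """
        return next(iter(self.alt_alleles.values()))

    @property
    def is_multiallelic(self) -> bool:
        return len(set(self.alt_alleles.values())) > 1

    def sort_key(self) -> tuple[str, int]:
        return (self.contig_id, self.position)
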