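"""Validation of candidate SNPs by segregation in a recombinant inbred line
(RIL) population genotyped by sequencing.

Each RIL is called at each candidate locus with the same thresholds as the
discovery caller (minimum depth, consensus ratio, quality); calls failing any
threshold — including residually heterozygous lines whose ratio falls between
the two homozygous bands — are missing.  A locus is then

* ``validated``   — both parental alleles observed, each in at least
  ``min_minor_lines`` RILs (segregation is direct evidence, so no quorum of
  informative lines is required on this branch);
* ``non_validated`` — at least ``floor(eligibility_fraction * n_rils)``
  informative calls (86 of 96 at the default 0.9) but no segregation: at
  most one parental allele is carried by enough lines;
* ``ineligible``  — anything else (too few informative lines to decide).

The validation rate is computed over eligible loci only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_io import SiteObservation
from .records import SNPRecord
from .snp_caller import CallerConfig


@dataclass
class RILCall:
    ril_id: str
    contig_id: str
    position: int
    allele: str | None  # None = missing
    depth: int = 0
    consensus_ratio: float = 0.0


@dataclass
class LocusValidation:
    contig_id: str
    position: int
    parent_alleles: tuple[str, str]  # (reference-parent, alternate-parent)
    n_called: int
    allele_counts: dict[str, int]
    status: str  # validated | non_validated | ineligible

    @property
    def n_off_parent(self) -> int:
        p1, p2 = self.parent_alleles
        return sum(v for k, v in self.allele_counts.items() if k not in (p1, p2))


@dataclass
class ValidationSummary:
    n_candidates: int
    n_eligible: int
    n_validated: int
    n_non_validated: int

    @property
    def validation_rate(self) -> float:
        """Percent validated among eligible loci; NaN with no eligible locus."""
        return validation_rate(self.n_validated, self.n_non_validated)


def validation_rate(n_validated: int, n_non_validated: int) -> float:
    n_eligible = n_validated + n_non_validated
    if n_eligible == 0:
        return float("nan")
    return 100.0 * n_validated / n_eligible


def call_ril_allele(
    observations: Sequence[SiteObservation],
    config: CallerConfig | None = None,
) -> RILCall:
    """Homozygous allele call for one RIL at one locus.

    Unlike discovery, the consensus may equal the reference base — a valid
    reference-parent call.  Any threshold failure yields a missing call.
    """
    config = config or CallerConfig()
    if not observations:
        raise ValueError("no observations supplied")
    obs = observations[0]
    miss = RILCall(obs.genotype_id, obs.contig_id, obs.position, None, obs.depth)
    if obs.depth < config.min_depth or not obs.base_calls:
        return miss
    counts = Counter(b for b in obs.base_calls if b != "N")
    if not counts:
        return miss
    ranked = counts.most_common(2)
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return miss
    consensus, top = ranked[0]
    ratio = top / len(obs.base_calls)
    if ratio < config.min_consensus_ratio:
        return miss
    quals = [q for b, q in zip(obs.base_calls, obs.base_quals) if b == consensus]
    if sum(quals) / len(quals) < config.min_quality:
        return miss
    return RILCall(obs.genotype_id, obs.contig_id, obs.position, consensus, obs.depth, round(ratio, 4))


def classify_locus(
    ril_calls: Iterable[RILCall],
    n_rils_total: int,
    parent_alleles: tuple[str, str],
    eligibility_fraction: float = 0.9,
    min_minor_lines: int = 2,
) -> LocusValidation:
    """Classify one candidate locus from per-RIL allele calls.

    RIL alleles matching neither parent are tallied separately and excluded
    from the parental counts, so a handful of discordant calls cannot fake
    segregation.
    """
    p_ref, p_alt = parent_alleles
    if p_ref == p_alt:
        raise ValueError("parent alleles must differ")
    if n_rils_total < 1:
        raise ValueError("n_rils_total must be >= 1")
    calls = list(ril_calls)
    counts: dict[str, int] = Counter(
        c.allele for c in calls if c.allele is not None
    )
    n_called = sum(counts.values())
    contig = calls[0].contig_id if calls else "?"
    position = calls[0].position if calls else 0
    quorum = math.floor(eligibility_fraction * n_rils_total)
    # an allele "observed" below min_minor_lines is treated as noise: it
    # neither demonstrates segregation nor blocks the non-validated verdict
    segregates = counts.get(p_ref, 0) >= min_minor_lines and counts.get(p_alt, 0) >= min_minor_lines
    if segregates:
        status = "validated"
    elif n_called >= quorum:
        status = "non_validated"
    else:
        status = "ineligible"
    return LocusValidation(contig, position, parent_alleles, n_called, dict(counts), status)


def validate(
    candidates: Sequence[SNPRecord],
    ril_observations: Mapping[str, Mapping[tuple[str, int], SiteObservation]] | None = None,
    call_matrix: Mapping[tuple[str, int], Mapping[str, str | None]] | None = None,
    n_rils_total: int | None = None,
    alt_parent: str | None = None,
    config: CallerConfig | None = None,
    eligibility_fraction: float = 0.9,
    min_minor_lines: int = 2,
) -> tuple[ValidationSummary, list[LocusValidation]]:
    """Validate candidate SNPs against a RIL population.

    Input is either ``ril_observations`` (ril_id -> locus -> pileup column,
    calls made here with the discovery thresholds) or a precomputed
    ``call_matrix`` (locus -> ril_id -> allele or None).  ``alt_parent``
    selects which genotype's alternate allele defines the segregating allele
    when candidates carry several; by default the first recorded one.
    """
    config = config or CallerConfig()
    if (ril_observations is None) == (call_matrix is None):
        raise ValueError("supply exactly one of ril_observations or call_matrix")
    if ril_observations is not None:
        ril_ids = sorted(ril_observations)
        if len(set(ril_ids)) != len(ril_ids):
            raise ValueError("duplicate RIL identifiers")
        n_total = n_rils_total or len(ril_ids)
    else:
        all_rils = {r for locus in call_matrix.values() for r in locus}
        n_total = n_rils_total or len(all_rils)

    per_locus: list[LocusValidation] = []
    n_validated = n_non = 0
    for cand in candidates:
        locus = (cand.contig_id, cand.position)
        p_alt = (
            cand.alt_alleles.get(alt_parent) if alt_parent else None
        ) or cand.primary_alt
        parents = (cand.ref_allele, p_alt)
        if ril_observations is not None:
            calls = [
                call_ril_allele([ril_observations[r][locus]], config)
                for r in ril_ids
                if locus in ril_observations[r]
            ]
        else:
            calls = [
                RILCall(r, cand.contig_id, cand.position, allele)
                for r, allele in call_matrix.get(locus, {}).items()
            ]
        lv = classify_locus(calls, n_total, parents, eligibility_fraction, min_minor_lines)
        if not calls:
            lv = LocusValidation(
                cand.contig_id, cand.position, parents, 0, {}, "ineligible"
            )
        per_locus.append(lv)
        n_validated += lv.status == "validated"
        n_non += lv.status == "non_validated"
    summary = ValidationSummary(
        n_candidates=len(candidates),
        n_eligible=n_validated + n_non,
        n_validated=n_validated,
        n_non_validated=n_non,
    )
    return summary, per_locus


def read_call_matrix(path) -> tuple[dict[tuple[str, int], dict[str, str | None]], list[str]]:
    """Read the RIL call-matrix TSV: rows = loci, columns = RILs, cells in
    {A,C,G,T,-} with '-' for missing.  First two columns are contig, position."""
    matrix: dict[tuple[str, int], dict[str, str | None]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["contig", "position"]:
            raise ValueError("call matrix must start with contig, position columns")
        rils = header[2:]
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            locus = (cols[0], int(cols[1]))
            matrix[locus] = {
                r: (None if c == "-" else c) for r, c in zip(rils, cols[2:])
            }
    return matrix, rils


def write_call_matrix(
    matrix: Mapping[tuple[str, int], Mapping[str, str | None]],
    rils: Sequence[str],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\t" + "\t".join(rils) + "\n")
        for (contig, pos) in sorted(matrix):
            row = matrix[(contig, pos)]
            fh.write(
                f"{contig}\t{pos}\t"
                + "\t".join(row.get(r) or "-" for r in rils)
                + "\n"
            )


def write_validation_table(per_locus: Sequence[LocusValidation], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tparent_ref\tparent_alt\tn_called\tallele_counts\tstatus\n")
        for lv in per_locus:
            counts = ",".join(f"{a}:{n}" for a, n in sorted(lv.allele_counts.items()))
            fh.write(
                f"{lv.contig_id}\t{lv.position}\t{lv.parent_alleles[0]}\t"
                f"{lv.parent_alleles[1]}\t{lv.n_called}\t{counts or '.'}\t{lv.status}\n"
            )
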