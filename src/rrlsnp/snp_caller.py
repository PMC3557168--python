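"""Pileup-based multi-genotype substitution SNP caller with the AGSNP-style
filter stack.

The caller targets inbred, essentially homozygous material: at each covered
site the consensus (most frequent) base is compared with the reference, and a
candidate variant survives only if it passes all of

* minimum mapped read depth (default ≥ 3),
* maximum mapped read depth X̄ + 2s, evaluated with the genotype's own depth
  statistics (repeat/paralog guard),
* consensus base ratio ≥ 0.9 (near-fixed allele, heterozygous or mixed sites
  are rejected),
* site quality ≥ 20 — the mean Phred base quality of consensus-supporting
  calls, additionally capped by the RMS mapping quality when per-read mapping
  qualities are available,
* not inside or immediately adjacent to a reference homopolymer run of ≥ 3,
* not within 2 bp of another candidate of the same genotype (both members of
  a close pair are removed; removal propagates through chains).

Candidates passing in at least one genotype are merged into
:class:`~rrlsnp.records.SNPRecord` keyed by (contig, position).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .depth_stats import DepthStats
from .genome_io import ReferenceGenome, SiteObservation
from .records import SNPRecord

logger = logging.getLogger(__name__)

FILTER_NAMES = ("low_depth", "high_depth", "low_ratio", "low_quality", "homopolymer", "adjacent")


@dataclass
class CallerConfig:
    """Thresholds of the SNP filter stack; defaults are the discovery settings."""

    min_depth: int = 3
    max_depth_mode: str = "auto"  # "auto" = per-genotype X̄+2s, or "fixed"
    max_depth_fixed: float | None = None
    min_consensus_ratio: float = 0.9
    min_quality: float = 20.0
    homopolymer_min_run: int = 3
    min_gap_between_snps: int = 2

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_quality < 0 or self.min_consensus_ratio < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_gap_between_snps < 0:
            raise ValueError("min_gap_between_snps must be >= 0")
        if self.max_depth_mode not in ("auto", "fixed"):
            raise ValueError("max_depth_mode must be 'auto' or 'fixed'")
        if self.max_depth_mode == "fixed" and self.max_depth_fixed is None:
            raise ValueError("fixed max-depth mode needs max_depth_fixed")


@dataclass
class CandidateSNP:
    genotype_id: str
    contig_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth: int
    consensus_ratio: float
    quality: float
    filter_flags: set[str] = field(default_factory=set)

    @property
    def passes(self) -> bool:
        return not self.filter_flags


def call_candidate(site: SiteObservation) -> CandidateSNP | None:
    """Consensus-vs-reference call at one site; None when no variant.

    The consensus base is the most frequent among the base calls; a tie for
    the top count yields no call.  The consensus ratio divides by the number
    of base calls (deletion placeholders contribute to site depth but carry
    no base evidence).  Site quality is the mean Phred quality of the
    consensus-supporting calls, capped by the RMS mapping quality when
    mapping qualities are present.
    """
    if site.ref_base not in "ACGT" or not site.base_calls:
        return None
    counts = Counter(b for b in site.base_calls if b != "N")
    if not counts:
        return None
    ranked = counts.most_common(2)
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None  # ambiguous consensus
    consensus, top = ranked[0]
    if consensus == site.ref_base:
        return None
    ratio = top / len(site.base_calls)
    support_quals = [
        q for b, q in zip(site.base_calls, site.base_quals) if b == consensus
    ]
    quality = sum(support_quals) / len(support_quals)
    if site.map_quals:
        rms_mq = math.sqrt(sum(q * q for q in site.map_quals) / len(site.map_quals))
        quality = min(quality, rms_mq)
    return CandidateSNP(
        genotype_id=site.genotype_id,
        contig_id=site.contig_id,
        position=site.position,
        ref_allele=site.ref_base,
        alt_allele=consensus,
        depth=site.depth,
        consensus_ratio=round(ratio, 4),
        quality=round(quality, 4),
    )


def apply_site_filters(
    candidate: CandidateSNP, stats: DepthStats, config: CallerConfig
) -> CandidateSNP:
    """Depth, ratio and quality thresholds; returns the flagged candidate."""
    if stats.genotype_id != candidate.genotype_id:
        raise ValueError("depth stats belong to a different genotype")
    flags = set(candidate.filter_flags)
    if candidate.depth < config.min_depth:
        flags.add("low_depth")
    cutoff = (
        config.max_depth_fixed
        if config.max_depth_mode == "fixed"
        else stats.max_depth_cutoff
    )
    if candidate.depth > cutoff:
        flags.add("high_depth")
    if candidate.consensus_ratio < config.min_consensus_ratio:
        flags.add("low_ratio")
    if candidate.quality < config.min_quality:
        flags.add("low_quality")
    return replace(candidate, filter_flags=flags)


def homopolymer_context(sequence: str, pos0: int, min_run: int) -> bool:
    """True when the maximal identical-base run containing ``pos0``, or the
    maximal run immediately left or right of it, has length ≥ ``min_run``."""

    def run_length(i: int) -> int:
        b = sequence[i]
        lo = i
        while lo > 0 and sequence[lo - 1] == b:
            lo -= 1
        hi = i
        while hi + 1 < len(sequence) and sequence[hi + 1] == b:
            hi += 1
        return hi - lo + 1, lo, hi

    length, lo, hi = run_length(pos0)
    if length >= min_run:
        return True
    if lo > 0 and run_length(lo - 1)[0] >= min_run:
        return True
    if hi + 1 < len(sequence) and run_length(hi + 1)[0] >= min_run:
        return True
    return False


def filter_homopolymer(
    candidate: CandidateSNP, reference: ReferenceGenome, min_run: int = 3
) -> CandidateSNP:
    """Flag candidates sitting in or abutting a reference homopolymer run."""
    seq = reference.sequence(candidate.contig_id)
    pos0 = candidate.position - 1
    if not 0 <= pos0 < len(seq):
        raise IndexError(
            f"candidate position {candidate.position} outside contig {candidate.contig_id}"
        )
    if homopolymer_context(seq, pos0, min_run):
        return replace(candidate, filter_flags=candidate.filter_flags | {"homopolymer"})
    return candidate


def filter_adjacent(
    candidates: list[CandidateSNP], min_gap: int = 2
) -> list[CandidateSNP]:
    """Flag clusters of close candidates within one genotype.

    With ``gap = pos2 - pos1 - 1`` between consecutive same-contig candidates,
    any gap < ``min_gap`` flags BOTH members; the flag propagates through
    chains, so three candidates spaced 2 apart are all removed.  Input must be
    sorted by (contig, position).
    """
    keys = [(c.contig_id, c.position) for c in candidates]
    if keys != sorted(keys):
        raise ValueError("candidates must be sorted by (contig, position)")
    flagged = [False] * len(candidates)
    for i in range(1, len(candidates)):
        a, b = candidates[i - 1], candidates[i]
        if a.contig_id == b.contig_id and (b.position - a.position - 1) < min_gap:
            flagged[i - 1] = flagged[i] = True
    return [
        replace(c, filter_flags=c.filter_flags | {"adjacent"}) if f else c
        for c, f in zip(candidates, flagged)
    ]


def _call_genotype(
    observations: Iterable[SiteObservation],
    genotype_id: str,
    reference: ReferenceGenome,
    config: CallerConfig,
) -> tuple[list[CandidateSNP], DepthStats]:
    """Single pass: depth stats + raw candidates, then the staged filters."""
    n = 0
    total = 0.0
    total_sq = 0.0
    raw: list[CandidateSNP] = []
    for obs in observations:
        if obs.depth >= 1:
            n += 1
            total += obs.depth
            total_sq += obs.depth * obs.depth
        cand = call_candidate(obs)
        if cand is not None:
            raw.append(cand)
    if n == 0:
        stats = DepthStats(genotype_id, float("nan"), float("nan"), 0)
        return [], stats
    mean = total / n
    var = max(total_sq / n - mean * mean, 0.0)
    stats = DepthStats(genotype_id, mean, math.sqrt(var), n)

    staged = [apply_site_filters(c, stats, config) for c in raw]
    staged = [filter_homopolymer(c, reference, config.homopolymer_min_run) for c in staged]
    staged.sort(key=lambda c: (c.contig_id, c.position))
    staged = filter_adjacent(staged, config.min_gap_between_snps)
    _log_filter_counts(genotype_id, staged)
    return staged, stats


def _log_filter_counts(genotype_id: str, candidates: list[CandidateSNP]) -> None:
    per_flag = Counter(f for c in candidates for f in c.filter_flags)
    n_pass = sum(1 for c in candidates if c.passes)
    logger.info(
        "%s: %d candidates, %d passing, removed per filter: %s",
        genotype_id,
        len(candidates),
        n_pass,
        dict(per_flag),
    )


def discover_snps(
    pileups: Mapping[str, Iterable[SiteObservation]],
    reference: ReferenceGenome,
    config: CallerConfig | None = None,
) -> tuple[list[SNPRecord], dict[str, DepthStats], dict[str, list[CandidateSNP]]]:
    """Run the full per-genotype calling + filter pipeline and merge.

    ``pileups`` maps genotype id to its site-observation stream.  Returns the
    merged passing SNP records (sorted by contig, position), the per-genotype
    depth statistics, and all candidates (flagged and passing) per genotype.
    """
    config = config or CallerConfig()
    stats_by_gt: dict[str, DepthStats] = {}
    candidates_by_gt: dict[str, list[CandidateSNP]] = {}
    merged: dict[tuple[str, int], SNPRecord] = {}
    for gt in sorted(pileups):
        cands, stats = _call_genotype(pileups[gt], gt, reference, config)
        if stats.n_covered_positions == 0:
            logger.warning("genotype %s has zero covered positions; excluded", gt)
            continue
        stats_by_gt[gt] = stats
        candidates_by_gt[gt] = cands
        for c in cands:
            if not c.passes:
                continue
            key = (c.contig_id, c.position)
            rec = merged.get(key)
            if rec is None:
                rec = SNPRecord(c.contig_id, c.position, c.ref_allele)
                merged[key] = rec
            rec.alt_alleles[gt] = c.alt_allele
            rec.depth[gt] = c.depth
            rec.consensus_ratio[gt] = c.consensus_ratio
            rec.quality[gt] = c.quality
    snps = sorted(merged.values(), key=SNPRecord.sort_key)
    return snps, stats_by_gt, candidates_by_gt


def estimate_false_positive_rate(n_self_snps: int, reference_length: int) -> float:
    """Self-mapping error rate per nucleotide.

    Mapping the reference genotype's own reads against the reference should
    call nothing; the rate of sites the caller does produce estimates the
    combined sequencing + mapping error ("false positive") rate.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    return n_self_snps / reference_length
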