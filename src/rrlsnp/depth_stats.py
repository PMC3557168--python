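"""Per-genotype depth summaries, genome-equivalent coverage and binned MCP/MRD.

Definitions follow the reduced-representation mapping vocabulary:

* X (genome equivalents) — total sequenced bases / genome size.
* X̄, s — mean and (population) standard deviation of mapped read depth over
  covered positions (depth ≥ 1); X̄ + 2s is the maximum-depth cutoff used to
  discard repeat- or paralog-inflated sites.
* MCP (mapping coverage percentage) — percent of positions in a genome bin
  covered by at least one read.
* MRD (mapped read depth) — mean depth over covered positions in a bin.

Bins are laid over the *concatenated* reference: contigs are abutted in file
order and the genome-wide coordinate is split into windows of ``bin_size``
(default 0.5 Mbp); the last bin keeps its true, possibly shorter, width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genome_io import ReferenceGenome, SiteObservation
from .records import SNPRecord

DEFAULT_BIN_SIZE = 500_000
DEFAULT_GENOME_SIZE = 370_000_000  # estimated genome size used for X


@dataclass
class DepthStats:
    genotype_id: str
    mean_depth: float
    sd_depth: float
    n_covered_positions: int

    @property
    def max_depth_cutoff(self) -> float:
        """X̄ + 2s, the per-genotype maximum mapped read depth."""
        return self.mean_depth + 2.0 * self.sd_depth


@dataclass
class CoverageSummary:
    genotype_id: str
    n_reads: int
    total_bases: int
    genome_size: int = DEFAULT_GENOME_SIZE

    @property
    def genome_equivalents(self) -> float:
        return genome_equivalents(self.total_bases, self.genome_size)


@dataclass
class BinStats:
    bin_index: int
    start: int  # concatenated coordinate, 0-based half-open
    end: int
    mcp: float  # percent of bin positions with depth >= 1
    mrd: float  # mean depth over covered positions; 0 when covered is False
    covered: bool
    snp_count: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start


def depth_summary(
    observations: Iterable[SiteObservation], genotype_id: str
) -> DepthStats:
    """Mean/SD of mapped depth over covered positions for one genotype.

    Positions absent from the stream are uncovered and do not enter the
    average; the standard deviation is the population form (divide by n) so
    the X̄ + 2s cutoff is a plain descriptive statistic.
    """
    n = 0
    total = 0.0
    total_sq = 0.0
    for obs in observations:
        if obs.genotype_id != genotype_id:
            raise ValueError(
                f"observation for {obs.genotype_id!r} in stream for {genotype_id!r}"
            )
        if obs.depth < 1:
            continue
        n += 1
        total += obs.depth
        total_sq += obs.depth * obs.depth
    if n == 0:
        return DepthStats(genotype_id, float("nan"), float("nan"), 0)
    mean = total / n
    var = max(total_sq / n - mean * mean, 0.0)
    return DepthStats(genotype_id, mean, float(np.sqrt(var)), n)


def genome_equivalents(total_bases: float, genome_size: float = DEFAULT_GENOME_SIZE) -> float:
    """Raw sequence coverage X = total read length / genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_bases / genome_size


def mapping_percentage(n_mapped: int, n_total: int) -> float:
    """Percent of reads mapped, as printed in read-mapping summaries."""
    if n_total <= 0:
        raise ValueError("total read count must be positive")
    return 100.0 * n_mapped / n_total


def _bin_edges(total_length: int, bin_size: int) -> list[tuple[int, int]]:
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    edges = []
    start = 0
    while start < total_length:
        edges.append((start, min(start + bin_size, total_length)))
        start += bin_size
    return edges


def bin_coverage(
    observations: Iterable[SiteObservation],
    reference: ReferenceGenome,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[BinStats]:
    """Per-bin MCP and MRD for one genotype's site observations.

    Every reference position belongs to exactly one bin via the concatenated
    coordinate; the MCP denominator is the bin's actual width, so the short
    final bin is never padded.
    """
    edges = _bin_edges(reference.total_length, bin_size)
    n_bins = len(edges)
    covered = np.zeros(n_bins, dtype=np.int64)
    depth_sum = np.zeros(n_bins, dtype=np.float64)
    for obs in observations:
        if obs.depth < 1:
            continue
        if obs.pos0 >= reference.contig_length(obs.contig_id):
            raise ValueError(
                f"observation at {obs.contig_id}:{obs.position} beyond contig end"
            )
        coord = reference.concat_coord(obs.contig_id, obs.pos0)
        b = coord // bin_size
        covered[b] += 1
        depth_sum[b] += obs.depth
    out = []
    for i, (start, end) in enumerate(edges):
        width = end - start
        is_cov = covered[i] > 0
        out.append(
            BinStats(
                bin_index=i,
                start=start,
                end=end,
                mcp=100.0 * covered[i] / width,
                mrd=float(depth_sum[i] / covered[i]) if is_cov else 0.0,
                covered=bool(is_cov),
            )
        )
    return out


def bin_snp_density(
    snps: Iterable[SNPRecord],
    reference: ReferenceGenome,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[int]:
    """SNP count per concatenated-coordinate bin; counts sum to the input size."""
    edges = _bin_edges(reference.total_length, bin_size)
    counts = [0] * len(edges)
    for s in snps:
        if s.contig_id not in reference.concat_offset:
            raise KeyError(f"SNP on unknown contig {s.contig_id!r}")
        coord = reference.concat_coord(s.contig_id, s.position - 1)
        counts[coord // bin_size] += 1
    return counts


def write_bin_table(
    bins: list[BinStats], path, reference: ReferenceGenome, bin_size: int = DEFAULT_BIN_SIZE
) -> None:
    """Emit the bin table as TSV (bin index, contig range, MCP, MRD, SNPs)."""
    # map concatenated starts back to contig-local labels
    offsets = sorted(
        ((off, cid) for cid, off in reference.concat_offset.items()), reverse=True
    )

    def label(coord: int) -> str:
        for off, cid in offsets:
            if coord >= off:
                return f"{cid}:{coord - off + 1}"
        return "?"

    with open(path, "w") as fh:
        fh.write("bin_index\trange\tmcp\tmrd\tsnp_count\n")
        for b in bins:
            fh.write(
                f"{b.bin_index}\t{label(b.start)}-{label(b.end - 1)}\t"
                f"{b.mcp:.4f}\t{b.mrd:.4f}\t{b.snp_count}\n"
            )
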