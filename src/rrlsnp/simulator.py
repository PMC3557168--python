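"""Synthetic data generator for the whole pipeline.

Emulates a reduced-representation sequencing experiment end to end: a random
reference genome, per-genotype substitution variants, an in-silico restriction
digest with fragment size selection (MseI-style TTAA motif, cut one base into
the motif, 350-425 bp window), site-level pileup observations with a
depth/error/quality model restricted to the selected fragments, and an
F6-style recombinant inbred line population with residual heterozygosity.

Reads are not modeled individually: every downstream computation consumes
pileup columns, so the simulator draws per-site depth and base calls
directly.  The digest is performed on the reference and the resulting
fragment set is shared by all genotypes, which keeps the truth bookkeeping
(which implants are recoverable) exact.

Every operation takes an explicit seed or NumPy generator; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .genome_io import ReferenceGenome, SiteObservation
from .snp_caller import homopolymer_context

_BASES = np.array(list("ACGT"))
_BASE_TO_INT = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Study-condition defaults mirror the experiment being emulated:
    MseI digest (TTAA, cut after the first T), 350-425 bp size selection,
    96 F6-derived RILs (five selfing generations after F1)."""

    genome_length: int = 1_000_000
    n_contigs: int = 4
    gc_fraction: float = 0.38
    n_genotypes: int = 2
    snp_density: float = 2e-4
    enzyme_motif: str = "TTAA"
    cut_offset: int = 1
    fragment_size_range: tuple[int, int] = (350, 425)
    mean_depth: float = 10.0
    depth_dispersion: float = 0.15  # NB overdispersion; 0 = constant depth
    base_error_rate: float = 0.0
    qual_mean: float = 35.0
    qual_sd: float = 3.0
    n_rils: int = 96
    selfing_generations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in (
            ("gc_fraction", self.gc_fraction),
            ("snp_density", self.snp_density),
            ("base_error_rate", self.base_error_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 1 or self.n_contigs < 1 or self.n_rils < 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.fragment_size_range
        if lo > hi:
            raise ValueError("fragment_size_range min > max")
        if len(self.enzyme_motif) < 2:
            raise ValueError("enzyme motif must be at least 2 bases")
        if not 0 <= self.cut_offset <= len(self.enzyme_motif):
            raise ValueError("cut_offset outside the motif")


@dataclass
class Fragment:
    contig_id: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Implanted variants and derived RIL inheritance, for truth comparisons."""

    # genotype -> {(contig, 1-based pos): (ref, alt)}
    variants: dict[str, dict[tuple[str, int], tuple[str, str]]]
    # (contig, pos) -> flags
    in_homopolymer: dict[tuple[str, int], bool] = field(default_factory=dict)
    in_selected_fragment: dict[tuple[str, int], bool] = field(default_factory=dict)
    # ril_id -> {(contig, pos): allele}; filled by simulate_ril_population
    ril_alleles: dict[str, dict[tuple[str, int], str]] = field(default_factory=dict)
    residual_het: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    def loci(self, genotype: str) -> set[tuple[str, int]]:
        return set(self.variants.get(genotype, {}))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_reference(config: SimConfig, rng=None) -> ReferenceGenome:
    """I.i.d. base model at the configured GC fraction, split into contigs of
    equal length (the last takes the remainder)."""
    rng = _rng(config.seed if rng is None else rng)
    p_gc = config.gc_fraction / 2.0
    p_at = (1.0 - config.gc_fraction) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    per = config.genome_length // config.n_contigs
    contigs = []
    for i in range(config.n_contigs):
        length = per if i < config.n_contigs - 1 else config.genome_length - per * (
            config.n_contigs - 1
        )
        seq = "".join(_BASES[rng.choice(4, size=length, p=probs)])
        contigs.append((f"ctg{i + 1}", seq))
    return ReferenceGenome(contigs)


def digest_and_select(
    sequence: str,
    motif: str = "TTAA",
    size_range: tuple[int, int] = (350, 425),
    cut_offset: int = 1,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """In-silico restriction digest of one sequence.

    Cuts at every (possibly overlapping) motif occurrence, ``cut_offset``
    bases into the motif (1 for T^TAA).  Returns ``(all_fragments,
    selected)`` as 0-based half-open intervals; fragments tile the sequence
    without overlap, and ``selected`` keeps those with length inside the
    inclusive size range.
    """
    cuts = []
    start = 0
    while True:
        i = sequence.find(motif, start)
        if i < 0:
            break
        cuts.append(i + cut_offset)
        start = i + 1  # overlapping occurrences also cut
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(sequence)]
    fragments = [
        (a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]
    lo, hi = size_range
    selected = [(a, b) for a, b in fragments if lo <= b - a <= hi]
    return fragments, selected


def digest_reference(config: SimConfig, reference: ReferenceGenome) -> list[Fragment]:
    """Digest every contig and keep size-selected fragments."""
    out = []
    for cid, seq in reference.contigs:
        _, selected = digest_and_select(
            seq, config.enzyme_motif, config.fragment_size_range, config.cut_offset
        )
        out.extend(Fragment(cid, a, b) for a, b in selected)
    return out


def implant_variants(
    reference: ReferenceGenome,
    config: SimConfig,
    rng=None,
    *,
    min_spacing: int = 0,
    avoid_homopolymer: bool = False,
    restrict_to_fragments: Sequence[Fragment] | None = None,
    genotype_ids: Sequence[str] | None = None,
) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Substitution-only variants per genotype at the configured density.

    Candidate positions are drawn per position (Bernoulli ``snp_density``)
    and then thinned by the optional constraints: minimum spacing between
    truth variants of the same genotype, exclusion of homopolymer contexts
    (run of >= 3 containing or abutting the site), and restriction to the
    selected fragments — when all three are requested, every truth variant is
    recoverable by the discovery caller by construction.

    Returns ``(genotype_sequences, truth)`` where sequences are per contig.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    if genotype_ids is None:
        genotype_ids = [f"GT{i + 1}" for i in range(config.n_genotypes)]
    allowed: dict[str, np.ndarray] | None = None
    if restrict_to_fragments is not None:
        allowed = {cid: np.zeros(reference.contig_length(cid), dtype=bool) for cid, _ in reference.contigs}
        for fr in restrict_to_fragments:
            allowed[fr.contig_id][fr.start : fr.end] = True

    sequences: dict[str, dict[str, str]] = {}
    truth = TruthSet(variants={g: {} for g in genotype_ids})
    for gt in genotype_ids:
        per_contig: dict[str, str] = {}
        for cid, refseq in reference.contigs:
            n = len(refseq)
            hits = np.flatnonzero(rng.random(n) < config.snp_density)
            chosen: list[int] = []
            last = -(10**9)
            for p in hits:
                p = int(p)
                if refseq[p] == "N":
                    continue
                if allowed is not None and not allowed[cid][p]:
                    continue
                if min_spacing and p - last < min_spacing:
                    continue
                if avoid_homopolymer and homopolymer_context(refseq, p, 3):
                    continue
                chosen.append(p)
                last = p
            seq = list(refseq)
            for p in chosen:
                ref_b = refseq[p]
                alt = _BASES[
                    rng.choice([i for i in range(4) if i != _BASE_TO_INT[ref_b]])
                ]
                seq[p] = alt
                key = (cid, p + 1)
                truth.variants[gt][key] = (ref_b, str(alt))
                truth.in_homopolymer[key] = homopolymer_context(refseq, p, 3)
                truth.in_selected_fragment[key] = (
                    bool(allowed[cid][p]) if allowed is not None else True
                )
            per_contig[cid] = "".join(seq)
        sequences[gt] = per_contig
    return sequences, truth


def _draw_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.depth_dispersion <= 0:
        return np.full(n, int(round(config.mean_depth)), dtype=np.int64)
    # gamma-Poisson mixture: mean m, variance m + disp * m^2
    shape = 1.0 / config.depth_dispersion
    lam = rng.gamma(shape, config.mean_depth / shape, size=n)
    return rng.poisson(lam)


def simulate_pileup(
    genotype_sequence: dict[str, str],
    fragments: Sequence[Fragment],
    config: SimConfig,
    genotype_id: str,
    rng=None,
    reference: ReferenceGenome | None = None,
) -> Iterator[SiteObservation]:
    """Site observations over the selected fragments for one genotype.

    Per-site depth follows the gamma-Poisson (negative-binomial-like) model;
    each call flips to a uniformly chosen different base with probability
    ``base_error_rate``; base qualities are Gaussian around ``qual_mean``
    clipped to [2, 41].  The pileup reference column comes from ``reference``
    when given (normal use), else from the genotype sequence itself.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    for fr in sorted(fragments, key=lambda f: (f.contig_id, f.start)):
        seq = genotype_sequence[fr.contig_id]
        width = fr.end - fr.start
        depths = _draw_depths(width, config, rng)
        for off in range(width):
            pos0 = fr.start + off
            depth = int(depths[off])
            if depth == 0:
                continue
            true_base = seq[pos0]
            calls = np.full(depth, _BASE_TO_INT.get(true_base, 0), dtype=np.int64)
            if config.base_error_rate > 0.0:
                err = rng.random(depth) < config.base_error_rate
                n_err = int(err.sum())
                if n_err:
                    # uniformly one of the three other bases
                    shift = rng.integers(1, 4, size=n_err)
                    calls[err] = (calls[err] + shift) % 4
            quals = np.clip(
                np.rint(rng.normal(config.qual_mean, config.qual_sd, size=depth)),
                2,
                41,
            ).astype(int)
            ref_base = (
                reference.base_at(fr.contig_id, pos0) if reference is not None else true_base
            )
            yield SiteObservation(
                genotype_id=genotype_id,
                contig_id=fr.contig_id,
                position=pos0 + 1,
                ref_base=ref_base,
                depth=depth,
                base_calls="".join(_BASES[c] for c in calls),
                base_quals=quals.tolist(),
            )


def simulate_ril_population(
    parent_loci: dict[tuple[str, int], tuple[str, str]],
    config: SimConfig,
    rng=None,
) -> tuple[dict[str, dict[tuple[str, int], str]], dict[str, set[tuple[str, int]]]]:
    """F_{2+selfing} RIL inheritance at the given biparental loci.

    Each RIL inherits one parental allele per locus (loci independent); a
    locus remains residually heterozygous with probability
    (1/2)^selfing_generations (heterozygosity halves each selfing generation
    from the fully heterozygous F1).  Returns per-RIL alleles and the
    residual-het mask; at masked loci the stored allele is the one a
    homozygous-call model would NOT recover (callers should treat them as
    missing, which tests assert via the mask).
    """
    rng = _rng(config.seed + 3 if rng is None else rng)
    loci = sorted(parent_loci)
    p_het = 0.5**config.selfing_generations
    alleles: dict[str, dict[tuple[str, int], str]] = {}
    het_mask: dict[str, set[tuple[str, int]]] = {}
    for i in range(config.n_rils):
        ril = f"RIL{i + 1:03d}"
        het_mask[ril] = set()
        mine: dict[tuple[str, int], str] = {}
        pick = rng.random(len(loci))
        hets = rng.random(len(loci)) < p_het
        for j, locus in enumerate(loci):
            ref_a, alt_a = parent_loci[locus]
            if hets[j]:
                het_mask[ril].add(locus)
            mine[locus] = alt_a if pick[j] < 0.5 else ref_a
        alleles[ril] = mine
    return alleles, het_mask


def simulate_ril_observations(
    reference: ReferenceGenome,
    parent_loci: dict[tuple[str, int], tuple[str, str]],
    ril_alleles: dict[str, dict[tuple[str, int], str]],
    het_mask: dict[str, set[tuple[str, int]]],
    config: SimConfig,
    rng=None,
) -> dict[str, dict[tuple[str, int], SiteObservation]]:
    """Pileup columns for each RIL at each locus under the depth/error model.

    Residually heterozygous loci emit a 50:50 mixture of the two observed
    parental alleles, which the homozygous caller rejects on the consensus
    ratio — exactly how such lines surface in real GBS data.
    """
    rng = _rng(config.seed + 4 if rng is None else rng)
    out: dict[str, dict[tuple[str, int], SiteObservation]] = {}
    for ril in sorted(ril_alleles):
        per_locus: dict[tuple[str, int], SiteObservation] = {}
        for locus in sorted(ril_alleles[ril]):
            contig, pos = locus
            depth = int(_draw_depths(1, config, rng)[0])
            if depth == 0:
                continue
            allele = ril_alleles[ril][locus]
            ref_base = reference.base_at(contig, pos - 1)
            calls_int = np.full(depth, _BASE_TO_INT[allele], dtype=np.int64)
            if locus in het_mask[ril]:
                p_ref, p_alt = parent_loci[locus]
                other = p_alt if allele == p_ref else p_ref
                half = rng.random(depth) < 0.5
                calls_int[half] = _BASE_TO_INT[other]
            if config.base_error_rate > 0.0:
                err = rng.random(depth) < config.base_error_rate
                n_err = int(err.sum())
                if n_err:
                    calls_int[err] = (calls_int[err] + rng.integers(1, 4, size=n_err)) % 4
            quals = np.clip(
                np.rint(rng.normal(config.qual_mean, config.qual_sd, size=depth)),
                2,
                41,
            ).astype(int)
            per_locus[locus] = SiteObservation(
                genotype_id=ril,
                contig_id=contig,
                position=pos,
                ref_base=ref_base,
                depth=depth,
                base_calls="".join(_BASES[c] for c in calls_int),
                base_quals=quals.tolist(),
            )
        out[ril] = per_locus
    return out


@dataclass
class SimulatedExperiment:
    config: SimConfig
    reference: ReferenceGenome
    fragments: list[Fragment]
    genotype_sequences: dict[str, dict[str, str]]
    truth: TruthSet

    def pileup(self, genotype_id: str, seed_offset: int = 0) -> Iterator[SiteObservation]:
        idx = sorted(self.genotype_sequences).index(genotype_id)
        rng = np.random.default_rng(self.config.seed * 1000 + 17 * idx + seed_offset)
        return simulate_pileup(
            self.genotype_sequences[genotype_id],
            self.fragments,
            self.config,
            genotype_id,
            rng,
            reference=self.reference,
        )


def simulate_experiment(
    config: SimConfig,
    *,
    recoverable: bool = True,
) -> SimulatedExperiment:
    """Reference + digest + implanted genotypes in one call.

    With ``recoverable=True`` the implants are constrained to selected
    fragments, non-homopolymer contexts and >= 3 bp spacing, so an error-free
    run of the discovery caller recovers the truth set exactly.
    """
    master = np.random.SeedSequence(config.seed)
    s_ref, s_var = master.spawn(2)
    reference = simulate_reference(config, np.random.default_rng(s_ref))
    fragments = digest_reference(config, reference)
    kwargs = (
        dict(min_spacing=3, avoid_homopolymer=True, restrict_to_fragments=fragments)
        if recoverable
        else {}
    )
    sequences, truth = implant_variants(
        reference, config, np.random.default_rng(s_var), **kwargs
    )
    return SimulatedExperiment(config, reference, fragments, sequences, truth)


def write_truth_table(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tcontig\tposition\tref\talt\tin_homopolymer\tin_selected_fragment\n")
        for gt in sorted(truth.variants):
            for (contig, pos), (ref, alt) in sorted(truth.variants[gt].items()):
                fh.write(
                    f"{gt}\t{contig}\t{pos}\t{ref}\t{alt}\t"
                    f"{int(truth.in_homopolymer.get((contig, pos), False))}\t"
                    f"{int(truth.in_selected_fragment.get((contig, pos), True))}\n"
                )
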