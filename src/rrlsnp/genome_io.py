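"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions: external text formats keep their native conventions
(FASTA/pileup/GFF3/VCF are 1-based, BED-like tables 0-based half-open); the
internal representation is uniformly 0-based half-open and conversion happens
only here, at the I/O boundary.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .records import SNPRecord

VALID_BASES = frozenset("ACGTN")
_PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """Ordered contigs plus the concatenated coordinate system used for bins.

    The concatenation order is the file order; ``concat_offset[cid]`` is the
    0-based offset of the contig start in the genome-wide coordinate system.
    """

    contigs: list[tuple[str, str]]
    concat_offset: dict[str, int] = field(init=False)
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        self.concat_offset = {}
        offset = 0
        for cid, seq in self.contigs:
            if cid in seen:
                raise FormatError(f"duplicate contig id {cid!r}")
            seen.add(cid)
            self.concat_offset[cid] = offset
            offset += len(seq)
        self.total_length = offset
        self._seq = {cid: seq for cid, seq in self.contigs}

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    def sequence(self, contig_id: str) -> str:
        return self._seq[contig_id]

    def contig_length(self, contig_id: str) -> int:
        return len(self._seq[contig_id])

    def base_at(self, contig_id: str, pos0: int) -> str:
        seq = self._seq[contig_id]
        if not 0 <= pos0 < len(seq):
            raise IndexError(
                f"position {pos0} outside contig {contig_id} (length {len(seq)})"
            )
        return seq[pos0]

    def concat_coord(self, contig_id: str, pos0: int) -> int:
        """Genome-wide 0-based coordinate of a contig-local 0-based position."""
        if contig_id not in self.concat_offset:
            raise KeyError(f"unknown contig {contig_id!r}")
        return self.concat_offset[contig_id] + pos0


def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a (possibly gzipped) FASTA into a :class:`ReferenceGenome`.

    Lowercase is folded to uppercase; any character outside {A,C,G,T,N} is
    rejected with the contig and offset named in the error.
    """
    contigs: list[tuple[str, str]] = []
    with _maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"contig {rec.id!r} has an empty sequence")
            bad = next((i for i, b in enumerate(seq) if b not in VALID_BASES), None)
            if bad is not None:
                raise FormatError(
                    f"illegal character {seq[bad]!r} in contig {rec.id!r} at offset {bad}"
                )
            contigs.append((rec.id, seq))
    if not contigs:
        raise FormatError(f"no sequences found in {path}")
    return ReferenceGenome(contigs)


def write_reference(reference: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in reference.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _maybe_gzip(path: str | os.PathLike) -> IO[str]:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


@dataclass
class SiteObservation:
    """One pileup column for one genotype.

    ``depth`` is the mapped-read depth at the site, including deletion
    placeholders ('*'), which count toward coverage but contribute no base
    call; hence ``depth >= len(base_calls)``.  ``base_calls`` are strand-folded
    to uppercase with reference-match symbols resolved to ``ref_base``, and
    ``base_quals`` is aligned with ``base_calls``.
    """

    genotype_id: str
    contig_id: str
    position: int  # 1-based
    ref_base: str
    depth: int
    base_calls: str
    base_quals: list[int]
    map_quals: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.base_calls) != len(self.base_quals):
            raise ValueError("base_calls and base_quals length mismatch")
        if self.depth < len(self.base_calls):
            raise ValueError("depth smaller than number of base calls")

    @property
    def pos0(self) -> int:
        return self.position - 1


def parse_pileup_bases(bases: str, quals: str, ref_base: str, map_quals: str | None = None):
    """Decode one pileup read-base string against its quality string.

    Returns ``(calls, call_quals, n_deleted, call_mapquals)`` where ``calls``
    excludes deletion placeholders and indel runs.  Raises :class:`ValueError`
    when the number of quality-consuming symbols disagrees with the quality
    string length.
    """
    calls: list[str] = []
    call_quals: list[int] = []
    call_mapquals: list[int] = []
    n_deleted = 0
    qi = 0  # index into quality string(s)
    i = 0
    n = len(bases)
    ref_up = ref_base.upper()
    while i < n:
        c = bases[i]
        if c == "^":  # read start; next char is the mapping quality
            i += 2
            continue
        if c == "$":  # read end marker
            i += 1
            continue
        if c in "+-":  # indel run: +<n><seq> / -<n><seq>; no quality attached
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"malformed indel run at offset {i}")
            run = int(bases[i + 1 : j])
            i = j + run
            continue
        # everything from here consumes one quality character
        if qi >= len(quals):
            raise ValueError("more base symbols than quality characters")
        q = ord(quals[qi]) - _PHRED_OFFSET
        mq = ord(map_quals[qi]) - _PHRED_OFFSET if map_quals is not None else None
        qi += 1
        i += 1
        if c in ".,":
            calls.append(ref_up)
        elif c.upper() in "ACGTN":
            calls.append(c.upper())
        elif c in "*<>":
            n_deleted += 1
            continue
        else:
            raise ValueError(f"unexpected pileup symbol {c!r}")
        call_quals.append(q)
        if mq is not None:
            call_mapquals.append(mq)
    if qi != len(quals):
        raise ValueError(
            f"quality string length {len(quals)} does not match {qi} parsed symbols"
        )
    return "".join(calls), call_quals, n_deleted, (call_mapquals if map_quals else None)


def read_pileup(
    stream: IO[str] | str | os.PathLike, genotype_id: str
) -> Iterator[SiteObservation]:
    """Stream :class:`SiteObservation` from a samtools text pileup.

    Accepts the 6-column layout (chrom, pos, ref, depth, bases, base quals)
    and the 7-column one with per-read mapping qualities appended.  Single
    pass; memory does not grow with file length.
    """
    own = False
    if isinstance(stream, (str, os.PathLike)):
        stream = _maybe_gzip(stream)
        own = True
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) == 1:  # tolerate space-separated toy inputs
                cols = line.split()
            if len(cols) not in (6, 7):
                raise FormatError(
                    f"line {lineno}: expected 6 or 7 columns, found {len(cols)}"
                )
            chrom, pos_s, ref, depth_s, bases, quals = cols[:6]
            mapq = cols[6] if len(cols) == 7 else None
            try:
                pos = int(pos_s)
                declared_depth = int(depth_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer field ({exc})") from None
            if declared_depth == 0:
                yield SiteObservation(genotype_id, chrom, pos, ref.upper(), 0, "", [])
                continue
            try:
                calls, call_quals, n_del, call_mq = parse_pileup_bases(
                    bases, quals, ref, mapq
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            # reconcile the declared depth with what was actually parsed
            depth = len(calls) + n_del
            yield SiteObservation(
                genotype_id,
                chrom,
                pos,
                ref.upper(),
                depth,
                calls,
                call_quals,
                call_mq,
            )
    finally:
        if own:
            stream.close()


def write_pileup(observations: Iterable[SiteObservation], path: str | os.PathLike) -> None:
    """Emit observations as 6/7-column samtools text pileup."""
    with open(path, "w") as fh:
        for obs in observations:
            quals = "".join(chr(q + _PHRED_OFFSET) for q in obs.base_quals)
            fields = [
                obs.contig_id,
                str(obs.position),
                obs.ref_base,
                str(obs.depth),
                obs.base_calls if obs.depth else "*",
                quals if obs.depth else "*",
            ]
            if obs.map_quals is not None:
                fields.append("".join(chr(q + _PHRED_OFFSET) for q in obs.map_quals))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Allele-count table dialect
# ---------------------------------------------------------------------------

_COUNT_COLS = ("contig", "pos", "ref", "nA", "nC", "nG", "nT", "meanQ")


def read_allele_counts(path: str | os.PathLike, genotype_id: str) -> Iterator[SiteObservation]:
    """Alternative input dialect: a TSV of per-site allele counts.

    Columns: contig, pos (1-based), ref, nA, nC, nG, nT, meanQ.  The counts are
    expanded into synthetic base calls all carrying the site's mean quality,
    which is sufficient for every downstream filter (none looks at per-read
    quality variance).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COUNT_COLS:
            raise FormatError(
                f"allele-count header must be {'	'.join(_COUNT_COLS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 8:
                raise FormatError(f"line {lineno}: expected 8 columns")
            contig, pos_s, ref = cols[0], cols[1], cols[2].upper()
            counts = dict(zip("ACGT", (int(c) for c in cols[3:7])))
            mean_q = int(round(float(cols[7])))
            calls = "".join(b * counts[b] for b in "ACGT")
            yield SiteObservation(
                genotype_id,
                contig,
                int(pos_s),
                ref,
                len(calls),
                calls,
                [mean_q] * len(calls),
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    start: int  # 0-based half-open
    end: int
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: end <= start")
        for s, e in self.cds:
            if e <= s:
                raise FormatError(f"gene {self.gene_id}: CDS end <= start")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )


class GeneModelSet:
    """Gene and CDS intervals with point-containment queries.

    All intervals are stored 0-based half-open.  Lookup uses sorted interval
    lists with bisection per contig; gene sets of realistic size need nothing
    fancier.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self.genes: list[GeneModel] = list(genes)
        self._gene_idx: dict[str, list[tuple[int, int]]] = {}
        self._cds_idx: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            self._gene_idx.setdefault(g.contig_id, []).append((g.start, g.end))
            for iv in g.cds:
                self._cds_idx.setdefault(g.contig_id, []).append(iv)
        for idx in (self._gene_idx, self._cds_idx):
            for cid in idx:
                idx[cid] = _merge_intervals(idx[cid])

    def __len__(self) -> int:
        return len(self.genes)

    def is_genic(self, contig_id: str, pos0: int) -> bool:
        return _point_in(self._gene_idx.get(contig_id, []), pos0)

    def is_cds(self, contig_id: str, pos0: int) -> bool:
        return _point_in(self._cds_idx.get(contig_id, []), pos0)

    def genic_length(self) -> int:
        """Total bases covered by the union of gene intervals."""
        return sum(e - s for ivs in self._gene_idx.values() for s, e in ivs)

    def cds_length(self) -> int:
        return sum(e - s for ivs in self._cds_idx.values() for s, e in ivs)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _point_in(ivs: list[tuple[int, int]], pos: int) -> bool:
    import bisect

    i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | os.PathLike, format: str = "gff3") -> GeneModelSet:
    """Load gene/CDS intervals from GFF3 or a 4+-column BED-like table.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open;
    CDS features are attached to their parent gene directly via ``Parent`` or
    through an intermediate mRNA.  The BED-like dialect has columns
    (contig, start, end, type, gene_id) already 0-based half-open.
    """
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bedlike(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gff3(path: str | os.PathLike) -> GeneModelSet:
    genes: dict[str, GeneModel] = {}
    feature_parent: dict[str, str] = {}  # mRNA/transcript id -> gene id
    pending_cds: list[tuple[str, str, int, int]] = []
    with _maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"line {lineno}: GFF3 needs 9 columns")
            contig, _, ftype, start_s, end_s, *_rest = cols[:6]
            attrs = _parse_gff_attributes(cols[8])
            start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            if end <= start:
                raise FormatError(f"line {lineno}: end <= start")
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_{lineno}")
                genes[gid] = GeneModel(gid, contig, start, end)
            elif ftype in ("mRNA", "transcript"):
                if "ID" in attrs and "Parent" in attrs:
                    feature_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"line {lineno}: CDS without Parent")
                pending_cds.append((parent, contig, start, end))
    for parent, contig, start, end in pending_cds:
        gid = feature_parent.get(parent, parent)
        gid = feature_parent.get(gid, gid)  # tolerate one more indirection
        if gid not in genes:
            raise FormatError(f"CDS parent {parent!r} resolves to no gene")
        genes[gid].cds.append((start, end))
    out = []
    for g in genes.values():
        g.cds = _merge_intervals(g.cds)
        out.append(GeneModel(g.gene_id, g.contig_id, g.start, g.end, g.cds))
    return GeneModelSet(out)


def _read_bedlike(path: str | os.PathLike) -> GeneModelSet:
    genes: dict[str, GeneModel] = {}
    pending: list[tuple[str, str, int, int]] = []
    with _maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(
                    f"line {lineno}: BED-like table needs contig,start,end,type,gene_id"
                )
            contig, start_s, end_s, ftype, gid = cols[:5]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise FormatError(f"line {lineno}: end <= start")
            if ftype == "gene":
                genes[gid] = GeneModel(gid, contig, start, end)
            elif ftype == "CDS":
                pending.append((gid, contig, start, end))
    for gid, contig, start, end in pending:
        if gid not in genes:
            raise FormatError(f"CDS references unknown gene {gid!r}")
        genes[gid].cds.append((start, end))
    return GeneModelSet(
        GeneModel(g.gene_id, g.contig_id, g.start, g.end, _merge_intervals(g.cds))
        for g in genes.values()
    )


# ---------------------------------------------------------------------------
# SNP tables (TSV and VCF 4.2)
# ---------------------------------------------------------------------------

_TSV_HEADER = [
    "contig",
    "position",
    "ref",
    "alt",
    "genotypes",
    "depth",
    "consensus_ratio",
    "quality",
    "region_class",
    "cds_flag",
    "substitution_class",
]


def write_snp_table(
    snps: Iterable[SNPRecord],
    path: str | os.PathLike,
    format: str = "tsv",
    reference: ReferenceGenome | None = None,
) -> None:
    """Write SNP records as TSV or VCF 4.2 (contig-local 1-based coordinates).

    The TSV keeps per-genotype alt/depth/ratio/quality as comma-joined lists
    aligned with the genotype column, so the table round-trips exactly.  VCF
    output needs ``reference`` for contig header lines when available.
    """
    snps = sorted(snps, key=SNPRecord.sort_key)
    if format == "tsv":
        _write_tsv(snps, path)
    elif format == "vcf":
        _write_vcf(snps, path, reference)
    else:
        raise ValueError(f"unknown SNP table format {format!r}")


def _fmt_float(x: float) -> str:
    return format(x, ".6g")


def _write_tsv(snps: list[SNPRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for s in snps:
            gts = sorted(s.alt_alleles)
            fh.write(
                "\t".join(
                    [
                        s.contig_id,
                        str(s.position),
                        s.ref_allele,
                        ",".join(s.alt_alleles[g] for g in gts),
                        ",".join(gts),
                        ",".join(str(s.depth.get(g, 0)) for g in gts),
                        ",".join(_fmt_float(s.consensus_ratio.get(g, 0.0)) for g in gts),
                        ",".join(_fmt_float(s.quality.get(g, 0.0)) for g in gts),
                        s.region_class or ".",
                        {True: "1", False: "0", None: "."}[s.cds_flag],
                        s.substitution_class or ".",
                    ]
                )
                + "\n"
            )


def read_snp_table(path: str | os.PathLike, format: str = "tsv") -> list[SNPRecord]:
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown SNP table format {format!r}")


def _read_tsv(path: str | os.PathLike) -> list[SNPRecord]:
    out: list[SNPRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise FormatError(f"unexpected SNP table header in {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(_TSV_HEADER):
                raise FormatError(f"line {lineno}: column count mismatch")
            gts = cols[4].split(",") if cols[4] else []
            alts = cols[3].split(",") if cols[3] else []
            depths = [int(x) for x in cols[5].split(",")] if cols[5] else []
            ratios = [float(x) for x in cols[6].split(",")] if cols[6] else []
            quals = [float(x) for x in cols[7].split(",")] if cols[7] else []
            out.append(
                SNPRecord(
                    contig_id=cols[0],
                    position=int(cols[1]),
                    ref_allele=cols[2],
                    alt_alleles=dict(zip(gts, alts)),
                    depth=dict(zip(gts, depths)),
                    consensus_ratio=dict(zip(gts, ratios)),
                    quality=dict(zip(gts, quals)),
                    region_class=None if cols[8] == "." else cols[8],
                    cds_flag={"1": True, "0": False, ".": None}[cols[9]],
                    substitution_class=None if cols[10] == "." else cols[10],
                )
            )
    return out


def _write_vcf(
    snps: list[SNPRecord], path: str | os.PathLike, reference: ReferenceGenome | None
) -> None:
    samples = sorted({g for s in snps for g in s.alt_alleles})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rrlsnp\n")
        if reference is not None:
            for cid, seq in reference.contigs:
                fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##INFO=<ID=RC,Number=1,Type=String,Description="Region class">\n')
        fh.write('##INFO=<ID=CDS,Number=0,Type=Flag,Description="Within a coding region">\n')
        fh.write('##INFO=<ID=SC,Number=1,Type=String,Description="Substitution class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=CR,Number=1,Type=Float,Description="Consensus base ratio">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Call quality">\n')
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            cols += "\tFORMAT\t" + "\t".join(samples)
        fh.write(cols + "\n")
        for s in snps:
            alts = sorted(set(s.alt_alleles.values()))
            alt_index = {a: i + 1 for i, a in enumerate(alts)}
            info_parts = []
            if s.region_class:
                info_parts.append(f"RC={s.region_class}")
            if s.cds_flag:
                info_parts.append("CDS")
            if s.substitution_class:
                info_parts.append(f"SC={s.substitution_class}")
            info = ";".join(info_parts) or "."
            sample_fields = []
            for g in samples:
                if g in s.alt_alleles:
                    idx = alt_index[s.alt_alleles[g]]
                    sample_fields.append(
                        f"{idx}/{idx}:{s.depth.get(g, 0)}:"
                        f"{_fmt_float(s.consensus_ratio.get(g, 0.0))}:"
                        f"{_fmt_float(s.quality.get(g, 0.0))}"
                    )
                else:
                    sample_fields.append("./.:.:.:.")
            fh.write(
                "\t".join(
                    [
                        s.contig_id,
                        str(s.position),
                        ".",
                        s.ref_allele,
                        ",".join(alts),
                        ".",
                        "PASS",
                        info,
                        "GT:DP:CR:GQ",
                    ]
                    + sample_fields
                )
                + "\n"
            )


def _read_vcf(path: str | os.PathLike) -> list[SNPRecord]:
    import pysam

    out: list[SNPRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            region = rec.info.get("RC")
            snp = SNPRecord(
                contig_id=rec.chrom,
                position=rec.pos,
                ref_allele=rec.ref,
                region_class=region,
                cds_flag=("CDS" in rec.info) if region is not None else None,
                substitution_class=rec.info.get("SC"),
            )
            alleles = [rec.ref] + list(rec.alts or ())
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None or gt[0] is None:
                    continue
                snp.alt_alleles[sample_name] = alleles[gt[0]]
                if sample.get("DP") is not None:
                    snp.depth[sample_name] = int(sample["DP"])
                if sample.get("CR") is not None:
                    # FORMAT floats go through float32; 4 d.p. survives that
                    snp.consensus_ratio[sample_name] = round(float(sample["CR"]), 4)
                if sample.get("GQ") is not None:
                    snp.quality[sample_name] = round(float(sample["GQ"]), 4)
            out.append(snp)
    return out
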