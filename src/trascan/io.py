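"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are normalised to a single internal convention —
0-based half-open — at parse time.  VCF positions (1-based) and GFF3/GTF
coordinates (1-based inclusive) are converted once, here, and converted
back only when serialising.  Chromosome names are matched by exact
string comparison; an explicit ``chrom_map`` may be supplied to rename
on ingest (e.g. ``{"1": "chr1"}``), but no renaming happens by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from pyfaidx import Fasta

from trascan.errors import FormatError, RecordError

logger = logging.getLogger(__name__)

_VALID_ALLELE = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open: ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TFBSCluster:
    """One ENCODE-style TFBS cluster row: an interval bound by one regulator."""

    interval: GenomicInterval
    regulator: str
    score: int | None = None

    def __post_init__(self) -> None:
        if not self.regulator:
            raise ValueError("regulator must be non-empty")
        if self.score is not None and not (0 <= self.score <= 1000):
            raise ValueError(f"score must lie in [0, 1000], got {self.score}")


@dataclass(frozen=True)
class GeneModel:
    """One representative protein-coding transcript per gene.

    ``cds_segments`` are stored in genomic order regardless of strand;
    translation order is derived from ``strand`` where needed.  A model
    whose total CDS length is not divisible by 3 is kept but flagged
    ``codable=False`` and excluded from consequence annotation.
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    span: GenomicInterval
    strand: str
    cds_segments: tuple[GenomicInterval, ...]
    codable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for seg in self.cds_segments:
            if seg.chrom != self.span.chrom:
                raise ValueError("CDS segment on a different chromosome than span")
            if seg.start < self.span.start or seg.end > self.span.end:
                raise ValueError("CDS segment outside gene span")
            if seg.start < prev_end:
                raise ValueError("CDS segments overlap or are unsorted")
            prev_end = seg.end

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)


@dataclass(frozen=True)
class VariantCall:
    """A single-sample variant call with AD-style read support.

    ``pos`` is kept 1-based as printed in VCF; the equivalent internal
    interval is exposed via :meth:`interval` (an SNV at pos *p* occupies
    ``[p-1, p)``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    sample: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_ALLELE:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} not in {{A,C,G,T}}+"
                )
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for germline subtraction and timepoint matching."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        """alt_reads / (ref_reads + alt_reads); 0.0 at zero depth."""
        depth = self.ref_reads + self.alt_reads
        return self.alt_reads / depth if depth else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def anchor(self) -> int:
        """Leftmost reference base, 0-based (the indel anchor rule)."""
        return self.pos - 1

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))


# ---------------------------------------------------------------------------
# TFBS cluster BED
# ---------------------------------------------------------------------------

def _map_chrom(chrom: str, chrom_map: Mapping[str, str] | None) -> str:
    if chrom_map is not None:
        return chrom_map.get(chrom, chrom)
    return chrom


def read_tfbs_clusters(
    path: str | Path,
    min_score: int | None = None,
    chrom_map: Mapping[str, str] | None = None,
) -> list[TFBSCluster]:
    """Read an ENCODE-dialect TFBS cluster BED file.

    Only the first five columns (chrom, start, end, name, score) are
    interpreted; further columns (expCount, expNums, expScores in the
    wgEncodeRegTfbsClusteredV3 track) are tolerated and ignored.  Rows
    scoring below ``min_score`` are dropped when the threshold is given.
    Duplicate rows are retained verbatim — de-duplication is a
    downstream concern.
    """
    clusters: list[TFBSCluster] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated columns "
                    f"(chrom, start, end, name), got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise RecordError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end or start < 0:
                raise RecordError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            score: int | None = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = int(fields[4])
                except ValueError as exc:
                    raise RecordError(
                        f"{path}: line {lineno}: non-integer score {fields[4]!r}"
                    ) from exc
            if min_score is not None and (score is None or score < min_score):
                continue
            clusters.append(
                TFBSCluster(
                    GenomicInterval(_map_chrom(chrom, chrom_map), start, end),
                    name,
                    score,
                )
            )
    return clusters


def write_tfbs_clusters(clusters: Iterable[TFBSCluster], path: str | Path) -> None:
    """Write clusters back out in the same 4/5-column BED dialect."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for c in clusters:
            row = [c.interval.chrom, str(c.interval.start), str(c.interval.end),
                   c.regulator]
            if c.score is not None:
                row.append(str(c.score))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Variant tables (VCF or 6-column TSV)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "ref_reads", "alt_reads")


def _looks_like_vcf(path: str | Path) -> bool:
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return True
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def read_variants(
    path: str | Path,
    sample: str,
    chrom_map: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Read variant calls from a VCF (AD-style depths) or a 6-column TSV.

    Multi-allelic VCF records are split into one :class:`VariantCall`
    per alternate allele, pairing each alt with its own AD entry.
    Positions stay 1-based on the record; conversion to the internal
    0-based convention happens at the interval boundary.
    """
    if _looks_like_vcf(path):
        return _read_vcf(path, sample, chrom_map)
    return _read_variant_tsv(path, sample, chrom_map)


def _read_vcf(
    path: str | Path, sample: str, chrom_map: Mapping[str, str] | None
) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            locus = f"{rec.chrom}:{rec.pos}"
            if not rec.alts:
                continue
            ad = _allele_depths(rec, locus)
            for i, alt in enumerate(rec.alts):
                if alt is None or alt in (".", "*", "<NON_REF>"):
                    continue
                calls.append(
                    VariantCall(
                        chrom=_map_chrom(rec.chrom, chrom_map),
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        ref_reads=int(ad[0]),
                        alt_reads=int(ad[i + 1]),
                        sample=sample,
                    )
                )
    return calls


def _allele_depths(rec, locus: str) -> Sequence[int]:
    if rec.samples:
        sample0 = rec.samples[0]
        ad = sample0.get("AD")
        if ad is not None and ad[0] is not None:
            return ad
    ad = rec.info.get("AD")
    if ad is not None:
        return ad
    raise FormatError(f"no AD allele-depth field at {locus}")


def _read_variant_tsv(
    path: str | Path, sample: str, chrom_map: Mapping[str, str] | None
) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header[:6]) != _TSV_COLUMNS:
            raise FormatError(
                f"{path}: expected header columns {_TSV_COLUMNS}, got {header[:6]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise RecordError(f"{path}: line {lineno}: expected 6 columns")
            chrom, pos_s, ref, alt, rr_s, ar_s = fields[:6]
            try:
                pos, rr, ar = int(pos_s), int(rr_s), int(ar_s)
            except ValueError as exc:
                raise RecordError(
                    f"{path}: line {lineno}: non-integer field"
                ) from exc
            try:
                calls.append(
                    VariantCall(
                        chrom=_map_chrom(chrom, chrom_map),
                        pos=pos, ref=ref, alt=alt,
                        ref_reads=rr, alt_reads=ar, sample=sample,
                    )
                )
            except ValueError as exc:
                raise RecordError(f"{path}: line {lineno}: {exc}") from exc
    return calls


def write_variants_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for v in calls:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.ref_reads}\t{v.alt_reads}\n"
            )


def write_variants_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    sample_name: str = "SAMPLE",
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls as a minimal VCF v4.2 with per-sample AD depths.

    Calls sharing (chrom, pos, ref) are emitted as one multi-allelic
    record so a write/read cycle exercises the allele-splitting path.
    """
    grouped: dict[tuple[str, int, str], list[VariantCall]] = {}
    order: list[tuple[str, int, str]] = []
    for v in calls:
        k = (v.chrom, v.pos, v.ref)
        if k not in grouped:
            grouped[k] = []
            order.append(k)
        grouped[k].append(v)

    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            seen: list[str] = []
            for k in order:
                if k[0] not in seen:
                    seen.append(k[0])
            for name in seen:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for k in order:
            group = grouped[k]
            chrom, pos, ref = k
            alts = ",".join(v.alt for v in group)
            ad = ",".join(
                [str(group[0].ref_reads)] + [str(v.alt_reads) for v in group]
            )
            gt = "0/1" if len(group) == 1 else "1/2"
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT:AD\t{gt}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3/GTF subset) and genome FASTA
# ---------------------------------------------------------------------------

class GenomeAccessor:
    """Uppercase random access into a FASTA genome (0-based half-open)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise RecordError(f"chromosome {chrom!r} absent from genome")
        return str(self._fasta[chrom][start:end])

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def chrom_names(self) -> list[str]:
        return list(self._fasta.keys())

    def close(self) -> None:
        self._fasta.close()


def read_genome(path: str | Path) -> GenomeAccessor:
    return GenomeAccessor(path)


def read_gene_models(
    path: str | Path,
    genome: GenomeAccessor | None = None,
    chrom_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Parse a GFF3/GTF subset into one GeneModel per gene.

    Per gene, the transcript with the longest total CDS is selected;
    ties break lexicographically by transcript id.  GFF3 1-based
    inclusive coordinates are converted to 0-based half-open here.
    Models whose CDS length is not divisible by 3 are flagged
    non-codable with a warning rather than dropped, so they still
    participate in proximity searches.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type(("gene",)):
        gene_id = gene.id
        gene_name = _first_attr(gene, ("Name", "gene_name", "gene_id"), gene_id)
        best: tuple[int, str, list, object] | None = None
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            cds = sorted(
                db.children(tx, featuretype="CDS", level=1), key=lambda f: f.start
            )
            if not cds:
                continue
            total = sum(f.end - f.start + 1 for f in cds)
            cand = (total, tx.id, cds, tx)
            if best is None or (cand[0], _neg_lex(cand[1])) > (
                best[0], _neg_lex(best[1])
            ):
                best = cand
        if best is None:
            continue
        _, tx_id, cds_feats, tx = best
        chrom = _map_chrom(gene.seqid, chrom_map)
        segments = tuple(
            GenomicInterval(chrom, f.start - 1, f.end) for f in cds_feats
        )
        if genome is not None:
            chrom_len = genome.chrom_length(chrom)
            for seg in segments:
                if seg.end > chrom_len:
                    raise FormatError(
                        f"CDS {seg.chrom}:{seg.start}-{seg.end} exceeds "
                        f"chromosome length {chrom_len}"
                    )
        total_len = sum(len(s) for s in segments)
        codable = total_len % 3 == 0
        if not codable:
            logger.warning(
                "gene %s transcript %s: CDS length %d not divisible by 3; "
                "flagged non-codable and excluded from consequence calls",
                gene_id, tx_id, total_len,
            )
        span = GenomicInterval(
            chrom,
            min(gene.start - 1, segments[0].start),
            max(gene.end, segments[-1].end),
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_name,
                transcript_id=tx_id,
                span=span,
                strand=gene.strand if gene.strand in "+-" else tx.strand,
                cds_segments=segments,
                codable=codable,
            )
        )
    models.sort(key=lambda m: (m.span.chrom, m.span.start, m.gene_id))
    return models


def _first_attr(feature, names: Sequence[str], default: str) -> str:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return default


class _neg_lex(str):
    """Sort helper: smaller string wins when totals tie (ties break
    lexicographically ascending while the total sorts descending)."""

    def __lt__(self, other):  # pragma: no cover - trivial inversion
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
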