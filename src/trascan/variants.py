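"""Somatic variant filtering, germline subtraction, timepoint
classification, and coding-consequence annotation.

The identification rule for a genuine alteration is a variant allele
frequency strictly above 20% supported by at least five reads.  "Five
reads" is read as five alt-supporting reads by default; the alternative
reading (total depth >= 5) is one configuration flag away
(``depth_rule="total"``).

Variant identity throughout is the tuple (chrom, pos, ref, alt) with no
implicit indel normalisation; an optional explicit left-alignment pass
against the genome is provided but off by default, because silently
re-normalising records can merge calls the caller meant to keep
distinct.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio.Seq import Seq

from trascan.errors import ReferenceMismatchError
from trascan.io import GeneModel, GenomeAccessor, VariantCall

logger = logging.getLogger(__name__)

Consequence = Literal[
    "synonymous", "missense", "nonsense", "stop_lost", "start_lost",
    "frameshift", "inframe_indel", "non_CDS",
]

#: coding consequences that change the protein
NON_SYNONYMOUS: frozenset[str] = frozenset(
    {"missense", "nonsense", "stop_lost", "start_lost",
     "frameshift", "inframe_indel"}
)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Variant identification conditions.

    min_vaf
        variant allele frequency bound, strict: kept iff VAF > min_vaf.
    min_alt_reads
        read-support bound, inclusive: kept iff the supporting read
        count >= min_alt_reads.
    depth_rule
        which count must clear ``min_alt_reads``: ``"alt"`` (default)
        counts alt-supporting reads, ``"total"`` counts ref+alt depth.
    """

    min_vaf: float = 0.20
    min_alt_reads: int = 5
    depth_rule: Literal["alt", "total"] = "alt"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_vaf < 1.0):
            raise ValueError("min_vaf must lie in [0, 1)")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")
        if self.depth_rule not in ("alt", "total"):
            raise ValueError("depth_rule must be 'alt' or 'total'")


@dataclass
class FilterLog:
    """Tally of rejected calls by reason."""

    n_input: int = 0
    n_kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def filter_calls(
    calls: Iterable[VariantCall],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantCall], FilterLog]:
    """Apply the identification conditions; preserves relative order.

    Zero-depth calls are rejected with reason ``zero depth`` rather
    than tripping a division error.
    """
    kept: list[VariantCall] = []
    log = FilterLog()
    for v in calls:
        log.n_input += 1
        depth = v.ref_reads + v.alt_reads
        if depth == 0:
            log.reject("zero depth")
            continue
        support = v.alt_reads if thresholds.depth_rule == "alt" else depth
        if support < thresholds.min_alt_reads:
            log.reject("low support")
            continue
        if not (v.vaf > thresholds.min_vaf):
            log.reject("low VAF")
            continue
        kept.append(v)
    log.n_kept = len(kept)
    return kept, log


def subtract_germline(
    tumor: Iterable[VariantCall], germline: Iterable[VariantCall]
) -> list[VariantCall]:
    """Drop tumor calls whose (chrom, pos, ref, alt) key appears in the
    matched normal; germline read counts play no role in matching."""
    germline_keys = {g.key for g in germline}
    return [v for v in tumor if v.key not in germline_keys]


def left_align(v: VariantCall, genome: GenomeAccessor) -> VariantCall:
    """Left-normalise an indel against the genome (explicit opt-in pass).

    Trims shared suffix bases, prepending the preceding reference base,
    until the alleles can shift no further; SNVs pass through unchanged.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if len(ref) == len(alt) == 1:
        return v
    changed = True
    while changed:
        changed = False
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if ref[-1] == alt[-1] and pos > 1:
            prev = genome.fetch(v.chrom, pos - 2, pos - 1)
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    from dataclasses import replace
    return replace(v, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Timepoint classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimepointPartition:
    """Diagnosis/relapse comparison: the three sets partition the
    key-union of the two filtered call sets."""

    common: tuple[VariantCall, ...]
    additional: tuple[VariantCall, ...]
    lost: tuple[VariantCall, ...]


def _dedup(calls: Iterable[VariantCall], label: str) -> dict[tuple, VariantCall]:
    out: dict[tuple, VariantCall] = {}
    dupes = 0
    for v in calls:
        prev = out.get(v.key)
        if prev is None:
            out[v.key] = v
        else:
            dupes += 1
            if v.alt_reads > prev.alt_reads:
                out[v.key] = v
    if dupes:
        logger.warning(
            "%s: %d duplicate variant key(s) collapsed (kept max alt_reads)",
            label, dupes,
        )
    return out


def classify_timepoints(
    diagnosis: Iterable[VariantCall], relapse: Iterable[VariantCall]
) -> TimepointPartition:
    """Partition variants into common (both samples), additional
    (relapse only) and lost (diagnosis only).

    Inputs are expected to be germline-subtracted and filtered already.
    For common variants the relapse-sample call is retained as the
    representative record.  Duplicate keys within one sample collapse
    to the call with the larger alt read count, with a warning.
    """
    dx = _dedup(diagnosis, "diagnosis")
    rl = _dedup(relapse, "relapse")
    common = tuple(rl[k] for k in rl if k in dx)
    additional = tuple(rl[k] for k in rl if k not in dx)
    lost = tuple(dx[k] for k in dx if k not in rl)
    return TimepointPartition(common=common, additional=additional, lost=lost)


# ---------------------------------------------------------------------------
# Consequence annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifiedVariant:
    """A filtered somatic call with timepoint status and consequence."""

    call: VariantCall
    status: Literal["common", "additional", "lost"]
    variant_class: Literal["SNV", "indel"]
    consequence: str
    gene_id: str | None = None
    hgvs_like: str | None = None

    @property
    def is_non_synonymous(self) -> bool:
        return self.consequence in NON_SYNONYMOUS


@dataclass(frozen=True)
class _ConsequenceResult:
    consequence: str
    gene_id: str | None
    hgvs_like: str | None


class ConsequenceAnnotator:
    """Annotates SNVs/indels against codable gene models and the genome.

    An SNV inside a CDS segment is classified by substituting the alt
    base into its codon on the coding strand and comparing amino acids;
    an indel whose reference footprint overlaps any CDS segment is a
    frameshift when the allele length difference is not a multiple of
    three, otherwise an in-frame indel.  Everything else is non-CDS
    (splice/UTR sub-classes are deliberately not distinguished).
    """

    def __init__(self, genes: Sequence[GeneModel], genome: GenomeAccessor):
        self._genome = genome
        # per-chromosome CDS segment index: sorted starts + parallel data
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, GeneModel]]]] = {}
        tmp: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in genes:
            if not g.codable:
                continue
            for seg in g.cds_segments:
                tmp.setdefault(seg.chrom, []).append((seg.start, seg.end, g))
        for chrom, segs in tmp.items():
            segs.sort(key=lambda t: t[0])
            self._by_chrom[chrom] = (
                [s for s, _, _ in segs],
                [(e, g) for _, e, g in segs],
            )
        self._coding_maps: dict[str, list[int]] = {}

    # -- CDS lookup ---------------------------------------------------------

    def _overlapping_gene(self, chrom: str, start: int, end: int) -> GeneModel | None:
        """First gene model with a CDS segment overlapping [start, end)."""
        idx = self._by_chrom.get(chrom)
        if idx is None:
            return None
        starts, data = idx
        i = bisect_right(starts, end - 1)
        for j in range(i - 1, -1, -1):
            seg_end, gene = data[j]
            if seg_end > start:
                return gene
            # segments are non-overlapping per gene but may interleave
            # across genes; scan back while a segment could still reach
            if starts[j] < start - 10_000_000:
                break
        return None

    def _coding_positions(self, gene: GeneModel) -> list[int]:
        """Genomic positions of the CDS in transcript (5'->3') order."""
        cached = self._coding_maps.get(gene.transcript_id)
        if cached is None:
            pos: list[int] = []
            for seg in gene.cds_segments:
                pos.extend(range(seg.start, seg.end))
            if gene.strand == "-":
                pos.reverse()
            cached = pos
            self._coding_maps[gene.transcript_id] = cached
        return cached

    def _base(self, chrom: str, pos: int, strand: str) -> str:
        b = self._genome.fetch(chrom, pos, pos + 1)
        return _COMPLEMENT[b] if strand == "-" else b

    # -- public API ---------------------------------------------------------

    def annotate(self, v: VariantCall) -> _ConsequenceResult:
        ref_len = len(v.ref)
        start, end = v.anchor, v.anchor + ref_len
        genome_ref = self._genome.fetch(v.chrom, start, end)
        if genome_ref != v.ref:
            raise ReferenceMismatchError(
                f"reference mismatch at {v.chrom}:{v.pos}: call says {v.ref!r}, "
                f"genome says {genome_ref!r}"
            )
        if v.is_snv:
            gene = self._gene_containing(v.chrom, v.anchor)
            if gene is None:
                return _ConsequenceResult("non_CDS", None, None)
            return self._annotate_snv(v, gene)
        gene = self._overlapping_gene(v.chrom, start, end)
        if gene is None:
            return _ConsequenceResult("non_CDS", None, None)
        return self._annotate_indel(v, gene)

    def _gene_containing(self, chrom: str, pos: int) -> GeneModel | None:
        return self._overlapping_gene(chrom, pos, pos + 1)

    def _annotate_snv(self, v: VariantCall, gene: GeneModel) -> _ConsequenceResult:
        coding = self._coding_positions(gene)
        cpos0 = coding.index(v.anchor) if gene.strand == "-" else None
        if gene.strand == "+":
            # arithmetic lookup avoids the O(n) index() on plus strand
            cpos0 = 0
            for seg in gene.cds_segments:
                if seg.start <= v.anchor < seg.end:
                    cpos0 += v.anchor - seg.start
                    break
                cpos0 += len(seg)
        codon_idx = cpos0 // 3
        within = cpos0 % 3
        codon_pos = coding[codon_idx * 3: codon_idx * 3 + 3]
        wt_codon = "".join(self._base(v.chrom, p, gene.strand) for p in codon_pos)
        ref_c = _COMPLEMENT[v.ref] if gene.strand == "-" else v.ref
        alt_c = _COMPLEMENT[v.alt] if gene.strand == "-" else v.alt
        mut_codon = wt_codon[:within] + alt_c + wt_codon[within + 1:]
        wt_aa = str(Seq(wt_codon).translate())
        mut_aa = str(Seq(mut_codon).translate())
        if wt_aa == mut_aa:
            cons = "synonymous"
        elif mut_aa == "*":
            cons = "nonsense"
        elif wt_aa == "*":
            cons = "stop_lost"
        elif codon_idx == 0 and wt_aa == "M":
            cons = "start_lost"
        else:
            cons = "missense"
        hgvs = (
            f"c.{cpos0 + 1}{ref_c}>{alt_c} (p.{wt_aa}{codon_idx + 1}{mut_aa})"
        )
        return _ConsequenceResult(cons, gene.gene_id, hgvs)

    def _annotate_indel(self, v: VariantCall, gene: GeneModel) -> _ConsequenceResult:
        delta = len(v.ref) - len(v.alt)
        cons = "frameshift" if delta % 3 != 0 else "inframe_indel"
        coding = self._coding_positions(gene)
        # VCF-anchored indels share the first base; the event starts after it
        event_start = v.anchor + 1 if v.ref[0] == v.alt[0] else v.anchor
        cds_set = set(coding)
        probe = next(
            (p for p in range(event_start, v.anchor + len(v.ref)) if p in cds_set),
            None,
        )
        if probe is None:
            probe = next(
                (p for p in range(v.anchor, v.anchor + len(v.ref)) if p in cds_set),
                None,
            )
        hgvs = None
        if probe is not None:
            cpos0 = coding.index(probe)
            codon_idx = cpos0 // 3
            codon_pos = coding[codon_idx * 3: codon_idx * 3 + 3]
            wt_codon = "".join(
                self._base(v.chrom, p, gene.strand) for p in codon_pos
            )
            wt_aa = str(Seq(wt_codon).translate())
            if delta > 0 and len(v.alt) == 1 and v.ref[0] == v.alt[0]:
                deleted = v.ref[1:]
                if gene.strand == "-":
                    deleted = _revcomp(deleted)
                tag = f"del{deleted}" if len(deleted) <= 10 else "del"
            elif delta < 0 and len(v.ref) == 1 and v.ref[0] == v.alt[0]:
                inserted = v.alt[1:]
                if gene.strand == "-":
                    inserted = _revcomp(inserted)
                tag = f"ins{inserted}" if len(inserted) <= 10 else "ins"
            else:
                tag = "delins"
            suffix = "fs" if cons == "frameshift" else "del" if delta > 0 else "ins"
            hgvs = f"c.{cpos0 + 1}{tag} (p.{wt_aa}{codon_idx + 1}{suffix})"
        return _ConsequenceResult(cons, gene.gene_id, hgvs)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def annotate_consequence(
    v: VariantCall, genes: Sequence[GeneModel], genome: GenomeAccessor
) -> _ConsequenceResult:
    """One-shot convenience wrapper around :class:`ConsequenceAnnotator`."""
    return ConsequenceAnnotator(genes, genome).annotate(v)


def classify_and_annotate(
    partition: TimepointPartition,
    genes: Sequence[GeneModel],
    genome: GenomeAccessor | None,
) -> list[ClassifiedVariant]:
    """Join timepoint status with consequence for every variant.

    Without a genome/gene set every variant is labelled non-CDS, which
    keeps the purely interval-based downstream stages usable.
    """
    annot = ConsequenceAnnotator(genes, genome) if genome is not None else None
    out: list[ClassifiedVariant] = []
    for status, calls in (
        ("common", partition.common),
        ("additional", partition.additional),
        ("lost", partition.lost),
    ):
        for v in calls:
            if annot is not None:
                res = annot.annotate(v)
            else:
                res = _ConsequenceResult("non_CDS", None, None)
            out.append(
                ClassifiedVariant(
                    call=v,
                    status=status,
                    variant_class="SNV" if v.is_snv else "indel",
                    consequence=res.consequence,
                    gene_id=res.gene_id,
                    hgvs_like=res.hgvs_like,
                )
            )
    return out
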