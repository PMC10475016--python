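"""Transcription regulatory areas (TRAs).

A TRA is a maximal genomic interval where at least ``min_regulators``
DISTINCT transcription regulators have overlapping binding-site
clusters.  Construction is a per-chromosome sweep over cluster
endpoints that tracks the number of distinct regulator names active at
each base (duplicate clusters of one regulator never double-count);
qualifying segments that touch are merged.

Variants join a TRA through their anchor base — the single mutated base
for an SNV, the leftmost reference base for an indel — and regulator
involvement is attributed at that base by default (the regulators whose
clusters overlap the mutated position), with region-level attribution
(all regulators overlapping the whole TRA) available as an option.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from trascan.io import GeneModel, GenomicInterval, TFBSCluster
from trascan.variants import ClassifiedVariant


@dataclass(frozen=True)
class TRARegion:
    """A maximal interval with >= threshold distinct bound regulators.

    ``regulators`` is the union of all factor names whose clusters
    overlap the interval (it can exceed ``max_distinct_depth``, the
    peak simultaneous count, because clusters need not all overlap one
    base).
    """

    interval: GenomicInterval
    regulators: frozenset[str]
    max_distinct_depth: int


@dataclass(frozen=True)
class TRAAlteration:
    """A classified variant whose anchor base lies inside a TRA."""

    variant: ClassifiedVariant
    tra: TRARegion
    involved_regulators: frozenset[str]


@dataclass(frozen=True)
class ProximityConfig:
    """Flanking window for collecting genes near TRA alterations (bp,
    inclusive at exactly ``window``)."""

    window: int = 20_000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")


# ---------------------------------------------------------------------------
# TRA construction
# ---------------------------------------------------------------------------

def build_tra_regions(
    clusters: Iterable[TFBSCluster], min_regulators: int = 5
) -> list[TRARegion]:
    """Sweep-line construction of TRAs from TFBS clusters.

    Returns disjoint regions sorted by (chrom, start).  Adjacent
    qualifying segments merge, so each region is maximal.
    """
    if min_regulators < 1:
        raise ValueError("min_regulators must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end, c.regulator)
        )

    regions: list[TRARegion] = []
    for chrom in sorted(by_chrom):
        regions.extend(_sweep_chrom(chrom, by_chrom[chrom], min_regulators))
    return regions


def _sweep_chrom(
    chrom: str, rows: list[tuple[int, int, str]], k: int
) -> list[TRARegion]:
    events: list[tuple[int, int, str]] = []  # (coord, +1/-1, regulator)
    for start, end, name in rows:
        events.append((start, 1, name))
        events.append((end, -1, name))
    events.sort(key=lambda e: e[0])

    active: Counter[str] = Counter()
    out: list[TRARegion] = []
    cur_start: int | None = None
    cur_regs: set[str] = set()
    cur_depth = 0
    prev_coord: int | None = None
    i, n = 0, len(events)
    while i < n:
        coord = events[i][0]
        if cur_start is not None and prev_coord is not None and prev_coord < coord:
            # segment [prev_coord, coord) was active with >= k regulators
            cur_regs.update(active.keys())
            cur_depth = max(cur_depth, len(active))
        # apply all events at this coordinate
        while i < n and events[i][0] == coord:
            _, delta, name = events[i]
            if delta > 0:
                active[name] += 1
            else:
                active[name] -= 1
                if active[name] == 0:
                    del active[name]
            i += 1
        qualifies = len(active) >= k
        if qualifies and cur_start is None:
            cur_start = coord
            cur_regs = set(active.keys())
            cur_depth = len(active)
        elif not qualifies and cur_start is not None:
            out.append(
                TRARegion(
                    GenomicInterval(chrom, cur_start, coord),
                    frozenset(cur_regs),
                    cur_depth,
                )
            )
            cur_start = None
            cur_regs = set()
            cur_depth = 0
        prev_coord = coord
    return out


def regulators_at(
    clusters: Iterable[TFBSCluster], chrom: str, pos: int
) -> frozenset[str]:
    """Distinct factor names whose cluster contains the base ``[pos, pos+1)``."""
    return frozenset(
        c.regulator for c in clusters if c.interval.contains(chrom, pos)
    )


class _ClusterIndex:
    """Per-chromosome point query over cluster intervals."""

    def __init__(self, clusters: Iterable[TFBSCluster]):
        tmp: dict[str, list[tuple[int, int, str]]] = {}
        for c in clusters:
            tmp.setdefault(c.interval.chrom, []).append(
                (c.interval.start, c.interval.end, c.regulator)
            )
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, rows in tmp.items():
            rows.sort()
            self._by_chrom[chrom] = rows
            self._max_len[chrom] = max(e - s for s, e, _ in rows)

    def at(self, chrom: str, pos: int) -> frozenset[str]:
        rows = self._by_chrom.get(chrom)
        if not rows:
            return frozenset()
        lo_bound = pos - self._max_len[chrom]
        i = bisect_right(rows, (pos, float("inf"), ""))
        names: set[str] = set()
        for j in range(i - 1, -1, -1):
            start, end, name = rows[j]
            if start < lo_bound:
                break
            if start <= pos < end:
                names.add(name)
        return frozenset(names)


def intersect_variants_tras(
    variants: Iterable[ClassifiedVariant],
    tras: Sequence[TRARegion],
    clusters: Iterable[TFBSCluster],
    attribution: Literal["position", "region"] = "position",
) -> list[TRAAlteration]:
    """Join classified variants with the TRA containing their anchor base.

    ``attribution`` chooses how ``involved_regulators`` is filled:
    ``position`` (default) takes the regulators whose clusters overlap
    the mutated base; ``region`` takes every regulator overlapping the
    whole TRA.
    """
    if attribution not in ("position", "region"):
        raise ValueError("attribution must be 'position' or 'region'")
    by_chrom: dict[str, tuple[list[int], list[TRARegion]]] = {}
    for t in sorted(tras, key=lambda t: (t.interval.chrom, t.interval.start)):
        starts, regs = by_chrom.setdefault(t.interval.chrom, ([], []))
        starts.append(t.interval.start)
        regs.append(t)
    index = _ClusterIndex(clusters) if attribution == "position" else None

    out: list[TRAAlteration] = []
    for cv in variants:
        chrom, anchor = cv.call.chrom, cv.call.anchor
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, regs = entry
        i = bisect_right(starts, anchor) - 1
        if i < 0:
            continue
        tra = regs[i]
        if not (tra.interval.start <= anchor < tra.interval.end):
            continue
        involved = (
            index.at(chrom, anchor) if index is not None else tra.regulators
        )
        out.append(TRAAlteration(cv, tra, involved))
    return out


# ---------------------------------------------------------------------------
# Proximity gene collection
# ---------------------------------------------------------------------------

def _gap_to_span(anchor: int, span: GenomicInterval) -> int:
    """Bases strictly between the anchor base and the gene span (0 inside)."""
    if anchor < span.start:
        return span.start - anchor - 1
    if anchor >= span.end:
        return anchor - span.end
    return 0


def genes_within_window(
    alterations: Sequence[TRAAlteration],
    genes: Sequence[GeneModel],
    cfg: ProximityConfig = ProximityConfig(),
) -> tuple[dict[TRAAlteration, frozenset[str]], dict[str, set[str]]]:
    """Collect genes whose span lies within ``cfg.window`` bp of each
    TRA alteration's anchor base (inclusive at exactly the window).

    Returns the per-alteration gene-id mapping and the union gene-id
    set per variant status (common/additional/lost).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span.start)

    per_alt: dict[TRAAlteration, frozenset[str]] = {}
    per_status: dict[str, set[str]] = {}
    for alt in alterations:
        anchor = alt.variant.call.anchor
        hits: set[str] = set()
        for g in by_chrom.get(alt.variant.call.chrom, ()):
            if _gap_to_span(anchor, g.span) <= cfg.window:
                hits.add(g.gene_id)
        per_alt[alt] = frozenset(hits)
        per_status.setdefault(alt.variant.status, set()).update(hits)
    return per_alt, per_status


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_tra_bed(tras: Sequence[TRARegion], path) -> None:
    """BED5+1: chrom, start, end, TRA_<n>, max distinct depth, regulators."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for n, t in enumerate(tras, start=1):
            regs = ";".join(sorted(t.regulators))
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"TRA_{n}\t{t.max_distinct_depth}\t{regs}\n"
            )


def total_coverage(tras: Iterable[TRARegion]) -> int:
    """Total bases covered by a (disjoint) TRA set."""
    return sum(len(t.interval) for t in tras)
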