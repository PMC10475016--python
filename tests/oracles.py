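"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
— per-base materialisation, full-protein translation, quadratic
distance scans — and stays independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from trascan.io import GeneModel, GenomicInterval, TFBSCluster, VariantCall
from trascan.tra import TRAAlteration, TRARegion
from trascan.variants import ClassifiedVariant


# ---------------------------------------------------------------------------
# Per-base TRA oracle
# ---------------------------------------------------------------------------

def brute_force_tras(
    clusters: list[TFBSCluster], min_regulators: int
) -> list[tuple[str, int, int]]:
    """Materialise distinct-regulator counts for every base, threshold,
    take maximal runs.  Returns sorted (chrom, start, end) triples."""
    by_chrom: dict[str, list[TFBSCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        length = max(c.interval.end for c in cs) + 1
        regs = sorted({c.regulator for c in cs})
        counts = np.zeros(length, dtype=np.int32)
        for reg in regs:
            cover = np.zeros(length, dtype=bool)
            for c in cs:
                if c.regulator == reg:
                    cover[c.interval.start: c.interval.end] = True
            counts += cover
        above = counts >= min_regulators
        # maximal runs of True
        padded = np.concatenate(([False], above, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def brute_force_regulators_at(
    clusters: list[TFBSCluster], chrom: str, pos: int
) -> frozenset[str]:
    return frozenset(
        c.regulator for c in clusters
        if c.interval.chrom == chrom and c.interval.start <= pos < c.interval.end
    )


# ---------------------------------------------------------------------------
# Toy gene models on an in-memory genome
# ---------------------------------------------------------------------------

class DictGenome:
    """Duck-typed genome accessor backed by plain strings."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = {k: v.upper() for k, v in seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])


_STOPS = ("TAA", "TAG", "TGA")
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def random_gene_genome(
    rng: np.random.Generator, chrom: str = "chrT"
) -> tuple[GeneModel, DictGenome]:
    """A random multi-exon gene (either strand, arbitrary exon phases)
    written into a random background sequence."""
    n_codons = int(rng.integers(12, 60))
    cds = (
        "ATG"
        + "".join(_SAFE_CODONS[i]
                  for i in rng.integers(0, len(_SAFE_CODONS), n_codons))
        + _STOPS[int(rng.integers(0, 3))]
    )
    n_exons = int(rng.integers(1, 4))
    # arbitrary splits (codons may straddle exon boundaries)
    if n_exons == 1:
        chunks = [len(cds)]
    else:
        cuts = sorted(
            int(x) for x in rng.choice(
                np.arange(1, len(cds)), size=n_exons - 1, replace=False
            )
        )
        bounds = [0, *cuts, len(cds)]
        chunks = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    segs: list[tuple[int, int]] = []
    pos = int(rng.integers(50, 200))
    for ln in chunks:
        segs.append((pos, pos + ln))
        pos += ln + int(rng.integers(20, 120))
    total = pos + 200
    background = "".join("ACGT"[i] for i in rng.integers(0, 4, total))
    seq = list(background)
    if strand == "+":
        off = 0
        for s, e in segs:
            seq[s:e] = cds[off: off + (e - s)]
            off += e - s
    else:
        off = 0
        for s, e in reversed(segs):
            seq[s:e] = _revcomp(cds[off: off + (e - s)])
            off += e - s
    genome = DictGenome({chrom: "".join(seq)})
    gene = GeneModel(
        gene_id="TOY1",
        gene_name="TOY1",
        transcript_id="TOY1.t1",
        span=GenomicInterval(chrom, segs[0][0], segs[-1][1]),
        strand=strand,
        cds_segments=tuple(
            GenomicInterval(chrom, s, e) for s, e in segs
        ),
    )
    return gene, genome


def spliced_cds(gene: GeneModel, genome: DictGenome) -> str:
    """CDS in transcript order via splice + reverse complement."""
    parts = [
        genome.fetch(seg.chrom, seg.start, seg.end)
        for seg in gene.cds_segments
    ]
    cds = "".join(parts)
    return _revcomp(cds) if gene.strand == "-" else cds


def oracle_snv_consequence(
    v: VariantCall, gene: GeneModel, genome: DictGenome
) -> str:
    """Translate the entire wildtype and mutant CDS and diff proteins."""
    wt_cds = spliced_cds(gene, genome)
    mut_seq = dict(genome.seqs)
    chrom_seq = list(mut_seq[v.chrom])
    assert chrom_seq[v.anchor] == v.ref
    chrom_seq[v.anchor] = v.alt
    mut_genome = DictGenome({v.chrom: "".join(chrom_seq)})
    mut_cds = spliced_cds(gene, mut_genome)
    wt_prot = str(Seq(wt_cds).translate())
    mut_prot = str(Seq(mut_cds).translate())
    if wt_prot == mut_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b]
    i = diffs[0]
    if mut_prot[i] == "*":
        return "nonsense"
    if wt_prot[i] == "*":
        return "stop_lost"
    if i == 0 and wt_prot[0] == "M":
        return "start_lost"
    return "missense"


# ---------------------------------------------------------------------------
# Proximity oracle
# ---------------------------------------------------------------------------

def brute_force_genes_near(
    anchor_chrom: str, anchor: int, genes: list[GeneModel], window: int
) -> set[str]:
    """O(G) scan counting bases strictly between anchor base and span."""
    hits: set[str] = set()
    for g in genes:
        if g.span.chrom != anchor_chrom:
            continue
        if g.span.start <= anchor < g.span.end:
            gap = 0
        elif anchor < g.span.start:
            gap = g.span.start - anchor - 1
        else:
            gap = anchor - g.span.end
        if gap <= window:
            hits.add(g.gene_id)
    return hits


# ---------------------------------------------------------------------------
# Alteration construction helpers
# ---------------------------------------------------------------------------

def make_alteration(
    status: str, regulators: set[str], pos: int = 100, chrom: str = "chr1"
) -> TRAAlteration:
    call = VariantCall(chrom, pos + 1, "A", "T", 20, 10, "relapse")
    cv = ClassifiedVariant(call, status, "SNV", "non_CDS")
    tra = TRARegion(
        GenomicInterval(chrom, pos - 10 if pos >= 10 else 0, pos + 10),
        frozenset(regulators), max(len(regulators), 1),
    )
    return TRAAlteration(cv, tra, frozenset(regulators))
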