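"""Synthetic inputs with planted ground truth.

Every pipeline input — genome FASTA, gene-model GFF3, TFBS-cluster
BED, per-sample variant tables, and gene/transcript expression tables
— can be generated here as a pure function of a seed, together with a
JSON truth sidecar that records exactly what was planted (TRA
intervals, per-class variant counts, per-regulator involvement
probabilities, DE/shift gene sets).  Tests and golden runs read the
sidecar; they never re-derive the truth.

The planted-TRA construction uses a zone scheme so that regulator
involvement can be planted base-by-base: a planted region carries a
core of ``k`` regulators covering it end to end (these define the
region), plus ``m`` optional regulators laid out over ``2**m`` equal
zones where zone ``j`` is covered by exactly the optional regulators
whose bit is set in ``j``.  A variant that should involve optional
subset ``S`` is then dropped into zone ``bitmask(S)``, giving exact
base-level involvement under position attribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from trascan.errors import TrascanError
from trascan.io import (
    GenomicInterval,
    TFBSCluster,
    VariantCall,
    write_tfbs_clusters,
    write_variants_tsv,
)
from trascan.tra import build_tra_regions

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: str) -> str:
    return s.encode()[::-1].translate(_COMPLEMENT).decode()


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Machine-readable record of everything a simulation planted."""

    seed: int
    planted_tras: list[tuple[str, int, int]] = field(default_factory=list)
    planted_counts: dict[str, int] = field(default_factory=dict)
    recovered_counts: dict[str, int] = field(default_factory=dict)
    regulator_probs: dict[str, tuple[float, float]] = field(default_factory=dict)
    de_truth: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_tras": [list(t) for t in self.planted_tras],
            "planted_counts": self.planted_counts,
            "recovered_counts": self.recovered_counts,
            "regulator_probs": {
                k: list(v) for k, v in self.regulator_probs.items()
            },
            "de_truth": self.de_truth,
        }
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            planted_tras=[tuple(t) for t in d["planted_tras"]],
            planted_counts=d["planted_counts"],
            recovered_counts=d["recovered_counts"],
            regulator_probs={
                k: tuple(v) for k, v in d["regulator_probs"].items()
            },
            de_truth=d["de_truth"],
        )


# ---------------------------------------------------------------------------
# Reference genome + gene models
# ---------------------------------------------------------------------------

def simulate_reference(
    out_fasta: str | Path,
    out_gff: str | Path,
    n_chrom: int = 2,
    chrom_length: int = 300_000,
    n_genes: int = 60,
    cds_exons_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> dict[str, int]:
    """Write a random genome and non-overlapping codable gene models.

    Every emitted CDS starts with ATG, ends with a stop codon, has no
    internal stop, and a total length divisible by 3; both strands are
    represented.  Returns the chromosome-size map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    genomes = {
        c: rng.integers(0, 4, size=chrom_length).astype(np.uint8)
        for c in chrom_names
    }

    # budget: genes packed sequentially with random gaps
    genes_per_chrom = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        genes_per_chrom[i] += 1

    gff_lines: list[str] = ["##gff-version 3"]
    gene_idx = 0
    for chrom, n_here in zip(chrom_names, genes_per_chrom):
        cursor = 500
        for _ in range(n_here):
            gene_idx += 1
            n_codons = int(rng.integers(40, 200))  # aa incl. neither ATG nor stop
            codons = (
                ["ATG"]
                + [_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons)]
                + [("TAA", "TAG", "TGA")[rng.integers(0, 3)]]
            )
            cds = "".join(codons)
            n_exons = int(rng.integers(cds_exons_per_gene[0],
                                       cds_exons_per_gene[1] + 1))
            chunks = _split_lengths(rng, len(cds), n_exons)
            strand = "+" if rng.random() < 0.5 else "-"
            segs: list[tuple[int, int]] = []
            pos = cursor + int(rng.integers(200, 1200))
            for ln in chunks:
                segs.append((pos, pos + ln))
                pos += ln + int(rng.integers(50, 500))
            if segs[-1][1] > chrom_length - 500:
                raise TrascanError(
                    "infeasible gene packing: reduce n_genes or enlarge "
                    "chromosomes"
                )
            cursor = segs[-1][1] + int(rng.integers(500, 2000))
            _write_cds_into_genome(genomes[chrom], cds, segs, strand)

            gid = f"GENE{gene_idx:04d}"
            tid = f"{gid}.t1"
            span = (segs[0][0], segs[-1][1])
            gff_lines.append(
                f"{chrom}\tsim\tgene\t{span[0] + 1}\t{span[1]}\t.\t{strand}\t.\t"
                f"ID={gid};Name={gid}"
            )
            gff_lines.append(
                f"{chrom}\tsim\tmRNA\t{span[0] + 1}\t{span[1]}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={gid}"
            )
            for k, (s, e) in enumerate(segs, start=1):
                phase = _segment_phase(chunks, k - 1, strand)
                gff_lines.append(
                    f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t"
                    f"ID={tid}.cds{k};Parent={tid}"
                )

    with open(out_fasta, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = _BASES[genomes[chrom]].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    with open(out_gff, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    return {c: chrom_length for c in chrom_names}


def _split_lengths(rng: np.random.Generator, total: int, n: int) -> list[int]:
    """Split ``total`` (divisible by 3) into n chunks, each >= 3."""
    if n == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(1, total // 3), size=n - 1,
                             replace=False) * 3)
    bounds = [0, *map(int, cuts), total]
    return [bounds[i + 1] - bounds[i] for i in range(n)]


def _segment_phase(chunks: Sequence[int], idx: int, strand: str) -> int:
    if strand == "+":
        before = sum(chunks[:idx])
    else:
        before = sum(chunks[idx + 1:])
    return (3 - before % 3) % 3


def _write_cds_into_genome(
    genome: np.ndarray, cds: str, segs: Sequence[tuple[int, int]], strand: str
) -> None:
    lut = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    if strand == "+":
        offset = 0
        for s, e in segs:
            chunk = cds[offset: offset + (e - s)]
            genome[s:e] = [lut[b] for b in chunk.encode()]
            offset += e - s
    else:
        # transcript order is reverse genomic order; each chunk lands
        # reverse-complemented on the plus strand
        offset = 0
        for s, e in reversed(segs):
            chunk = cds[offset: offset + (e - s)]
            genome[s:e] = [lut[b] for b in _revcomp(chunk).encode()]
            offset += e - s


# ---------------------------------------------------------------------------
# TFBS clusters with planted TRAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTRA:
    """Specification of one planted regulatory region.

    ``core_regulators`` cover the interval end to end and define
    whether the region qualifies (len >= the build threshold or not).
    ``optional_regulators`` (m of them) are laid out over ``2**m``
    zones as described in the module docstring.
    """

    chrom: str
    start: int
    end: int
    core_regulators: tuple[str, ...]
    optional_regulators: tuple[str, ...] = ()

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def n_zones(self) -> int:
        return 2 ** len(self.optional_regulators)

    @property
    def zone_width(self) -> int:
        return (self.end - self.start) // self.n_zones

    def zone_interval(self, j: int) -> tuple[int, int]:
        s = self.start + j * self.zone_width
        e = self.end if j == self.n_zones - 1 else s + self.zone_width
        return s, e

    def zone_of_subset(self, subset: Sequence[str]) -> int:
        mask = 0
        for i, reg in enumerate(self.optional_regulators):
            if reg in subset:
                mask |= 1 << i
        return mask


def simulate_tfbs(
    chrom_sizes: Mapping[str, int],
    planted: Sequence[PlantedTRA],
    background_regulators: Sequence[str],
    n_background: int = 150,
    min_regulators: int = 5,
    seed: int = 0,
    out_bed: str | Path | None = None,
    max_retries: int = 20,
) -> list[TFBSCluster]:
    """Emit TFBS clusters realising the planted regions exactly.

    Planted regions whose core size reaches ``min_regulators`` are
    guaranteed to be recovered verbatim by the TRA builder; background
    clusters are placed clear of planted intervals and re-jittered (up
    to ``max_retries``) until no accidental region reaches the
    threshold, audited by actually running the builder.
    """
    for p in planted:
        if p.optional_regulators and p.zone_width < 1:
            raise TrascanError(
                f"planted region {p.chrom}:{p.start}-{p.end} too short for "
                f"{len(p.optional_regulators)} optional regulators"
            )

    fixed: list[TFBSCluster] = []
    for p in planted:
        for reg in p.core_regulators:
            fixed.append(TFBSCluster(p.interval, reg, 1000))
        for i, reg in enumerate(p.optional_regulators):
            # merge consecutive zones carrying this regulator into runs
            run_start: int | None = None
            for j in range(p.n_zones + 1):
                has = j < p.n_zones and (j >> i) & 1
                if has and run_start is None:
                    run_start = j
                elif not has and run_start is not None:
                    s = p.zone_interval(run_start)[0]
                    e = p.zone_interval(j - 1)[1]
                    fixed.append(
                        TFBSCluster(GenomicInterval(p.chrom, s, e), reg, 800)
                    )
                    run_start = None

    expected = sorted(
        (p.chrom, p.start, p.end)
        for p in planted
        if len(p.core_regulators) >= min_regulators
    )
    forbidden = [(p.chrom, p.start, p.end) for p in planted]
    chroms = sorted(chrom_sizes)

    ss = np.random.SeedSequence([seed, 23])
    for attempt in range(max_retries):
        rng = np.random.default_rng(ss.spawn(1)[0] if attempt else ss)
        background: list[TFBSCluster] = []
        while len(background) < n_background:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(100, 600))
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            if any(
                c == chrom and start < fe + 1 and fs - 1 < start + length
                for c, fs, fe in forbidden
            ):
                continue
            reg = background_regulators[
                int(rng.integers(0, len(background_regulators)))
            ]
            score = int(rng.integers(100, 1000))
            background.append(
                TFBSCluster(GenomicInterval(chrom, start, start + length),
                            reg, score)
            )
        clusters = fixed + background
        built = build_tra_regions(clusters, min_regulators)
        got = sorted(
            (t.interval.chrom, t.interval.start, t.interval.end) for t in built
        )
        if got == expected:
            clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                         c.interval.end, c.regulator))
            if out_bed is not None:
                write_tfbs_clusters(clusters, out_bed)
            return clusters
    raise TrascanError(
        f"could not place background clusters without creating accidental "
        f"regions after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Variant sets
# ---------------------------------------------------------------------------

def simulate_variant_sets(
    genome_fetch,
    chrom_sizes: Mapping[str, int],
    planted_tras: Sequence[PlantedTRA],
    regulator_probs: Mapping[str, tuple[float, float]],
    n_germline: int = 40,
    n_common: int = 60,
    n_additional: int = 90,
    n_lost: int = 25,
    n_common_in_tra: int = 32,
    n_additional_in_tra: int = 54,
    subthreshold_fraction: float = 0.1,
    indel_fraction: float = 0.05,
    min_regulators: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall], SimulationTruth]:
    """Generate germline/diagnosis/relapse call tables with planted truth.

    Germline variants appear in all three tables (subtraction must
    remove them).  Common variants sit in both tumour samples,
    additional in relapse only, lost in diagnosis only.  In-TRA
    variants are placed at bases whose optional-regulator overlap is
    drawn per ``regulator_probs`` (index 0 = common, 1 = additional).
    ``subthreshold_fraction`` of each tumour class is given read
    support that fails the identification conditions (VAF exactly 0.20
    or four supporting reads, alternating), preferring variants
    outside TRAs so the in-TRA counts survive intact; the sidecar
    records both the planted and the expected post-filter counts.

    ``genome_fetch(chrom, start, end)`` must return uppercase sequence.
    """
    if n_common_in_tra > n_common or n_additional_in_tra > n_additional:
        raise TrascanError("in-TRA count exceeds its class total")
    qualifying = [
        p for p in planted_tras if len(p.core_regulators) >= min_regulators
    ]
    if (n_common_in_tra or n_additional_in_tra) and not qualifying:
        raise TrascanError("no qualifying planted regions to receive variants")
    capacity = sum(p.end - p.start for p in qualifying)
    if n_common_in_tra + n_additional_in_tra > capacity:
        raise TrascanError(
            f"in-TRA variant request ({n_common_in_tra + n_additional_in_tra}) "
            f"exceeds planted capacity ({capacity})"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    used: set[tuple[str, int]] = set()
    tra_intervals = [(p.chrom, p.start, p.end) for p in qualifying]
    chroms = sorted(chrom_sizes)

    def passing_support() -> tuple[int, int]:
        while True:
            depth = int(rng.integers(30, 101))
            alt = int(rng.binomial(depth, 0.35))
            if alt >= 5 and alt / depth > 0.20:
                return depth - alt, alt

    def germline_support() -> tuple[int, int]:
        while True:
            depth = int(rng.integers(30, 101))
            alt = int(rng.binomial(depth, 0.5))
            if alt >= 5 and alt / depth > 0.20:
                return depth - alt, alt

    def free_background_pos() -> tuple[str, int]:
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(10, chrom_sizes[chrom] - 10))
            if (chrom, pos) in used:
                continue
            if any(c == chrom and s <= pos < e for c, s, e in tra_intervals):
                continue
            used.add((chrom, pos))
            return chrom, pos

    def free_zone_pos(p: PlantedTRA, zone: int) -> tuple[str, int]:
        s, e = p.zone_interval(zone)
        for _ in range(200):
            pos = int(rng.integers(s, e))
            if (p.chrom, pos) not in used:
                used.add((p.chrom, pos))
                return p.chrom, pos
        raise TrascanError("zone exhausted; enlarge planted regions")

    def make_snv(chrom: str, pos: int, sample: str,
                 support: tuple[int, int]) -> VariantCall:
        ref = genome_fetch(chrom, pos, pos + 1)
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
        return VariantCall(chrom, pos + 1, ref, alt, support[0], support[1],
                           sample)

    def make_indel(chrom: str, pos: int, sample: str,
                   support: tuple[int, int]) -> VariantCall:
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # deletion
            ref = genome_fetch(chrom, pos, pos + 1 + size)
            alt = ref[0]
        else:  # insertion
            ref = genome_fetch(chrom, pos, pos + 1)
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size))
            alt = ref + ins
        return VariantCall(chrom, pos + 1, ref, alt, support[0], support[1],
                           sample)

    regs = list(regulator_probs)

    def draw_subset(class_idx: int) -> list[str]:
        return [
            r for r in regs
            if rng.random() < regulator_probs[r][class_idx]
        ]

    def place_in_tra(class_idx: int) -> tuple[str, int]:
        p = qualifying[int(rng.integers(0, len(qualifying)))]
        subset = [r for r in draw_subset(class_idx)
                  if r in p.optional_regulators]
        return free_zone_pos(p, p.zone_of_subset(subset))

    # ---- germline (in all three tables) ------------------------------
    germline: list[VariantCall] = []
    dx_extra: list[VariantCall] = []
    rl_extra: list[VariantCall] = []
    for _ in range(n_germline):
        chrom, pos = free_background_pos()
        germline.append(make_snv(chrom, pos, "germline", germline_support()))
        v = germline[-1]
        dx_extra.append(VariantCall(v.chrom, v.pos, v.ref, v.alt,
                                    *germline_support(), "diagnosis"))
        rl_extra.append(VariantCall(v.chrom, v.pos, v.ref, v.alt,
                                    *germline_support(), "relapse"))

    # ---- somatic classes ---------------------------------------------
    def build_class(n_total: int, n_in_tra: int, class_idx: int,
                    sample_for_pos: str) -> tuple[list[VariantCall], int]:
        """Returns the class calls (in-TRA first) and the in-TRA count."""
        calls: list[VariantCall] = []
        for _ in range(n_in_tra):
            chrom, pos = place_in_tra(class_idx)
            calls.append(make_snv(chrom, pos, sample_for_pos,
                                  passing_support()))
        for i in range(n_total - n_in_tra):
            chrom, pos = free_background_pos()
            maker = make_indel if rng.random() < indel_fraction else make_snv
            calls.append(maker(chrom, pos, sample_for_pos, passing_support()))
        return calls, n_in_tra

    common, _ = build_class(n_common, n_common_in_tra, 0, "relapse")
    additional, _ = build_class(n_additional, n_additional_in_tra, 1, "relapse")
    lost, _ = build_class(n_lost, 0, 0, "diagnosis")

    # ---- sub-threshold conversion ------------------------------------
    def subthreshold_support(i: int) -> tuple[int, int]:
        # alternate the two boundary failure modes
        return (24, 6) if i % 2 == 0 else (6, 4)  # VAF == 0.20 / alt == 4

    def convert_tail(calls: list[VariantCall], n_sub: int,
                     n_in_tra: int) -> tuple[list[VariantCall], int, int]:
        """Convert the last n_sub calls (out-of-TRA first by layout)."""
        out = list(calls)
        converted_in_tra = 0
        for i in range(n_sub):
            idx = len(out) - 1 - i
            if idx < n_in_tra:
                converted_in_tra += 1
            rr, ar = subthreshold_support(i)
            v = out[idx]
            out[idx] = VariantCall(v.chrom, v.pos, v.ref, v.alt, rr, ar,
                                   v.sample)
        return out, n_sub, converted_in_tra

    n_sub_common = round(subthreshold_fraction * n_common)
    n_sub_additional = round(subthreshold_fraction * n_additional)
    n_sub_lost = round(subthreshold_fraction * n_lost)
    common, sc, sc_tra = convert_tail(common, n_sub_common, n_common_in_tra)
    additional, sa, sa_tra = convert_tail(additional, n_sub_additional,
                                          n_additional_in_tra)
    lost, sl, _ = convert_tail(lost, n_sub_lost, 0)

    def resample(v: VariantCall, sample: str) -> VariantCall:
        if v.alt_reads == 4 or v.vaf <= 0.20:  # keep sub-threshold in both
            return VariantCall(v.chrom, v.pos, v.ref, v.alt, v.ref_reads,
                               v.alt_reads, sample)
        rr, ar = passing_support()
        return VariantCall(v.chrom, v.pos, v.ref, v.alt, rr, ar, sample)

    diagnosis = (
        dx_extra
        + [resample(v, "diagnosis") for v in common]
        + [VariantCall(v.chrom, v.pos, v.ref, v.alt, v.ref_reads,
                       v.alt_reads, "diagnosis") for v in lost]
    )
    relapse = rl_extra + list(common) + list(additional)

    def sort_calls(calls: list[VariantCall]) -> list[VariantCall]:
        return sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    germline = sort_calls(germline)
    diagnosis = sort_calls(diagnosis)
    relapse = sort_calls(relapse)

    truth = SimulationTruth(
        seed=seed,
        planted_tras=sorted(tra_intervals),
        planted_counts={
            "n_germline": n_germline,
            "n_common": n_common,
            "n_additional": n_additional,
            "n_lost": n_lost,
            "n_common_in_tra": n_common_in_tra,
            "n_additional_in_tra": n_additional_in_tra,
        },
        recovered_counts={
            "n_common": n_common - sc,
            "n_additional": n_additional - sa,
            "n_lost": n_lost - sl,
            "n_common_in_tra": n_common_in_tra - sc_tra,
            "n_additional_in_tra": n_additional_in_tra - sa_tra,
        },
        regulator_probs={k: tuple(v) for k, v in regulator_probs.items()},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_variants_tsv(germline, out_dir / "germline.tsv")
        write_variants_tsv(diagnosis, out_dir / "diagnosis.tsv")
        write_variants_tsv(relapse, out_dir / "relapse.tsv")
    return germline, diagnosis, relapse, truth


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 3000,
    n_up: int = 74,
    n_down: int = 320,
    n_shift_genes: int = 1321,
    effect_log2fc: float = 2.0,
    replicates: int = 3,
    noise_sd: float = 0.15,
    gene_ids: Sequence[str] | None = None,
    seed: int = 0,
    out_gene_tsv: str | Path | None = None,
    out_transcript_tsv: str | Path | None = None,
) -> tuple["pd.DataFrame", "pd.DataFrame", dict[str, list[str]]]:
    """Gene- and transcript-level FPKM tables with planted DE truth.

    Planted up/down genes carry the log2 effect with margin above the
    |FC| >= 2 bound and a p-value forced below the 0.01 cutoff; null
    genes fluctuate around zero log-FC with p drawn uniformly.  Shift
    genes (disjoint from up/down) receive one transcript with an
    accepted structure label passing both thresholds; decoy
    transcripts either fail the thresholds or carry a non-accepted
    label.  Returns (gene table, transcript table, de_truth dict).
    """
    import pandas as pd

    if n_up + n_down + n_shift_genes > n_genes:
        raise TrascanError("planted gene classes exceed the gene universe")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))

    universe = list(gene_ids or [])
    universe += [f"SIMG{i:05d}" for i in range(n_genes - len(universe))]
    universe = universe[:n_genes]
    perm = rng.permutation(n_genes)
    up_ids = [universe[i] for i in perm[:n_up]]
    down_ids = [universe[i] for i in perm[n_up: n_up + n_down]]
    shift_ids = [
        universe[i] for i in perm[n_up + n_down: n_up + n_down + n_shift_genes]
    ]
    up_set, down_set = set(up_ids), set(down_ids)

    ctrl_cols = [f"ctrl_{i + 1}" for i in range(replicates)]
    cond_cols = [f"cond_{i + 1}" for i in range(replicates)]

    base = rng.uniform(3.0, 8.0, size=n_genes)  # log2 FPKM
    effect = np.zeros(n_genes)
    for i in perm[:n_up]:
        effect[i] = effect_log2fc
    for i in perm[n_up: n_up + n_down]:
        effect[i] = -effect_log2fc
    ctrl = 2.0 ** (
        base[:, None] + rng.normal(0, noise_sd, (n_genes, replicates))
    )
    cond = 2.0 ** (
        base[:, None] + effect[:, None]
        + rng.normal(0, noise_sd, (n_genes, replicates))
    )
    p = rng.uniform(0.0, 1.0, n_genes)
    planted_mask = np.zeros(n_genes, dtype=bool)
    planted_mask[perm[: n_up + n_down]] = True
    p[planted_mask] = 10.0 ** rng.uniform(-8.0, -3.0, int(planted_mask.sum()))
    # a fluking null could otherwise cross both bounds at once; nulls with
    # sub-cutoff p keep their (near-zero) effect, which cannot reach |FC|>=2

    gene_df = pd.DataFrame({"gene_id": universe})
    for j, c in enumerate(ctrl_cols):
        gene_df[c] = np.round(ctrl[:, j], 4)
    for j, c in enumerate(cond_cols):
        gene_df[c] = np.round(cond[:, j], 4)
    gene_df["p_value"] = p

    # transcript rows: one passing accepted-class transcript per shift
    # gene plus decoys on a sample of other genes
    classes = ["containment_of_references", "junction_match"]
    rows: list[dict] = []
    for g in shift_ids:
        lfc = effect_log2fc * (1 if rng.random() < 0.5 else -1)
        rows.append(
            {
                "transcript_id": f"{g}.tvA",
                "gene_id": g,
                "fold_change": round(float(2.0 ** (lfc + rng.normal(0, 0.1))), 4),
                "p_value": float(10.0 ** rng.uniform(-6.0, -3.0)),
                "structure_class": classes[int(rng.integers(0, 2))],
            }
        )
    others = [universe[i] for i in perm[n_up + n_down + n_shift_genes:]]
    n_decoy = min(len(others), max(50, n_shift_genes // 4))
    for g in others[:n_decoy]:
        if rng.random() < 0.5:  # accepted class, fails thresholds
            rows.append(
                {
                    "transcript_id": f"{g}.tvA",
                    "gene_id": g,
                    "fold_change": round(float(2.0 ** rng.normal(0, 0.2)), 4),
                    "p_value": float(rng.uniform(0.02, 1.0)),
                    "structure_class": classes[int(rng.integers(0, 2))],
                }
            )
        else:  # passes thresholds but carries a non-accepted label
            rows.append(
                {
                    "transcript_id": f"{g}.tvA",
                    "gene_id": g,
                    "fold_change": round(float(2.0 ** (effect_log2fc
                                                       + rng.normal(0, 0.1))), 4),
                    "p_value": float(10.0 ** rng.uniform(-5.0, -3.0)),
                    "structure_class": "novel",
                }
            )
    tx_df = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "fold_change", "p_value",
                 "structure_class"],
    )

    de_truth = {
        "up": sorted(up_set),
        "down": sorted(down_set),
        "shift": sorted(shift_ids),
    }
    if out_gene_tsv is not None:
        gene_df.to_csv(out_gene_tsv, sep="\t", index=False,
                       lineterminator="\n")
    if out_transcript_tsv is not None:
        tx_df.to_csv(out_transcript_tsv, sep="\t", index=False,
                     lineterminator="\n")
    return gene_df, tx_df, de_truth


# ---------------------------------------------------------------------------
# The "default" preset fixture
# ---------------------------------------------------------------------------

#: always-on regulators covering each planted region end to end
CORE_REGULATORS = ("TAF1", "YY1", "SP1", "MAX", "JUND")

#: optional regulators with planted (p_common, p_additional) involvement
DEFAULT_REGULATOR_PROBS: dict[str, tuple[float, float]] = {
    "POLR2A": (0.60, 0.60),
    "EP300": (0.30, 0.30),
    "CTCF": (0.30, 0.30),
    "MYC": (0.28, 0.47),
    "RCOR1": (0.10, 0.40),
    "CHD2": (0.08, 0.30),
    "RXRA": (0.00, 0.05),
    "KDM5B": (0.00, 0.04),
}

BACKGROUND_REGULATORS = (
    "GATA1", "STAT1", "HDAC1", "PHF8", "REST", "EGR1", "ELF1", "FOS",
    "JUN", "NRF1", "SIN3A", "TBP", "USF1", "ZBTB33", "RAD21",
)


def default_fixture(out_dir: str | Path, seed: int = 7) -> SimulationTruth:
    """Generate the complete default fixture into ``out_dir``.

    Chooses study-scale defaults: a 2 x 300 kb genome with 60 genes, 12
    planted regulatory regions of 4,096 bp (5 core + 8 optional
    regulators) plus 3 sub-threshold decoy regions, 32 common and 54
    additional in-TRA variants among realistic class totals, and an
    expression universe of 3,000 genes with 74 up / 320 down / 1,321
    shift genes planted.  Writes every pipeline input plus the
    ``truth.json`` sidecar and returns the truth object.
    """
    from trascan.io import read_genome

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = simulate_reference(
        out / "genome.fa", out / "genes.gff3",
        n_chrom=2, chrom_length=300_000, n_genes=60,
        cds_exons_per_gene=(1, 3), seed=seed,
    )

    optional = tuple(DEFAULT_REGULATOR_PROBS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    planted: list[PlantedTRA] = []
    chroms = sorted(chrom_sizes)
    # 12 qualifying regions spread over both chromosomes, then 3 decoys
    # with only 4 core regulators (below the threshold of 5)
    slots = []
    for chrom in chroms:
        anchors = np.linspace(20_000, chrom_sizes[chrom] - 30_000, 8)
        slots.extend((chrom, int(a)) for a in anchors)
    order = rng.permutation(len(slots))
    for idx in order[:12]:
        chrom, start = slots[idx]
        start += int(rng.integers(0, 2_000))
        planted.append(
            PlantedTRA(chrom, start, start + 4096, CORE_REGULATORS, optional)
        )
    for idx in order[12:15]:
        chrom, start = slots[idx]
        start += int(rng.integers(0, 2_000))
        planted.append(
            PlantedTRA(chrom, start, start + 1000, CORE_REGULATORS[:4])
        )

    simulate_tfbs(
        chrom_sizes, planted, BACKGROUND_REGULATORS,
        n_background=150, min_regulators=5, seed=seed,
        out_bed=out / "tfbs_clusters.bed",
    )

    genome = read_genome(out / "genome.fa")
    try:
        _, _, _, truth = simulate_variant_sets(
            genome.fetch, chrom_sizes, planted, DEFAULT_REGULATOR_PROBS,
            n_germline=40, n_common=60, n_additional=90, n_lost=25,
            n_common_in_tra=32, n_additional_in_tra=54,
            subthreshold_fraction=0.1, seed=seed, out_dir=out,
        )
    finally:
        genome.close()

    _, _, de_truth = simulate_expression(
        n_genes=3000, n_up=74, n_down=320, n_shift_genes=1321,
        gene_ids=[f"GENE{i:04d}" for i in range(1, 61)], seed=seed,
        out_gene_tsv=out / "gene_expression.tsv",
        out_transcript_tsv=out / "transcript_expression.tsv",
    )
    truth.de_truth = de_truth
    truth.to_json(out / "truth.json")
    return truth
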