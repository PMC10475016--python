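"""End-to-end workflow composition.

Stage order is fixed: filter -> germline subtraction -> timepoint
classification -> consequence annotation -> TRA construction ->
variant/TRA intersection -> proximity gene collection -> regulator
involvement -> expression integration.  Every output is reproducible
byte-for-byte from the same inputs and configuration; wall-clock
timestamps are recorded in the manifest only on explicit request so
that reruns stay byte-identical by default.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

from trascan.errors import TrascanError
from trascan.expression import (
    DEFAULT_ACCEPTED_CLASSES,
    compute_fold_change,
    de_filter,
    overlap_sets,
    read_expression_table,
    transcript_shift_genes,
    write_gene_set,
    write_overlap_tsv,
)
from trascan.io import (
    VariantCall,
    read_gene_models,
    read_genome,
    read_tfbs_clusters,
    read_variants,
)
from trascan.regulators import (
    involvement_table,
    skew_report,
    write_involvement_tsv,
)
from trascan.tra import (
    ProximityConfig,
    TRAAlteration,
    build_tra_regions,
    genes_within_window,
    intersect_variants_tras,
    total_coverage,
    write_tra_bed,
)
from trascan.variants import (
    ClassifiedVariant,
    FilterThresholds,
    NON_SYNONYMOUS,
    classify_and_annotate,
    classify_timepoints,
    filter_calls,
    left_align,
    subtract_germline,
)

logger = logging.getLogger(__name__)

_version = "0.1.0"


@dataclass
class PipelineConfig:
    """One serialisable source of truth for a run.

    Precedence when assembled by the CLI: command-line flags > config
    file > these defaults.
    """

    tfbs_bed: str = ""
    germline: str = ""
    diagnosis: str = ""
    relapse: str = ""
    gff: str = ""
    fasta: str = ""
    gene_expression: str = ""
    transcript_expression: str = ""
    out_dir: str = "trascan_out"

    min_vaf: float = 0.20
    min_alt_reads: int = 5
    depth_rule: Literal["alt", "total"] = "alt"
    left_align_indels: bool = False
    min_regulators: int = 5
    window: int = 20_000
    attribution: Literal["position", "region"] = "position"
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    ratio_threshold: float = 2.0
    record_timestamps: bool = False

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise TrascanError(f"unknown config keys: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    """Machine-readable record of a run: version, config echo and
    per-stage record counts with internal consistency asserted."""

    version: str
    config: dict
    counts: dict[str, int] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    timestamps: dict[str, str] = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        for sample in ("diagnosis", "relapse"):
            if c[f"{sample}_filtered"] > c[f"{sample}_read"]:
                raise TrascanError(
                    f"manifest inconsistency: {sample} filtered > read"
                )
        union = c["common"] + c["additional"] + c["lost"]
        if union != c["classified_total"]:
            raise TrascanError(
                "manifest inconsistency: partition does not cover key-union"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "stages_completed": self.stages_completed,
        }
        if self.timestamps:
            payload["timestamps"] = self.timestamps
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Classified-variant / TRA-alteration TSV round trip
# ---------------------------------------------------------------------------

_CLASSIFIED_COLUMNS = (
    "chrom", "pos", "ref", "alt", "vaf", "ref_reads", "alt_reads",
    "status", "variant_class", "consequence", "gene_id", "hgvs_like",
)


def write_classified_tsv(variants: Sequence[ClassifiedVariant], path) -> None:
    rows = sorted(
        variants,
        key=lambda cv: (cv.call.chrom, cv.call.pos, cv.call.ref, cv.call.alt),
    )
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CLASSIFIED_COLUMNS) + "\n")
        for cv in rows:
            v = cv.call
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vaf:.6g}\t"
                f"{v.ref_reads}\t{v.alt_reads}\t{cv.status}\t"
                f"{cv.variant_class}\t{cv.consequence}\t"
                f"{cv.gene_id or ''}\t{cv.hgvs_like or ''}\n"
            )


def read_classified_tsv(path) -> list[ClassifiedVariant]:
    out: list[ClassifiedVariant] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                continue
            call = VariantCall(
                chrom=f[idx["chrom"]], pos=int(f[idx["pos"]]),
                ref=f[idx["ref"]], alt=f[idx["alt"]],
                ref_reads=int(f[idx["ref_reads"]]),
                alt_reads=int(f[idx["alt_reads"]]),
                sample="relapse" if f[idx["status"]] != "lost" else "diagnosis",
            )
            out.append(
                ClassifiedVariant(
                    call=call,
                    status=f[idx["status"]],
                    variant_class=f[idx["variant_class"]],
                    consequence=f[idx["consequence"]],
                    gene_id=f[idx["gene_id"]] or None,
                    hgvs_like=f[idx["hgvs_like"]] or None,
                )
            )
    return out


def write_alterations_tsv(alterations: Sequence[TRAAlteration], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tstatus\tconsequence\t"
            "tra_start\ttra_end\tinvolved_regulators\n"
        )
        rows = sorted(
            alterations,
            key=lambda a: (a.variant.call.chrom, a.variant.call.pos,
                           a.variant.call.ref, a.variant.call.alt),
        )
        for a in rows:
            v = a.variant.call
            regs = ";".join(sorted(a.involved_regulators))
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{a.variant.status}\t"
                f"{a.variant.consequence}\t{a.tra.interval.start}\t"
                f"{a.tra.interval.end}\t{regs}\n"
            )


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def _now() -> str:
    import datetime

    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and write all outputs to
    ``config.out_dir``; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=_version, config=asdict(config))
    stamp = (lambda k: manifest.timestamps.__setitem__(k, _now())) \
        if config.record_timestamps else (lambda k: None)
    stage = manifest.stages_completed.append
    c = manifest.counts
    stamp("start")

    thresholds = FilterThresholds(
        min_vaf=config.min_vaf,
        min_alt_reads=config.min_alt_reads,
        depth_rule=config.depth_rule,
    )

    # --- read & filter -------------------------------------------------
    germline = read_variants(config.germline, "germline")
    diagnosis = read_variants(config.diagnosis, "diagnosis")
    relapse = read_variants(config.relapse, "relapse")
    c["germline_read"] = len(germline)
    c["diagnosis_read"] = len(diagnosis)
    c["relapse_read"] = len(relapse)

    genome = read_genome(config.fasta) if config.fasta else None
    if config.left_align_indels and genome is not None:
        diagnosis = [left_align(v, genome) for v in diagnosis]
        relapse = [left_align(v, genome) for v in relapse]
        germline = [left_align(v, genome) for v in germline]

    dx_f, dx_log = filter_calls(diagnosis, thresholds)
    rl_f, rl_log = filter_calls(relapse, thresholds)
    c["diagnosis_filtered"] = len(dx_f)
    c["relapse_filtered"] = len(rl_f)
    for reason, n in sorted(dx_log.rejected.items()):
        logger.info("diagnosis filter: %d rejected (%s)", n, reason)
    for reason, n in sorted(rl_log.rejected.items()):
        logger.info("relapse filter: %d rejected (%s)", n, reason)
    stage("filter")

    # --- subtract & classify -------------------------------------------
    dx_som = subtract_germline(dx_f, germline)
    rl_som = subtract_germline(rl_f, germline)
    c["diagnosis_somatic"] = len(dx_som)
    c["relapse_somatic"] = len(rl_som)
    stage("subtract")

    partition = classify_timepoints(dx_som, rl_som)
    c["common"] = len(partition.common)
    c["additional"] = len(partition.additional)
    c["lost"] = len(partition.lost)
    stage("classify")

    # --- consequence ----------------------------------------------------
    genes = read_gene_models(config.gff, genome) if config.gff else []
    classified = classify_and_annotate(partition, genes, genome)
    c["classified_total"] = len(classified)
    c["non_synonymous_additional"] = sum(
        1 for cv in classified
        if cv.status == "additional" and cv.consequence in NON_SYNONYMOUS
    )
    write_classified_tsv(classified, out / "classified_variants.tsv")
    stage("consequence")

    # --- TRAs ------------------------------------------------------------
    clusters = read_tfbs_clusters(config.tfbs_bed)
    c["tfbs_clusters_read"] = len(clusters)
    tras = build_tra_regions(clusters, config.min_regulators)
    c["tra_regions"] = len(tras)
    c["tra_coverage_bp"] = total_coverage(tras)
    write_tra_bed(tras, out / "tra_regions.bed")
    stage("build-tra")

    alterations = intersect_variants_tras(
        classified, tras, clusters, attribution=config.attribution
    )
    for a in alterations:  # containment audit
        if not a.tra.interval.contains(a.variant.call.chrom,
                                       a.variant.call.anchor):
            raise TrascanError("TRA alteration anchor outside its region")
    by_status: dict[str, list[TRAAlteration]] = {}
    for a in alterations:
        by_status.setdefault(a.variant.status, []).append(a)
    c["tra_alterations_common"] = len(by_status.get("common", []))
    c["tra_alterations_additional"] = len(by_status.get("additional", []))
    c["tra_alterations_lost"] = len(by_status.get("lost", []))
    write_alterations_tsv(alterations, out / "tra_alterations.tsv")
    stage("intersect")

    # --- proximity genes -------------------------------------------------
    _, per_status_genes = genes_within_window(
        alterations, genes, ProximityConfig(config.window)
    )
    for status in ("common", "additional"):
        gene_set = per_status_genes.get(status, set())
        c[f"proximal_genes_{status}"] = len(gene_set)
        write_gene_set(gene_set, out / f"proximal_genes_{status}.txt")
    stage("proximity")

    # --- involvement ------------------------------------------------------
    table = involvement_table(
        by_status.get("common", []), by_status.get("additional", [])
    )
    c["regulators_in_table"] = len(table)
    write_involvement_tsv(table, out / "involvement.tsv")
    flags = skew_report(table, config.ratio_threshold)
    c["regulators_skewed"] = len(flags)
    with open(out / "skew.tsv", "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator\tratio\treason\tlow_frequency\n")
        for fl in flags:
            ratio = "" if fl.involvement.ratio is None \
                else f"{fl.involvement.ratio:.4f}"
            fh.write(
                f"{fl.involvement.regulator}\t{ratio}\t{fl.reason}\t"
                f"{str(fl.low_frequency).lower()}\n"
            )
    stage("involvement")

    # --- expression integration ------------------------------------------
    if config.gene_expression:
        gene_df = read_expression_table(config.gene_expression)
        ctrl = [col for col in gene_df.columns if col.startswith("ctrl_")]
        cond = [col for col in gene_df.columns if col.startswith("cond_")]
        if ctrl and cond:
            gene_df = compute_fold_change(gene_df, ctrl, cond)
        up, down = de_filter(
            gene_df, config.fc_threshold, config.p_threshold
        )
        c["de_up"] = len(up)
        c["de_down"] = len(down)
        write_gene_set(up, out / "de_up.txt")
        write_gene_set(down, out / "de_down.txt")

        shift: set[str] = set()
        if config.transcript_expression:
            tx_df = read_expression_table(config.transcript_expression)
            shift = transcript_shift_genes(
                tx_df, config.fc_threshold, config.p_threshold,
                DEFAULT_ACCEPTED_CLASSES,
            )
            c["shift_genes"] = len(shift)
            write_gene_set(shift, out / "shift_genes.txt")

        nonsyn_additional = {
            cv.gene_id for cv in classified
            if cv.status == "additional"
            and cv.consequence in NON_SYNONYMOUS and cv.gene_id
        }
        overlap_nonsyn = overlap_sets(
            {
                "nonsyn_additional": nonsyn_additional,
                "de": up | down,
                "shift": shift,
            }
        )
        write_overlap_tsv(overlap_nonsyn, out / "overlap_nonsynonymous.tsv")
        c["overlap_nonsyn_all"] = len(overlap_nonsyn.intersection_all)
        overlap_tra = overlap_sets(
            {
                "tra_proximal_additional":
                    per_status_genes.get("additional", set()),
                "de": up | down,
                "shift": shift,
            }
        )
        write_overlap_tsv(overlap_tra, out / "overlap_tra_proximal.tsv")
        c["overlap_tra_all"] = len(overlap_tra.intersection_all)
        stage("integrate")

    if genome is not None:
        genome.close()

    manifest.check_consistency()
    stamp("end")
    manifest.to_json(out / "manifest.json")
    return manifest
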