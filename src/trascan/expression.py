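"""Expression-table thresholds and gene-set overlap partitions.

Differential-expression calling here is threshold application only:
fold change on the ratio scale with "|FC| >= 2" realised as FC >= 2 or
FC <= 1/2 (equivalently |log2 FC| >= 1), and P < 0.01 strict.  The
statistical engine that produced the p-values is upstream; when
replicate FPKM columns are present a Welch two-sample t-test on
log2(FPKM + pseudocount) is offered as a convenience, otherwise
p-values must arrive in the input table.

Transcript-variant ("shift") genes are genes with at least one
transcript that passes the same thresholds and carries an accepted
structure label (by default reference containment or a junction
match); the structure label is consumed as-is, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from trascan.errors import FormatError, TrascanError

#: transcript structure labels accepted for the shift-gene call
DEFAULT_ACCEPTED_CLASSES: frozenset[str] = frozenset(
    {"containment_of_references", "junction_match"}
)


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene- or transcript-level expression TSV."""
    return pd.read_csv(path, sep="\t")


def compute_fold_change(
    records: pd.DataFrame,
    control_samples: Sequence[str],
    condition_samples: Sequence[str],
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Attach ``fold_change`` (and ``p_value`` when testable) columns.

    fold_change = (mean condition FPKM + pseudocount) /
    (mean control FPKM + pseudocount).  With >= 2 replicates per group
    and no pre-existing ``p_value`` column, a Welch t-test on
    log2(FPKM + pseudocount) supplies p-values.
    """
    for col in (*control_samples, *condition_samples):
        if col not in records.columns:
            raise FormatError(f"sample column {col!r} missing from table")
    out = records.copy()
    ctrl = out[list(control_samples)].to_numpy(dtype=float)
    cond = out[list(condition_samples)].to_numpy(dtype=float)
    out["fold_change"] = (cond.mean(axis=1) + pseudocount) / (
        ctrl.mean(axis=1) + pseudocount
    )
    if "p_value" not in out.columns:
        if len(control_samples) >= 2 and len(condition_samples) >= 2:
            log_ctrl = np.log2(ctrl + pseudocount)
            log_cond = np.log2(cond + pseudocount)
            _, p = stats.ttest_ind(log_cond, log_ctrl, axis=1, equal_var=False)
            out["p_value"] = p
    return out


def de_filter(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    gene_col: str = "gene_id",
) -> tuple[set[str], set[str]]:
    """Split genes into up/down sets at |FC| >= fc_threshold (ratio
    scale, threshold inclusive) and p strictly below p_threshold."""
    if "p_value" not in records.columns or records["p_value"].isna().any():
        missing = (
            records.loc[records["p_value"].isna(), gene_col].tolist()
            if "p_value" in records.columns
            else records[gene_col].tolist()
        )
        raise TrascanError(
            f"p_value missing for {len(missing)} record(s): "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    fc = records["fold_change"].to_numpy(dtype=float)
    p = records["p_value"].to_numpy(dtype=float)
    sig = p < p_threshold
    up = set(records.loc[sig & (fc >= fc_threshold), gene_col])
    down = set(records.loc[sig & (fc <= 1.0 / fc_threshold), gene_col])
    return up, down


def transcript_shift_genes(
    transcript_records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    accepted_classes: Iterable[str] = DEFAULT_ACCEPTED_CLASSES,
    gene_col: str = "gene_id",
    class_col: str = "structure_class",
) -> set[str]:
    """Genes with >= 1 transcript passing the FC/p thresholds AND
    carrying an accepted structure label."""
    accepted = set(accepted_classes)
    fc = transcript_records["fold_change"].to_numpy(dtype=float)
    p = transcript_records["p_value"].to_numpy(dtype=float)
    passes = (
        (p < p_threshold)
        & ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
        & transcript_records[class_col].isin(accepted).to_numpy()
    )
    return set(transcript_records.loc[passes, gene_col])


# ---------------------------------------------------------------------------
# Gene-set overlap (Venn partition)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetOverlap:
    """Exact Venn partition of 2-4 named gene sets.

    Region keys name the sets a region belongs to, joined by ``&`` (a
    member of that region is in exactly those sets); counts over all
    regions sum to the union size.
    """

    set_names: tuple[str, ...]
    region_counts: dict[str, int]
    region_members: dict[str, frozenset[str]]

    @property
    def intersection_all(self) -> frozenset[str]:
        return self.region_members.get("&".join(self.set_names), frozenset())

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def overlap_sets(named_sets: Mapping[str, Iterable[str]]) -> GeneSetOverlap:
    """Partition the union of 2-4 named sets into disjoint Venn regions."""
    names = tuple(named_sets)
    if not (2 <= len(names) <= 4):
        raise TrascanError(
            f"overlap supports 2-4 sets, got {len(names)}"
        )
    sets = {n: frozenset(named_sets[n]) for n in names}
    members: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            members["&".join(combo)] = set()
    for gene in frozenset().union(*sets.values()):
        inside = tuple(n for n in names if gene in sets[n])
        members["&".join(inside)].add(gene)
    frozen = {k: frozenset(v) for k, v in members.items()}
    return GeneSetOverlap(
        set_names=names,
        region_counts={k: len(v) for k, v in frozen.items()},
        region_members=frozen,
    )


def write_overlap_tsv(overlap: GeneSetOverlap, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("region\tcount\tmembers\n")
        for key in overlap.region_counts:
            members = ";".join(sorted(overlap.region_members[key]))
            fh.write(f"{key}\t{overlap.region_counts[key]}\t{members}\n")


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
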