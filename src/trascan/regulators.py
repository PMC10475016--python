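"""Per-regulator involvement of common vs additional TRA alterations.

For each transcription regulator the involvement rate is the
percentage of a status class's TRA alterations whose mutated base
overlaps that regulator's clusters; the involvement ratio is the
additional rate over the common rate.  Ratios are computed on
unrounded rates — rates are rounded only at serialisation — and a
regulator never seen among common alterations is reported as
"additional-exclusive" rather than as a numeric sentinel, sorting
before every finite ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from trascan.tra import TRAAlteration

logger = logging.getLogger(__name__)

Exclusivity = Literal["none", "additional_exclusive", "common_exclusive"]


@dataclass(frozen=True)
class RegulatorInvolvement:
    """One row of the involvement table."""

    regulator: str
    n_common_involved: int
    n_common_total: int
    n_additional_involved: int
    n_additional_total: int

    @property
    def common_rate(self) -> float:
        """Involvement among common alterations, percent (0 when the
        class is empty)."""
        if self.n_common_total == 0:
            return 0.0
        return 100.0 * self.n_common_involved / self.n_common_total

    @property
    def additional_rate(self) -> float:
        if self.n_additional_total == 0:
            return 0.0
        return 100.0 * self.n_additional_involved / self.n_additional_total

    @property
    def ratio(self) -> float | None:
        """additional_rate / common_rate; None (undefined) when the
        regulator is absent from common alterations."""
        if self.common_rate == 0.0:
            return None
        return self.additional_rate / self.common_rate

    @property
    def exclusivity(self) -> Exclusivity:
        if self.common_rate == 0.0 and self.additional_rate > 0.0:
            return "additional_exclusive"
        if self.additional_rate == 0.0 and self.common_rate > 0.0:
            return "common_exclusive"
        return "none"


def involvement_table(
    common_alts: Sequence[TRAAlteration],
    additional_alts: Sequence[TRAAlteration],
) -> list[RegulatorInvolvement]:
    """Count per-regulator involvement and order by ratio.

    Additional-exclusive regulators (undefined ratio, treated as +inf)
    come first; then finite ratios descending; ties break by
    additional rate descending, then name ascending.
    """
    n_common = len(common_alts)
    n_additional = len(additional_alts)
    if n_common == 0 and n_additional == 0:
        logger.warning("no TRA alterations in either class; empty table")
        return []
    regulators: set[str] = set()
    for a in common_alts:
        regulators.update(a.involved_regulators)
    for a in additional_alts:
        regulators.update(a.involved_regulators)

    rows = [
        RegulatorInvolvement(
            regulator=reg,
            n_common_involved=sum(
                1 for a in common_alts if reg in a.involved_regulators
            ),
            n_common_total=n_common,
            n_additional_involved=sum(
                1 for a in additional_alts if reg in a.involved_regulators
            ),
            n_additional_total=n_additional,
        )
        for reg in sorted(regulators)
    ]
    rows.sort(
        key=lambda r: (
            -(r.ratio if r.ratio is not None else math.inf),
            -r.additional_rate,
            r.regulator,
        )
    )
    return rows


@dataclass(frozen=True)
class SkewFlag:
    """A regulator flagged as skewed toward additional alterations."""

    involvement: RegulatorInvolvement
    reason: Literal["ratio", "additional_exclusive"]
    low_frequency: bool


def skew_report(
    table: Sequence[RegulatorInvolvement],
    ratio_threshold: float = 2.0,
    low_frequency_cutoff: float = 5.0,
) -> list[SkewFlag]:
    """Flag regulators involved at least ``ratio_threshold``-fold more in
    additional than in common TRA alterations, plus additional-exclusive
    regulators; exclusives below ``low_frequency_cutoff`` percent carry a
    low-frequency caveat."""
    flags: list[SkewFlag] = []
    for row in table:
        if row.exclusivity == "additional_exclusive":
            flags.append(
                SkewFlag(
                    row, "additional_exclusive",
                    low_frequency=row.additional_rate < low_frequency_cutoff,
                )
            )
        elif row.ratio is not None and row.ratio >= ratio_threshold:
            flags.append(SkewFlag(row, "ratio", low_frequency=False))
    return flags


# ---------------------------------------------------------------------------
# Serialisation & plotting
# ---------------------------------------------------------------------------

def involvement_frame(table: Sequence[RegulatorInvolvement]) -> pd.DataFrame:
    """Tabular form; rates to one decimal, ratio to four, only here at
    the serialisation boundary."""
    return pd.DataFrame(
        {
            "regulator": [r.regulator for r in table],
            "n_common_involved": [r.n_common_involved for r in table],
            "N_common": [r.n_common_total for r in table],
            "common_rate": [round(r.common_rate, 1) for r in table],
            "n_additional_involved": [r.n_additional_involved for r in table],
            "N_additional": [r.n_additional_total for r in table],
            "additional_rate": [round(r.additional_rate, 1) for r in table],
            "ratio": [
                round(r.ratio, 4) if r.ratio is not None else "" for r in table
            ],
            "exclusivity": [r.exclusivity for r in table],
        }
    )


def write_involvement_tsv(
    table: Sequence[RegulatorInvolvement], path
) -> None:
    involvement_frame(table).to_csv(path, sep="\t", index=False, lineterminator="\n")


def plot_involvement(table: Sequence[RegulatorInvolvement], path) -> None:
    """Dual-axis chart: involvement rates as paired bars (common vs
    additional) and the ratio as a point series on the right axis,
    regulators in table (ratio) order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    names = [r.regulator for r in table]
    x = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(names)), 4))
    ax.bar(x - 0.2, [r.common_rate for r in table], width=0.4,
           label="common", color="#4477aa")
    ax.bar(x + 0.2, [r.additional_rate for r in table], width=0.4,
           label="additional", color="#ee7733")
    ax.set_ylabel("involvement rate (%)")
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax2 = ax.twinx()
    finite = [
        (i, r.ratio) for i, r in enumerate(table) if r.ratio is not None
    ]
    if finite:
        ax2.plot(
            [i for i, _ in finite], [v for _, v in finite],
            "o", color="#228833", label="ratio",
        )
    ax2.set_ylabel("involvement ratio (additional / common)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
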