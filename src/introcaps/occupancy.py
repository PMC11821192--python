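"""Nodule occupancy genotyping and competition statistics.

Single root nodules are genotyped by two PCRs — a control amplicon from a
gene present in all rhizobia (*nodE*) and a target amplicon from *nodX*, a
gene carried only by some strains — followed by a restriction digest of the
target amplicon that separates the inoculant's allele (cut) from indigenous
alleles (uncut).  Each nodule yields one categorical call; per-group
occupancy percentages summarise strain competition, and two count
statistics (Kruskal-Wallis, Welch's t on log counts) compare nodulation
between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DigestPattern(str, Enum):
    CUT = "CUT"        # only digested fragments: inoculant-type allele
    UNCUT = "UNCUT"    # intact amplicon only: indigenous-type allele
    BOTH = "BOTH"      # both cut and uncut products: mixed infection
    NA = "NA"          # no target amplicon to digest


class NoduleCall(str, Enum):
    FAILED = "FAILED"              # control PCR failed; nodule not genotyped
    NODX_MINUS = "NODX_MINUS"      # control ok, no target product: nodX- strain
    TOM_ONLY = "TOM_ONLY"          # target cut: inoculant (TOM-type) allele only
    NON_TOM_ONLY = "NON_TOM_ONLY"  # target uncut: indigenous nodX+ allele only
    MIXED = "MIXED"                # both patterns: TOM and non-TOM alleles


#: calls entering occupancy denominators (everything except FAILED)
GENOTYPED_CALLS = (NoduleCall.NODX_MINUS, NoduleCall.TOM_ONLY,
                   NoduleCall.NON_TOM_ONLY, NoduleCall.MIXED)


class MalformedAssayError(ValueError):
    """An assay record violating the band/digest consistency rule."""


@dataclass(frozen=True)
class AssayRecord:
    nodule_id: str
    group: str
    control_band: bool
    target_band: bool
    digest_pattern: DigestPattern


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def call_nodule(assay: AssayRecord) -> NoduleCall:
    """Genotype one nodule from its assay bands and digest pattern.

    No control band -> FAILED; control without target -> NODX_MINUS; a target
    band is classified by its digest pattern (CUT -> TOM_ONLY, UNCUT ->
    NON_TOM_ONLY, BOTH -> MIXED).
    """
    if assay.target_band and assay.digest_pattern is DigestPattern.NA:
        raise MalformedAssayError(
            f"{assay.nodule_id}: target band present but digest pattern is NA")
    if not assay.target_band and assay.digest_pattern is not DigestPattern.NA:
        raise MalformedAssayError(
            f"{assay.nodule_id}: digest pattern recorded without a target band")
    if not assay.control_band:
        return NoduleCall.FAILED
    if not assay.target_band:
        return NoduleCall.NODX_MINUS
    return {DigestPattern.CUT: NoduleCall.TOM_ONLY,
            DigestPattern.UNCUT: NoduleCall.NON_TOM_ONLY,
            DigestPattern.BOTH: NoduleCall.MIXED}[assay.digest_pattern]


@dataclass(frozen=True)
class OccupancyTable:
    """Per-group nodule-call counts and integer percentages.

    ``counts`` has one row per group and one column per call category;
    ``percentages`` shares the layout but covers genotyped (non-FAILED)
    nodules only, rounded half-up to whole percent as they are reported.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame

    @property
    def total_genotyped(self) -> int:
        return int(self.counts[[c.value for c in GENOTYPED_CALLS]].to_numpy().sum())

    def share(self, group: str, call: NoduleCall) -> int:
        return int(self.percentages.loc[group, call.value])

    def to_tsv(self, path: str | Path) -> None:
        merged = self.counts.join(self.percentages, rsuffix="_pct")
        merged.to_csv(path, sep="\t", index_label="group")


def occupancy_table(calls: Iterable[tuple[str, NoduleCall]]) -> OccupancyTable:
    """Aggregate (group, call) pairs into counts and occupancy percentages.

    FAILED nodules are tallied but excluded from percentage denominators.
    Groups with no genotyped nodule are dropped with a warning.
    """
    cols = [c.value for c in NoduleCall]
    df = pd.DataFrame(calls, columns=["group", "call"])
    if df.empty:
        raise ValueError("no calls supplied")
    df["call"] = df["call"].map(lambda c: NoduleCall(c).value)
    counts = (df.groupby(["group", "call"]).size().unstack(fill_value=0)
                .reindex(columns=cols, fill_value=0))
    genotyped = counts[[c.value for c in GENOTYPED_CALLS]]
    denom = genotyped.sum(axis=1)
    empty = denom[denom == 0].index.tolist()
    if empty:
        warnings.warn(f"groups without genotyped nodules excluded: {empty}")
        counts = counts.drop(index=empty)
        genotyped = genotyped.drop(index=empty)
        denom = denom.drop(index=empty)
    pct = genotyped.div(denom, axis=0).mul(100).map(round_half_up).astype(int)
    pct.insert(0, NoduleCall.FAILED.value, 0)
    return OccupancyTable(counts, pct)


def tom_containing_fraction(table: OccupancyTable, group: str) -> int:
    """Percent of genotyped nodules in ``group`` containing the inoculant
    allele, alone or mixed (TOM_ONLY + MIXED)."""
    if group not in table.counts.index:
        raise KeyError(f"group {group!r} not in table")
    row = table.counts.loc[group]
    tom = int(row[NoduleCall.TOM_ONLY.value] + row[NoduleCall.MIXED.value])
    denom = int(sum(row[c.value] for c in GENOTYPED_CALLS))
    return round_half_up(100.0 * tom / denom)


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across two or more samples.

    Returns (H, p) with the usual tie correction and a chi-square reference
    distribution on k-1 degrees of freedom.  If every pooled observation is
    identical the test is degenerate: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least one observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def welch_ln_test(a: Sequence[float], b: Sequence[float],
                  offset: float = 0.0) -> tuple[float, float, float]:
    """Welch's t-test on ln(x + offset) for two count samples.

    Count data are log-transformed toward normality before the unequal-
    variance t-test; ``offset`` (e.g. 1) accommodates zero counts.  Returns
    (t, Welch-Satterthwaite df, two-sided p).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        xa = np.log(np.asarray(a, dtype=float) + offset)
        xb = np.log(np.asarray(b, dtype=float) + offset)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(xb))):
        raise ValueError("values + offset must be positive")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; t undefined")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    sa, sb = va / xa.size, vb / xb.size
    df = (sa + sb) ** 2 / (sa ** 2 / (xa.size - 1) + sb ** 2 / (xb.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read an assay TSV (nodule_id, group, control_band, target_band,
    digest_pattern)."""
    df = pd.read_csv(path, sep="\t", dtype={"nodule_id": str, "group": str},
                     keep_default_na=False)  # 'NA' is a digest pattern, not NaN
    return [AssayRecord(r.nodule_id, r.group, bool(int(r.control_band)),
                        bool(int(r.target_band)), DigestPattern(r.digest_pattern))
            for r in df.itertuples()]


def call_assay_table(records: Iterable[AssayRecord]) -> OccupancyTable:
    """Call every record and aggregate into an occupancy table."""
    return occupancy_table((r.group, call_nodule(r)) for r in records)


def plot_occupancy(table: OccupancyTable, ax=None):
    """Stacked-bar chart of per-group occupancy percentages."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * len(table.percentages), 4))
    bottom = np.zeros(len(table.percentages))
    for call in GENOTYPED_CALLS:
        vals = table.percentages[call.value].to_numpy()
        ax.bar(table.percentages.index, vals, bottom=bottom, label=call.value)
        bottom += vals
    ax.set_ylabel("% of genotyped nodules")
    ax.legend(fontsize=8)
    return ax
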