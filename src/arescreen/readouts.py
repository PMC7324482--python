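"""Functional readouts: dual-luciferase reporters, in-silico ARE
deletion, CFSE proliferation indices, and group-comparison statistics.

The dual-luciferase assay normalises each well's firefly signal (the
reporter of interest) by its co-transfected renilla signal, removing
well-to-well transfection-efficiency variation; condition means are
then expressed relative to a control condition.

CFSE dilution profiles are summarised by precursor-weighted generation
counts: a cell observed in generation i descends from ``N_i / 2**i``
founder "precursors".  The division index averages divisions over all
precursors (undivided included); the proliferation index averages over
precursors that divided at least once, so proliferation index >=
division index whenever both are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from arescreen.are_scan import AREHit, UTRRecord, find_are_sites


def relative_reporter_activity(
    wells: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Per-condition normalised reporter activity relative to a control.

    ``wells`` has columns condition, firefly, renilla (both readings
    strictly positive).  Each well's ratio is firefly/renilla; replicate
    wells are aggregated as the mean of per-well ratios (not the ratio
    of means — the per-well pairing is the point of the dual reporter).
    Relative activity divides each condition's mean ratio by the control
    condition's, so the control is exactly 1.0.

    Returns a DataFrame indexed by condition with columns n_wells,
    mean_ratio, sd_ratio, relative_activity.
    """
    required = {"condition", "firefly", "renilla"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns {sorted(missing)}")
    if (wells["firefly"] <= 0).any() or (wells["renilla"] <= 0).any():
        raise ValueError("firefly and renilla readings must be > 0")
    conditions = wells["condition"].unique()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not present")

    df = wells.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    summary = (
        df.groupby("condition", sort=False)["ratio"]
        .agg(n_wells="size", mean_ratio="mean", sd_ratio="std")
        .fillna({"sd_ratio": 0.0})
    )
    control_mean = summary.loc[control_condition, "mean_ratio"]
    summary["relative_activity"] = summary["mean_ratio"] / control_mean
    return summary


def delete_are_from_utr(
    utr: UTRRecord, hits: Sequence[AREHit], which: int
) -> UTRRecord:
    """Excise the ``which``-th ARE (1-based ordinal) from a UTR.

    Models the deletion-mutant reporter constructs in which one ARE is
    removed from the cloned 3'UTR.  ``hits`` must be the sorted hits for
    this UTR.  If the splice fuses flanking bases into a new motif
    occurrence (so rescanning does not find exactly one fewer hit), a
    warning is emitted.
    """
    if not 1 <= which <= len(hits):
        raise ValueError(
            f"ARE ordinal {which} out of range (UTR has {len(hits)} hit(s))"
        )
    hit = sorted(hits, key=lambda h: h.start)[which - 1]
    if hit.end > utr.length:
        raise ValueError("hit extends beyond UTR bounds")
    new_seq = utr.sequence[: hit.start] + utr.sequence[hit.end :]
    new_rec = UTRRecord(gene_id=f"{utr.gene_id}|delARE{which}", sequence=new_seq)
    n_before = len(find_are_sites(utr.normalized))
    n_after = len(find_are_sites(new_rec.normalized))
    if n_after != n_before - 1:
        warnings.warn(
            f"{utr.gene_id}: deleting ARE {which} left {n_after} motif "
            f"occurrence(s) instead of {n_before - 1}; the splice junction "
            "recreated or destroyed a motif",
            stacklevel=2,
        )
    return new_rec


@dataclass(frozen=True)
class GenerationCounts:
    """Cell counts by completed division number; index 0 is undivided."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("generation counts must be >= 0")
        if sum(self.counts) == 0:
            raise ValueError("all generation counts are zero")


@dataclass(frozen=True)
class ProliferationSummary:
    """Precursor-weighted CFSE summary statistics.

    ``proliferation_index`` is None when no cell divided (the division
    index is then 0 and percent_undivided 100).
    """

    percent_undivided: float
    division_index: float
    proliferation_index: float | None


def proliferation_summary(counts: GenerationCounts | Sequence[int]) -> ProliferationSummary:
    """Division index, proliferation index and percent-undivided.

    With precursor counts ``P_i = N_i / 2**i``:

    - division index = sum(i * P_i) / sum(P_i)  (all precursors)
    - proliferation index = sum_{i>=1}(i * P_i) / sum_{i>=1}(P_i)
    - percent undivided = 100 * N_0 / sum(N_i)  (cell-weighted)
    """
    if not isinstance(counts, GenerationCounts):
        counts = GenerationCounts(tuple(int(c) for c in counts))
    n = np.asarray(counts.counts, dtype=float)
    gens = np.arange(len(n))
    precursors = n / 2.0**gens
    division_index = float(np.sum(gens * precursors) / np.sum(precursors))
    divided = precursors[1:]
    if divided.sum() > 0:
        proliferation_index = float(
            np.sum(gens[1:] * divided) / np.sum(divided)
        )
    else:
        proliferation_index = None
    percent_undivided = float(100.0 * n[0] / n.sum())
    return ProliferationSummary(
        percent_undivided=percent_undivided,
        division_index=division_index,
        proliferation_index=proliferation_index,
    )


@dataclass
class GroupComparison:
    """Result of a named group-comparison test."""

    statistic: float
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None


def group_compare(
    values_by_group: Mapping[str, Sequence[float]] | np.ndarray,
    design: str,
    *,
    welch: bool = False,
) -> GroupComparison:
    """Compare groups with the study's named tests.

    design = "two-group": two-sided Student's t-test, pooled variance by
    default (``welch=True`` for unequal variances).
    design = "multi-group": one-way ANOVA F-test plus a Tukey HSD
    pairwise table.
    design = "categorical": Pearson chi-squared (no continuity
    correction) on a 2x2 count table passed as an array.

    Significance is conventionally read at p < 0.05.
    """
    if design == "categorical":
        table = np.asarray(values_by_group, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("categorical design expects a 2x2 count table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(float(chi2), float(p), "chi2")

    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")

    if design == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group design expects exactly two groups")
        a, b = groups.values()
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison(float(t), float(p), "welch_t" if welch else "student_t")

    if design == "multi-group":
        f, p = stats.f_oneway(*groups.values())
        values = np.concatenate(list(groups.values()))
        labels = np.concatenate(
            [np.repeat(name, len(vals)) for name, vals in groups.items()]
        )
        tukey = pairwise_tukeyhsd(values, labels)
        pairwise = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return GroupComparison(float(f), float(p), "anova_tukey", pairwise)

    raise ValueError(f"unknown design {design!r}")
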