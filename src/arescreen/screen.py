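"""Expression screen for ARE-dependent downregulation.

Given a paired expression table (FPKM in a mock condition versus a
condition forcing expression of an ARE-binding protein) and the set of
ARE-containing genes, the screen

1. classifies genes as up- or downregulated by linear fold change,
2. selects candidate targets that simultaneously satisfy three
   criteria — expressed (FPKM >= 2 in either condition), reduced >= 2-fold
   by the forced expression, and ARE-positive in the 3'UTR — and
3. tests whether ARE-containing genes are enriched among the
   downregulated set with a 2x2 contingency-table statistic.

All thresholds are inclusive (>=).  Fold changes are linear ratios of
pseudocounted FPKMs so zero-abundance genes are handled
deterministically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_COLUMNS = ("gene_id", "fpkm_control", "fpkm_treatment")

#: Keys of the seven exclusive regions of the three-criterion Venn diagram.
VENN_REGIONS = (
    "expressed_only",
    "down_only",
    "are_only",
    "expressed_down",
    "expressed_are",
    "down_are",
    "expressed_down_are",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screen.

    min_fpkm
        Abundance filter: a gene counts as expressed when
        max(control, treatment) >= min_fpkm.  Default 2 FPKM.
    fc_updown
        Fold-change threshold for the up/down classification (default 1.5).
    fc_candidate
        Stricter fold-change threshold for candidate selection (default 2).
    pseudocount
        Added to both FPKM values before taking the ratio (default 0.01).
    """

    min_fpkm: float = 2.0
    fc_updown: float = 1.5
    fc_candidate: float = 2.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.min_fpkm <= 0:
            raise ValueError("min_fpkm must be > 0")
        if self.fc_updown < 1 or self.fc_candidate < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, fpkm_control, fpkm_treatment.

    Lines starting with ``#`` are treated as comments.  Values must be
    finite and non-negative; gene ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.loc[:, list(EXPRESSION_COLUMNS)]
    validate_expression_table(df)
    return df


def validate_expression_table(df: pd.DataFrame) -> None:
    for col in ("fpkm_control", "fpkm_treatment"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite value in column {col}")
        if (vals < 0).any():
            raise ValueError(f"negative FPKM in column {col}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in expression table")


def compute_fold_change(
    fpkm_control: float, fpkm_treatment: float, pseudocount: float = 0.01
) -> tuple[str, float]:
    """Direction and linear magnitude of change between two FPKM values.

    With ``a = fpkm_control + pseudocount`` and
    ``b = fpkm_treatment + pseudocount``: returns ``("down", a/b)`` if
    a > b, ``("up", b/a)`` if b > a, and ``("flat", 1.0)`` if equal.
    The magnitude is always >= 1.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a = fpkm_control + pseudocount
    b = fpkm_treatment + pseudocount
    if a > b:
        return "down", a / b
    if b > a:
        return "up", b / a
    return "flat", 1.0


def fold_change_table(df: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Vectorised per-gene fold-change annotation.

    Adds columns ``direction`` (up/down/flat), ``fold_change``
    (magnitude >= 1) and ``expressed`` (abundance filter flag).
    """
    a = df["fpkm_control"].to_numpy(dtype=float) + config.pseudocount
    b = df["fpkm_treatment"].to_numpy(dtype=float) + config.pseudocount
    out = df.copy()
    direction = np.where(a > b, "down", np.where(b > a, "up", "flat"))
    with np.errstate(divide="ignore", invalid="ignore"):
        magnitude = np.where(a > b, a / b, np.where(b > a, b / a, 1.0))
    out["direction"] = direction
    out["fold_change"] = magnitude
    out["expressed"] = (
        np.maximum(df["fpkm_control"], df["fpkm_treatment"]) >= config.min_fpkm
    )
    return out


def classify_regulation(
    df: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> tuple[set[str], set[str]]:
    """Up/down gene sets at the fc_updown threshold.

    A gene is upregulated (downregulated) iff it passes the abundance
    filter and its fold change is >= ``config.fc_updown`` in that
    direction.  The two sets are disjoint by construction.
    """
    if len(df) == 0:
        raise ValueError("expression table is empty")
    annotated = fold_change_table(df, config)
    passing = annotated["expressed"] & (annotated["fold_change"] >= config.fc_updown)
    up = set(annotated.loc[passing & (annotated["direction"] == "up"), "gene_id"])
    down = set(annotated.loc[passing & (annotated["direction"] == "down"), "gene_id"])
    return up, down


@dataclass
class ScreenResult:
    """Outcome of the three-criterion candidate screen."""

    expressed_set: set[str]
    up_set: set[str]
    down_set: set[str]
    down2fold_set: set[str]
    are_positive_set: set[str]
    candidate_set: set[str]
    venn_counts: dict[str, int]
    table: pd.DataFrame = field(repr=False)

    @property
    def candidates_ordered(self) -> list[str]:
        """Candidate gene ids in input-table order."""
        return [g for g in self.table["gene_id"] if g in self.candidate_set]


def select_candidates(
    df: pd.DataFrame,
    are_positive_set: set[str],
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Apply the three candidate criteria and tabulate the Venn regions.

    Criteria: (1) expressed — max(control, treatment) >= min_fpkm;
    (2) downregulated >= fc_candidate-fold; (3) ARE in the 3'UTR.  The
    candidate set is the triple intersection.  ``venn_counts`` holds the
    seven exclusive regions of the three criterion sets, so the counts
    sum to the size of their union.

    ``are_positive_set`` must be a subset of the table's gene ids.
    """
    if len(df) == 0:
        raise ValueError("expression table is empty")
    universe = set(df["gene_id"])
    unknown = set(are_positive_set) - universe
    if unknown:
        examples = ", ".join(sorted(unknown)[:5])
        raise ValueError(
            f"{len(unknown)} gene(s) in are_positive_set absent from the "
            f"expression table (e.g. {examples})"
        )

    annotated = fold_change_table(df, config)
    up_set, down_set = classify_regulation(df, config)
    expressed = set(annotated.loc[annotated["expressed"], "gene_id"])
    down2 = set(
        annotated.loc[
            (annotated["direction"] == "down")
            & (annotated["fold_change"] >= config.fc_candidate),
            "gene_id",
        ]
    )
    are = set(are_positive_set)
    candidates = expressed & down2 & are

    venn = {
        "expressed_only": len(expressed - down2 - are),
        "down_only": len(down2 - expressed - are),
        "are_only": len(are - expressed - down2),
        "expressed_down": len((expressed & down2) - are),
        "expressed_are": len((expressed & are) - down2),
        "down_are": len((down2 & are) - expressed),
        "expressed_down_are": len(candidates),
    }

    annotated["is_expressed"] = annotated["gene_id"].isin(expressed)
    annotated["is_down_candidate_fc"] = annotated["gene_id"].isin(down2)
    annotated["is_are_positive"] = annotated["gene_id"].isin(are)
    annotated["is_candidate"] = annotated["gene_id"].isin(candidates)

    return ScreenResult(
        expressed_set=expressed,
        up_set=up_set,
        down_set=down_set,
        down2fold_set=down2,
        are_positive_set=are,
        candidate_set=candidates,
        venn_counts=venn,
        table=annotated,
    )


def proportion_percent(k: int, n: int, ndigits: int | None = 1) -> float:
    """Percentage 100*k/n, rounded for reporting (1 decimal by default).

    Pass ``ndigits=None`` for full precision.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * k / n
    return pct if ndigits is None else round(pct, ndigits)


@dataclass
class EnrichmentResult:
    """ARE enrichment in a gene set versus the remaining universe.

    ``table`` is the 2x2 count matrix [[ARE+ in set, ARE- in set],
    [ARE+ in rest, ARE- in rest]]; the odds ratio is (ad)/(bc), flagged
    infinite when a denominator cell is zero.
    """

    table: np.ndarray
    proportion_in_set: float
    proportion_background: float
    chi2: float
    p_value: float
    odds_ratio: float
    method: str

    @property
    def odds_ratio_infinite(self) -> bool:
        return math.isinf(self.odds_ratio)


def are_enrichment(
    in_set: set[str],
    are_positive_set: set[str],
    universe: Iterable[str],
    method: str = "chi2",
) -> EnrichmentResult:
    """Test whether ARE-positive genes are over-represented in a set.

    The 2x2 table partitions the universe into (in-set vs rest) x
    (ARE+ vs ARE-).  ``proportion_in_set`` is the percentage of in-set
    genes that are ARE-positive; ``proportion_background`` is the
    ARE-positive percentage over the whole universe (the figure a screen
    reports as its baseline).  Both are carried at full precision.

    method: ``chi2`` (Pearson, no continuity correction; default),
    ``chi2_yates``, or ``fisher``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not in_set:
        raise ValueError("in_set is empty; enrichment proportion undefined")
    if not in_set <= universe or not are_positive_set <= universe:
        raise ValueError("in_set and are_positive_set must be subsets of universe")

    rest = universe - in_set
    a = len(in_set & are_positive_set)
    b = len(in_set) - a
    c = len(rest & are_positive_set)
    d = len(rest) - c
    table = np.array([[a, b], [c, d]], dtype=int)

    if method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif method == "chi2_yates":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    elif method == "fisher":
        _, p = stats.fisher_exact(table)
        chi2 = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")

    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)

    n_are_universe = len(are_positive_set & universe)
    return EnrichmentResult(
        table=table,
        proportion_in_set=100.0 * a / len(in_set),
        proportion_background=100.0 * n_are_universe / len(universe),
        chi2=float(chi2),
        p_value=float(p),
        odds_ratio=float(odds),
        method=method,
    )


def read_gene_set(path: str | Path) -> list[str]:
    """Read a one-id-per-line gene set, preserving order, dropping blanks."""
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    if not ids:
        warnings.warn(f"gene set file {path} is empty", stacklevel=2)
    return ids


def filter_by_gene_set(
    candidates_ordered: Sequence[str], gene_set: Iterable[str]
) -> list[str]:
    """Intersect candidates with a user gene set, preserving candidate order.

    Matching is case-sensitive on gene ids.
    """
    keep = set(gene_set)
    return [g for g in candidates_ordered if g in keep]
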