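"""End-to-end orchestration: scan -> screen -> enrichment -> report.

Runs the motif scan on a UTR FASTA, reconciles its gene ids with the
expression table, applies the three-criterion candidate screen and the
ARE-enrichment test over downregulated genes, and writes a BED of motif
sites, a per-gene TSV, a JSON summary with stable key order, and a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import arescreen
from arescreen.are_scan import DEFAULT_MOTIF, read_utr_fasta, scan_utr_set, write_hits_bed
from arescreen.screen import (
    EnrichmentResult,
    ScreenConfig,
    ScreenResult,
    are_enrichment,
    read_expression_table,
    select_candidates,
)

logger = logging.getLogger("arescreen.pipeline")

#: Fraction of non-overlapping gene ids above which the run aborts
#: (almost certainly mismatched id namespaces).
MAX_NONOVERLAP = 0.5


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


class ValidationError(PipelineError):
    """Input reconciliation failed."""


@dataclass
class ReconciliationReport:
    """Genes present in only one of the two inputs."""

    n_fasta: int
    n_expression: int
    missing_utr: set[str]
    missing_expression: set[str]

    @property
    def nonoverlap_fraction(self) -> float:
        union = self.n_fasta + len(self.missing_utr)
        if union == 0:
            return 1.0
        return (len(self.missing_utr) + len(self.missing_expression)) / max(
            union, self.n_expression
        )


def validate_inputs(
    fasta_path: str | Path, expression_path: str | Path
) -> ReconciliationReport:
    """Reconcile gene ids between the UTR FASTA and the expression table.

    Default downstream policy: genes with expression but no UTR are
    treated as ARE-negative; genes with a UTR but no expression are
    dropped from the universe.  If more than half the ids fail to
    overlap the run is refused.
    """
    fasta_ids = {rec.gene_id for rec in read_utr_fasta(fasta_path)}
    expr_ids = set(read_expression_table(expression_path)["gene_id"])
    report = ReconciliationReport(
        n_fasta=len(fasta_ids),
        n_expression=len(expr_ids),
        missing_utr=expr_ids - fasta_ids,
        missing_expression=fasta_ids - expr_ids,
    )
    overlap = len(fasta_ids & expr_ids)
    denom = max(len(fasta_ids | expr_ids), 1)
    if 1 - overlap / denom > MAX_NONOVERLAP:
        examples = sorted(report.missing_utr | report.missing_expression)[:5]
        raise ValidationError(
            f"validate: {denom - overlap}/{denom} gene ids do not overlap "
            f"between FASTA and expression table (e.g. {examples}); "
            "likely mismatched id namespaces"
        )
    return report


@dataclass
class PipelineResult:
    screen: ScreenResult
    enrichment: EnrichmentResult
    reconciliation: ReconciliationReport
    manifest: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_screen_pipeline(
    fasta_path: str | Path,
    expression_path: str | Path,
    config: ScreenConfig = ScreenConfig(),
    out_dir: str | Path | None = None,
    *,
    motif: str = DEFAULT_MOTIF,
    drop_missing_utr: bool = False,
) -> PipelineResult:
    """Run scan, screen and enrichment over one input pair.

    With ``drop_missing_utr`` genes lacking a UTR are removed from the
    universe instead of being counted ARE-negative.  When ``out_dir`` is
    given, writes are_sites.bed, per_gene.tsv, summary.json and
    manifest.json there.
    """
    report = validate_inputs(fasta_path, expression_path)
    logger.info(
        "validate: %d genes without UTR, %d without expression",
        len(report.missing_utr),
        len(report.missing_expression),
    )

    try:
        records = read_utr_fasta(fasta_path)
        hits, are_positive = scan_utr_set(records, motif)
    except Exception as exc:  # pragma: no cover - re-raise with stage name
        raise PipelineError(f"scan: {exc}") from exc

    expr = read_expression_table(expression_path)
    if len(expr) == 0:
        raise PipelineError("screen: empty table")
    if drop_missing_utr:
        expr = expr[~expr["gene_id"].isin(report.missing_utr)].reset_index(drop=True)
    universe = set(expr["gene_id"])
    are_in_universe = are_positive & universe

    try:
        screen = select_candidates(expr, are_in_universe, config)
        enrichment = are_enrichment(screen.down_set, are_in_universe, universe)
    except Exception as exc:
        raise PipelineError(f"screen: {exc}") from exc

    summary = {
        "n_genes": len(universe),
        "n_are_positive": len(are_in_universe),
        "n_expressed": len(screen.expressed_set),
        "n_up": len(screen.up_set),
        "n_down": len(screen.down_set),
        "n_down_candidate_fc": len(screen.down2fold_set),
        "n_candidates": len(screen.candidate_set),
        "candidates": screen.candidates_ordered,
        "venn_counts": screen.venn_counts,
        "enrichment": {
            "table": enrichment.table.tolist(),
            "proportion_in_set_pct": round(enrichment.proportion_in_set, 1),
            "proportion_background_pct": round(enrichment.proportion_background, 1),
            "chi2": enrichment.chi2,
            "p_value": enrichment.p_value,
            "odds_ratio": enrichment.odds_ratio,
            "method": enrichment.method,
        },
        "config": {
            "min_fpkm": config.min_fpkm,
            "fc_updown": config.fc_updown,
            "fc_candidate": config.fc_candidate,
            "pseudocount": config.pseudocount,
            "motif": motif,
        },
        "reconciliation": {
            "n_missing_utr": len(report.missing_utr),
            "n_missing_expression": len(report.missing_expression),
            "policy": "drop" if drop_missing_utr else "are_negative",
        },
    }

    manifest = {
        "tool": "arescreen",
        "version": arescreen.__version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "fasta": {"path": str(fasta_path), "sha256": _sha256(fasta_path)},
            "expression": {
                "path": str(expression_path),
                "sha256": _sha256(expression_path),
            },
        },
        "config": summary["config"],
        "stage_counts": {
            "scan_records": len(records),
            "scan_hits": sum(len(v) for v in hits.values()),
            "screen_genes": len(universe),
            "candidates": len(screen.candidate_set),
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hits_bed(hits, out / "are_sites.bed", motif)
        screen.table.to_csv(out / "per_gene.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        screen=screen,
        enrichment=enrichment,
        reconciliation=report,
        manifest=manifest,
        summary=summary,
    )
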