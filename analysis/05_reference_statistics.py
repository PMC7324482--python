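"""Verify the pipeline's statistics against the published screen values.

Feeds the published contingency counts through the enrichment routines
and scans the three published Ikzf2 ARE probe sequences; writes
results/reference_statistics.json.
"""

import json
from pathlib import Path

from arescreen.are_scan import UTRRecord, scan_utr_set
from arescreen.datasets import IKZF2_ARE_PROBES, SCREEN_REFERENCE_COUNTS
from arescreen.screen import are_enrichment, proportion_percent

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    c = SCREEN_REFERENCE_COUNTS
    universe = [f"g{i}" for i in range(c["n_detected"])]
    down = set(universe[: c["n_down"]])
    n_rest_are = c["n_detected_are"] - c["n_down_are"]
    are = set(universe[: c["n_down_are"]]) | set(
        universe[c["n_down"] : c["n_down"] + n_rest_are]
    )
    enr = are_enrichment(down, are, set(universe))

    records = [UTRRecord(gene_id=k, sequence=v) for k, v in IKZF2_ARE_PROBES.items()]
    hits, positive = scan_utr_set(records)

    payload = {
        "are_pct_detected": proportion_percent(c["n_detected_are"], c["n_detected"]),
        "are_pct_downregulated": proportion_percent(c["n_down_are"], c["n_down"]),
        "chi2": enr.chi2,
        "p_value": enr.p_value,
        "odds_ratio": enr.odds_ratio,
        "probe_hits": {name: len(hits[name]) for name in positive},
    }
    print(
        f"ARE-containing genes: {payload['are_pct_detected']}% of detected, "
        f"{payload['are_pct_downregulated']}% of downregulated"
    )
    print(
        f"enrichment: chi2 = {enr.chi2:.1f}, p = {enr.p_value:.2e}, "
        f"odds ratio = {enr.odds_ratio:.2f}"
    )
    print(f"probe scan: {sum(payload['probe_hits'].values())} AREs across "
          f"{len(positive)} probes")
    (ROOT / "reference_statistics.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )


if __name__ == "__main__":
    main()
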