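"""Functional readouts: reporter activity, ARE deletions, CFSE indices.

Normalises the simulated dual-luciferase wells, builds the three
single-ARE deletion constructs of a model 3'UTR in silico, and reduces
the CFSE generation counts to division/proliferation indices; writes
results/readouts.json.
"""

import json
from pathlib import Path

import pandas as pd

from arescreen.are_scan import UTRRecord, scan_utr_set
from arescreen.datasets import IKZF2_ARE_PROBES
from arescreen.readouts import (
    delete_are_from_utr,
    proliferation_summary,
    relative_reporter_activity,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    payload = {}

    wells = pd.read_csv(ROOT / "synthetic" / "reporter.tsv", sep="\t", comment="#")
    summary = relative_reporter_activity(wells, "utr_emp")
    payload["reporter"] = summary["relative_activity"].round(3).to_dict()
    print("relative reporter activity (vs empty effector):")
    for condition, value in payload["reporter"].items():
        print(f"  {condition}: {value:.3f}")

    # model 3'UTR carrying three AREs: the probe regions joined in order
    utr = UTRRecord(gene_id="model_utr", sequence="".join(IKZF2_ARE_PROBES.values()))
    hits = scan_utr_set([utr])[0][utr.gene_id]
    print(f"model UTR: {len(hits)} AREs at {[(h.start, h.end) for h in hits]}")
    payload["deletion_constructs"] = {}
    for ordinal in range(1, len(hits) + 1):
        mutant = delete_are_from_utr(utr, hits, ordinal)
        remaining = len(scan_utr_set([mutant])[0].get(mutant.gene_id, []))
        payload["deletion_constructs"][f"del_are{ordinal}"] = {
            "length": mutant.length,
            "remaining_ares": remaining,
        }
        print(f"  del ARE{ordinal}: {mutant.length} nt, {remaining} AREs remain")

    cfse = pd.read_csv(ROOT / "synthetic" / "cfse.tsv", sep="\t", comment="#")
    payload["cfse"] = {}
    print("CFSE summaries:")
    for sample, grp in cfse.groupby("sample"):
        counts = grp.sort_values("generation")["count"].tolist()
        s = proliferation_summary(counts)
        payload["cfse"][str(sample)] = {
            "percent_undivided": round(s.percent_undivided, 2),
            "division_index": round(s.division_index, 3),
            "proliferation_index": (
                round(s.proliferation_index, 3) if s.proliferation_index else None
            ),
        }
        print(
            f"  {sample}: division index {s.division_index:.2f}, "
            f"{s.percent_undivided:.1f}% undivided"
        )

    (ROOT / "readouts.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
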