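"""Generate the synthetic input bundle every later step consumes.

Writes 3'UTR FASTA, paired expression TSV, decay chases, CFSE counts,
reporter wells and the planted ground truth to results/synthetic/.
"""

from pathlib import Path

from arescreen.simulate import SimulationConfig, simulate_all

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    config = SimulationConfig(seed=1)
    truth = simulate_all(config, OUT)
    print(f"wrote synthetic bundle to {OUT}")
    print(
        f"  {config.n_genes} genes, {len(truth.are_genes)} ARE-positive "
        f"({100 * len(truth.are_genes) / config.n_genes:.1f}%), "
        f"{len(truth.planted_targets)} planted knockdown targets"
    )


if __name__ == "__main__":
    main()
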