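"""Synthetic data with the statistical structure the screen assumes.

Every generator is seeded and deterministic: the same
:class:`SimulationConfig` produces byte-identical outputs.  The planted
ground truth (which genes carry an ARE, which were knocked down and by
how much, the true half-lives) is recorded so recovery tests can score
the analysis against it.

What is emulated
----------------
- a gene universe in which a configurable fraction of 3'UTRs (default
  17.5%) carries the ARE heptamer; ARE-negative backgrounds are
  rejection-sampled so base composition matches ARE-positive ones,
- a treatment that knocks down a subset of ARE-carrying genes
  (treatment FPKM = factor x control, factor uniform in a configured
  range) while all other genes fluctuate with multiplicative lognormal
  noise,
- exponential decay courses at stated half-lives with multiplicative
  noise,
- dual-luciferase wells with configured relative activities, and
- CFSE generation counts from a branching model in which every cell
  divides each round with a condition-specific probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from arescreen.are_scan import DEFAULT_MOTIF, UTRRecord, find_are_sites
from arescreen.decay import DecayCourse

_BASES = np.array(list("ACGT"))

# Fixed stream codes so each generator draws from an independent,
# order-insensitive substream of the config seed.
_STREAMS = {
    "flags": 1,
    "utr": 2,
    "expression": 3,
    "decay": 4,
    "cfse": 5,
    "reporter": 6,
}


@dataclass
class SimulationConfig:
    """All generator parameters in one block.

    Defaults mirror the study conditions the analysis is designed for:
    17.5% of 3'UTRs carry the ARE heptamer; half-lives of 3.01 h (mock)
    and 0.33 h (forced ARE-binding-protein expression); three-replicate
    chase courses on a 0-4 h grid with 5% multiplicative noise.
    Parameters without a stated counterpart (effect sizes, noise CVs,
    division probabilities) are declared here once.
    """

    seed: int
    n_genes: int = 1000
    p_are: float = 0.175
    utr_length_range: tuple[int, int] = (50, 300)
    p_target_given_are: float = 0.3
    knockdown_factor_range: tuple[float, float] = (0.1, 0.5)
    baseline_log2_fpkm_mean: float = 3.0
    baseline_log2_fpkm_sd: float = 2.0
    offtarget_noise_cv: float = 0.2
    decay_t_half_by_condition: dict[str, float] = field(
        default_factory=lambda: {"mock": 3.01, "zfp36l2": 0.33}
    )
    decay_times_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    decay_n_replicates: int = 3
    decay_noise_cv: float = 0.05
    cfse_p_divide_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "tresp_alone": 0.7,
            "tresp_mock_itreg": 0.3,
            "tresp_zfp36l2_itreg": 0.55,
        }
    )
    cfse_rounds: int = 6
    reporter_relative_activity: dict[str, float] = field(
        default_factory=lambda: {
            "utr_emp": 1.0,
            "utr_l1": 0.95,
            "utr_l2": 0.45,
            "del_are1_l2": 0.50,
            "del_are2_l2": 0.55,
            "del_are3_l2": 0.90,
        }
    )
    reporter_control_condition: str = "utr_emp"
    reporter_noise_cv: float = 0.10
    reporter_n_wells: int = 3
    motif: str = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        for name, p in (("p_are", self.p_are), ("p_target_given_are", self.p_target_given_are)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.cfse_p_divide_by_condition.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("division probabilities must be in [0, 1]")
        lo, hi = self.utr_length_range
        if lo > hi:
            raise ValueError("utr_length_range must be ordered")
        if lo < len(self.motif):
            raise ValueError("UTRs must be at least as long as the motif")
        flo, fhi = self.knockdown_factor_range
        if not (0 < flo <= fhi):
            raise ValueError("knockdown_factor_range must be ordered and positive")
        if self.n_genes < 1 or self.cfse_rounds < 1 or self.decay_n_replicates < 1:
            raise ValueError("counts must be >= 1")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class GroundTruth:
    """Planted truth behind a simulated dataset.

    ``true_factor`` maps every gene to the multiplier that produced its
    treatment FPKM from its control FPKM, so the expression table is
    exactly reproducible from the truth; ``planted_targets`` is the
    subset of ARE-positive genes given a deliberate knockdown.
    """

    are_genes: set[str] = field(default_factory=set)
    planted_targets: set[str] = field(default_factory=set)
    true_factor: dict[str, float] = field(default_factory=dict)
    control_fpkm: dict[str, float] = field(default_factory=dict)
    half_life_by_condition: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "are_genes": sorted(self.are_genes),
            "planted_targets": sorted(self.planted_targets),
            "true_factor": dict(sorted(self.true_factor.items())),
            "control_fpkm": dict(sorted(self.control_fpkm.items())),
            "half_life_by_condition": self.half_life_by_condition,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_gene_universe(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Gene ids and Bernoulli(p_are) ARE flags, without sequences.

    The flags drawn here are the ones :func:`simulate_utr_sequences`
    realises as sequences, so screens that only need ARE labels can skip
    sequence generation and still agree with the FASTA route.
    """
    ids = _gene_ids(config.n_genes)
    flags = _rng(config, "flags").random(config.n_genes) < config.p_are
    return ids, flags


def simulate_utr_sequences(
    config: SimulationConfig,
) -> tuple[list[UTRRecord], GroundTruth]:
    """Random 3'UTRs with the ARE planted in flagged genes only.

    ARE-positive genes get the motif written at a uniform-random offset
    in a uniform-random background; ARE-negative genes are
    rejection-sampled until the background contains no motif occurrence,
    so base composition matches and the scanner agrees exactly with the
    planted flags.
    """
    ids, flags = simulate_gene_universe(config)
    rng = _rng(config, "utr")
    lo, hi = config.utr_length_range
    motif = config.motif
    records: list[UTRRecord] = []
    for gene_id, is_are in zip(ids, flags):
        length = int(rng.integers(lo, hi + 1))
        if is_are:
            seq = "".join(rng.choice(_BASES, size=length))
            offset = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:offset] + motif + seq[offset + len(motif):]
        else:
            while True:
                seq = "".join(rng.choice(_BASES, size=length))
                if not find_are_sites(seq, motif):
                    break
        records.append(UTRRecord(gene_id=gene_id, sequence=seq))
    truth = GroundTruth(
        are_genes={g for g, f in zip(ids, flags) if f},
        half_life_by_condition=dict(config.decay_t_half_by_condition),
    )
    return records, truth


def simulate_screen_expression(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Paired control/treatment FPKM table with planted knockdown.

    Control FPKM is 2**x with x ~ Normal(baseline mean, sd).  Each
    ARE-positive gene becomes a planted target with probability
    p_target_given_are; a target's treatment value is factor x control
    with factor ~ Uniform(knockdown_factor_range).  Every other gene's
    treatment value is control x a multiplicative lognormal fluctuation
    with CV ``offtarget_noise_cv`` (unit mean).  The realised factor of
    every gene is recorded in the truth, so
    ``treatment == true_factor * control`` holds exactly.
    """
    ids, _ = simulate_gene_universe(config)
    rng = _rng(config, "expression")
    n = len(ids)
    control = np.power(
        2.0,
        rng.normal(config.baseline_log2_fpkm_mean, config.baseline_log2_fpkm_sd, n),
    )
    cv = config.offtarget_noise_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    flo, fhi = config.knockdown_factor_range
    knockdown = rng.uniform(flo, fhi, size=n)
    is_target = np.array(
        [
            gene in truth.are_genes and u < config.p_target_given_are
            for gene, u in zip(ids, rng.random(n))
        ]
    )
    factor = np.where(is_target, knockdown, noise)
    treatment = control * factor

    df = pd.DataFrame(
        {"gene_id": ids, "fpkm_control": control, "fpkm_treatment": treatment}
    )
    truth.planted_targets = {g for g, t in zip(ids, is_target) if t}
    truth.true_factor = dict(zip(ids, factor.tolist()))
    truth.control_fpkm = dict(zip(ids, control.tolist()))
    return df, truth


def simulate_decay_course(
    config: SimulationConfig, condition: str, *, offset: int = 0
) -> DecayCourse:
    """Exponential decay course for one condition.

    values = 100 * exp(-ln2 * t / t_half) * lognormal noise (unit mean,
    CV ``decay_noise_cv``), including the t=0 point.  ``offset``
    decorrelates repeated draws for the same condition (e.g. replicate
    experiments) under one config.
    """
    if condition not in config.decay_t_half_by_condition:
        raise ValueError(f"unknown decay condition {condition!r}")
    t_half = config.decay_t_half_by_condition[condition]
    cond_code = sorted(config.decay_t_half_by_condition).index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(_STREAMS["decay"], cond_code, offset)
        )
    )
    times = np.asarray(config.decay_times_h, dtype=float)
    cv = config.decay_noise_cv
    rows = []
    for rep in range(1, config.decay_n_replicates + 1):
        clean = 100.0 * np.exp(-math.log(2.0) * times / t_half)
        if cv > 0:
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            vals = clean * rng.lognormal(-sigma * sigma / 2.0, sigma, len(times))
        else:
            vals = clean
        for t, v in zip(times, vals):
            rows.append((condition, rep, t, v))
    data = pd.DataFrame(rows, columns=["condition", "replicate", "time_h", "value"])
    return DecayCourse(condition=condition, data=data.drop(columns="condition"))


def simulate_cfse(
    config: SimulationConfig, condition: str, n_cells: int
) -> np.ndarray:
    """Generation counts from a seeded branching division model.

    Starting from ``n_cells`` undivided founders, every cell divides in
    each of ``cfse_rounds`` rounds with the condition's probability,
    producing two daughters in the next generation.  Under this model
    the precursor-weighted generation distribution is exactly
    Binomial(rounds, p), so the expected division index is rounds * p.
    """
    if condition not in config.cfse_p_divide_by_condition:
        raise ValueError(f"unknown CFSE condition {condition!r}")
    p = config.cfse_p_divide_by_condition[condition]
    cond_code = sorted(config.cfse_p_divide_by_condition).index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS["cfse"], cond_code))
    )
    counts = np.zeros(config.cfse_rounds + 1, dtype=np.int64)
    counts[0] = n_cells
    for _ in range(config.cfse_rounds):
        divided = rng.binomial(counts, p)
        new = counts - divided
        new[1:] += 2 * divided[:-1]
        # cells already at the terminal generation cannot divide further
        new[-1] += divided[-1]
        counts = new
    return counts


def expected_division_index(p: float, rounds: int) -> float:
    """Analytic division index under the branching model, by exhaustive
    enumeration over per-round division outcomes (Binomial(rounds, p))."""
    from scipy.stats import binom

    gens = np.arange(rounds + 1)
    pmf = binom.pmf(gens, rounds, p)
    return float(np.sum(gens * pmf))


def simulate_reporter_wells(config: SimulationConfig) -> pd.DataFrame:
    """Dual-luciferase wells at configured relative activities.

    Each well draws a transfection-efficiency scale shared by both
    luciferases (so the firefly/renilla ratio cancels it) plus
    independent lognormal measurement noise at ``reporter_noise_cv``.
    """
    rng = _rng(config, "reporter")
    cv = config.reporter_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    rows = []
    for condition, rel in config.reporter_relative_activity.items():
        for _ in range(config.reporter_n_wells):
            efficiency = rng.lognormal(0.0, 0.5)
            renilla = 1e5 * efficiency
            firefly = 2e5 * rel * efficiency
            if sigma > 0:
                firefly *= rng.lognormal(-sigma * sigma / 2.0, sigma)
                renilla *= rng.lognormal(-sigma * sigma / 2.0, sigma)
            rows.append((condition, firefly, renilla))
    return pd.DataFrame(rows, columns=["condition", "firefly", "renilla"])


def _provenance_line(config: SimulationConfig) -> str:
    return "# arescreen simulate config: " + json.dumps(asdict(config), sort_keys=True)


def simulate_all(
    config: SimulationConfig, out_dir: str | Path, *, cfse_n_cells: int = 5000
) -> GroundTruth:
    """Write the full synthetic bundle to a directory.

    Produces utrs.fasta, expression.tsv, decay.tsv, cfse.tsv,
    reporter.tsv and truth.json.  Each TSV starts with a provenance
    comment echoing the full config; readers in this package skip
    ``#`` lines.  Identical configs yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance_line(config)

    records, truth = simulate_utr_sequences(config)
    with open(out / "utrs.fasta", "w") as fa:
        for rec in records:
            fa.write(f">{rec.gene_id}\n{rec.sequence}\n")

    expr, truth = simulate_screen_expression(config, truth)
    with open(out / "expression.tsv", "w") as fh:
        fh.write(header + "\n")
        expr.to_csv(fh, sep="\t", index=False)

    decay_rows = []
    for condition in sorted(config.decay_t_half_by_condition):
        course = simulate_decay_course(config, condition)
        block = course.data.copy()
        block.insert(0, "condition", condition)
        decay_rows.append(block)
    with open(out / "decay.tsv", "w") as fh:
        fh.write(header + "\n")
        pd.concat(decay_rows).to_csv(fh, sep="\t", index=False)

    cfse_rows = []
    for condition in sorted(config.cfse_p_divide_by_condition):
        counts = simulate_cfse(config, condition, cfse_n_cells)
        for gen, count in enumerate(counts):
            cfse_rows.append((condition, gen, int(count)))
    with open(out / "cfse.tsv", "w") as fh:
        fh.write(header + "\n")
        pd.DataFrame(cfse_rows, columns=["sample", "generation", "count"]).to_csv(
            fh, sep="\t", index=False
        )

    with open(out / "reporter.tsv", "w") as fh:
        fh.write(header + "\n")
        simulate_reporter_wells(config).to_csv(fh, sep="\t", index=False)

    truth.to_json(out / "truth.json")
    return truth


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping of field names."""
    import yaml

    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("utr_length_range", "knockdown_factor_range", "decay_times_h"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
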