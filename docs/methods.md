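# Methods

## ARE definition and scanning

The AU-rich element is operationalised as the literal heptamer
`TATTTAT` (`UAUUUAU` on the RNA strand) — the minimal high-affinity
site of ZFP36-family tandem zinc fingers. Scanning is exact substring
search over sequences normalised to upper-case DNA (U→T), sense strand
only (3′UTRs are already oriented), reporting every occurrence
including overlaps in 0-based half-open coordinates. Downstream, only
presence/absence per gene matters, so overlap handling cannot change
screen outcomes; hits are still reported losslessly for construct
design. `N` and other ambiguity codes never match in literal mode. An
optional IUPAC-degenerate mode exists for exploratory motifs but is off
by default, since the screen is defined on the literal heptamer.

## Expression screen

Inputs are paired FPKM values (mock control vs forced expression of the
RNA-binding protein). Choices that the screen's published description
leaves open are resolved as follows and exposed as `ScreenConfig`
fields:

- **Abundance filter** — "expressed" means max(control, treatment)
  ≥ 2 FPKM (logical OR over the two conditions).
- **Fold change** — linear ratio of pseudocounted values,
  (x + 0.01)/(y + 0.01). The pseudocount makes zero-FPKM genes
  well-defined and deterministic; it also means a gene whose raw ratio
  is exactly at a threshold can fall marginally below it (3.0/2.0 →
  1.4975 < 1.5). We accept this: the contract is the pseudocounted
  ratio, and thresholds are inclusive (≥) on that ratio.
- **Candidate selection** — the triple intersection expressed ∩
  (≥2-fold down) ∩ ARE⁺; selection is threshold-based, not p-value
  based, so no multiple-testing procedure applies.
- **Enrichment** — the universe of detected genes is partitioned
  (in-set vs rest) × (ARE⁺ vs ARE⁻) and tested with Pearson's χ²
  without continuity correction; Yates and Fisher's exact are options
  because small synthetic tables can violate expected-count rules. The
  background proportion is reported over the whole universe (the
  screen's natural baseline figure). Odds ratio is (ad)/(bc), flagged
  infinite when a denominator cell is zero.

## Decay model

Transcription-chase courses are normalised per replicate to the t = 0
measurement (≡ 100%), then fitted with the one-phase exponential
Y(t) = y₀·e^(−kt), plateau fixed at 0; t₁/₂ = ln 2/k. Numerical
choices:

- untransformed least squares over all pooled replicate points
  (the standard behaviour of one-phase-decay fitting in common curve
  fitting software), initialised from a log-linear regression of
  ln Y on t;
- y₀ is estimated by default — normalisation pins only the measured
  baseline, not the curve's intercept; `fix_y0` pins it at 100 for the
  stricter reading. A free plateau is available but off by default;
- fitted rates below 10⁻⁶ h⁻¹ are flagged non-decaying (half-life
  reported as infinite) rather than returned as absurdly long
  half-lives, since least squares on flat data can land at k = ±ε;
- uncertainty is a seeded bootstrap (default 1,000 resamples):
  replicates are resampled with replacement when there are several,
  residuals otherwise. Condition comparison reports the half-life
  ratio, a bootstrap percentile CI from independently resampled pairs,
  and a two-sided t-test on per-replicate log half-lives when every
  replicate supports its own fit (falling back to the bootstrap null
  otherwise).

## Reporter and proliferation readouts

Reporter wells are aggregated as the **mean of per-well
firefly/renilla ratios**, not the ratio of means — per-well pairing is
what the dual-reporter design buys. Relative activity divides by the
control condition's mean ratio.

CFSE generation counts are reduced with the precursor convention
Pᵢ = Nᵢ/2ⁱ. Two related indices exist in the field and we report both:
the **division index** Σi·Pᵢ/ΣPᵢ (mean divisions per founder,
undivided founders included) and the **proliferation index**
Σ_{i≥1}i·Pᵢ/Σ_{i≥1}Pᵢ (mean divisions among founders that divided),
together with the cell-weighted percent-undivided. Division index ≤
proliferation index whenever the latter is defined.

Group comparisons follow the conventional analysis of such experiments:
Student's t (pooled variance; Welch optional) for two numeric groups,
one-way ANOVA with Tukey HSD for more, Pearson χ² for 2×2 categorical
tables, significance read at p < 0.05.

In-silico ARE deletion removes one hit's span from the UTR; the product
is rescanned and a warning is raised if the splice junction recreated a
motif (possible when the flanks of the deleted site fuse into
`TATTTAT`).

## Synthetic data generator

The generator emulates the study conditions stage by stage, with every
parameter in one `SimulationConfig` block and full ground-truth
bookkeeping:

- **UTRs** — 1,000 genes by default, lengths uniform on 50–300 nt; each
  gene is ARE⁺ with probability 0.175 (the ARE frequency observed among
  detected genes). ARE⁺ genes get the heptamer planted at a uniform
  offset in a uniform random background; ARE⁻ genes are
  rejection-sampled to contain no occurrence, so base composition
  matches the ARE⁺ group and the scanner agrees exactly with the
  planted flags.
- **Expression** — control FPKM = 2^x, x ~ N(3, 2²), spanning silent to
  highly expressed genes. Each ARE⁺ gene is a planted target with
  probability 0.3; a target's treatment value is factor × control with
  factor ~ U(0.1, 0.5) (2–10-fold knockdown, bracketing the screen's
  2-fold criterion). Every other gene's treatment value fluctuates by a
  unit-mean lognormal factor with CV 0.2, a typical between-library
  spread for bulk RNA-seq fold changes of unaffected genes. The
  realised factor of every gene is recorded, so treatment =
  factor × control holds exactly and recovery tests have an exact
  answer key.
- **Decay** — half-lives 3.01 h (mock) and 0.33 h (forced expression),
  the values measured for the motivating transcript; grid
  {0, 0.5, 1, 2, 4} h, three replicates, multiplicative lognormal noise
  CV 5%, matching tight technical qPCR replicates.
- **Reporter** — wells at configured relative activities (destabiliser
  ≈ 0.45× control; single-ARE deletions partially or fully restoring
  activity), a shared per-well transfection-efficiency scale that the
  firefly/renilla ratio cancels, and 10% measurement noise.
- **CFSE** — a branching model: every cell divides in each of 6 rounds
  with a condition-specific probability (responders alone 0.7,
  suppressed by control iTregs 0.3, weakly suppressed 0.55). Under this
  model the precursor-weighted generation distribution is exactly
  Binomial(rounds, p), so the expected division index is rounds × p —
  an analytic oracle the tests use.

Determinism: each generator draws from an independent substream of the
config seed (`SeedSequence` spawn keys), so identical configs give
byte-identical outputs and generators can be re-run independently.

What the generator does **not** emulate: realistic 3′UTR sequence
composition or length distributions, count-level sequencing noise and
dispersion, partial knockdown heterogeneity across cells, CFSE peak
overlap, or death/quiescence in the division model. Passing recovery
tests therefore demonstrates the analysis logic is correct under its
own assumptions, not that the thresholds are optimal for any real
dataset.

## Problem sizes used in the checks

The recovery studies run 100 seeded replicates of the 1,000-gene screen
and of the 3-replicate decay experiment (bootstrap 100 resamples inside
each), and 50 null replicates with no planted effect; these sizes give
stable success-rate estimates while keeping the whole verification run
in the order of a minute.

## Known limitations

- The screen is threshold-based by design; it inherits the published
  criteria rather than a dispersion-aware differential-expression
  model, so its false-positive behaviour on real data depends on
  sequencing depth in a way the synthetic CV parameter only sketches.
- Half-life estimation assumes a single decay phase and full
  transcriptional shutoff at t = 0; delayed drug action or biphasic
  decay will bias k.
- The literal heptamer is one of several ARE definitions; pentamer
  (AUUUA) cluster scoring and ARE class systems are out of scope.
- Genes missing a UTR sequence are counted ARE⁻ by default (drop policy
  available), which is conservative for enrichment.
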