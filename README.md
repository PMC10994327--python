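# trustgame

Simulation and model-based analysis of reciprocity when bestowed trust is
ambiguous: a hidden-endowment variant of the Trust Game in which the
trustee sees only the investment and three candidate endowments.

The package provides a tested, reusable pipeline:

1. **`trustgame.design`** — generate the 120-trial session (40 unambiguous
   trials from a configurable frequency table, then 80 ambiguous trials in
   the fixed 20/20/40 block composition), with bestowed-trust banding
   (low 0.05–0.25, medium 0.35–0.50, high 0.70–1.00).
2. **`trustgame.agents`** — synthetic trustees with a fairness norm Δ, an
   ambiguity-resolution preference (τ, ψ) and truncated-Gaussian response
   noise; cohort simulation with per-participant seed substreams; the
   bonus-payment rule.
3. **`trustgame.reciprocity`** — the inequity-aversion forward model
   `R2 = max(0, (E − I + I·M)·Δ − (E − I))` and its per-participant
   grid-search NLL fit on unambiguous trials, with variance explained.
4. **`trustgame.inference`** — reverse inference of the hidden endowment
   from an observed return: the exact algebraic inverse of the forward
   model at M = 4 (default) plus the published rearrangement behind the
   `printed_eq2` audit switch, with candidate-range clamping, censoring of
   zero returns, and snapping to the nearest candidate.
5. **`trustgame.ars`** — the two-parameter ambiguity-resolution preference
   `p2(E) = (1 − |I/E − τ|)(1 − ψ) + (1 − |I/E − I/10|)ψ`, fitted per
   participant over the 101 × 101 (τ, ψ) grid (10201 coordinate pairs),
   plus the four fixed single-strategy models HAT/LAT/MT/HR.
6. **`trustgame.selection`** — AIC (`n·ln(SSE/n) + 2k`), one-tailed
   uncorrected paired t-tests with paired Cohen's d, automatic exclusion of
   perfectly predicted participants, and strategy classification.
7. **`trustgame.pipeline` / `trustgame.cli`** — end-to-end orchestration
   with CSV artifacts at every stage.

## CLI

```sh
# everything in one go: design, simulate, fit, infer, compare, report
trustgame run-all --seed 1 --outdir run

# or stage by stage, resumable from the CSVs in --outdir
trustgame design --seed 1 --outdir run
trustgame simulate --seed 1 --outdir run --config config.yaml
trustgame validate --outdir run
trustgame fit-delta --outdir run
trustgame infer-endowment --outdir run --method exact_inverse
trustgame fit-ars --outdir run
trustgame compare --outdir run
trustgame report --outdir run
```

A config file (YAML or JSON) mirrors `trustgame.pipeline.RunConfig`:

```yaml
seed: 1
noise_sd: 0.05
grid_points: 101
inversion_method: exact_inverse   # or printed_eq2
objective: choice                 # or preference_gap (audit)
mixture:
  - {strategy: MT,  count: 24, delta: 0.5}
  - {strategy: LAT, count: 8,  delta: 0.65}
  - {strategy: HAT, count: 2,  delta: 0.55}
```

Artifacts written per run: `design.csv`, `choices.csv`, `ground_truth.csv`,
`delta_fits.csv`, `inferences.csv`, `model_fits.csv`, `aic_summary.csv`,
`comparisons.csv`, `strategy_labels.csv`, `strategy_prevalence.csv`,
`recovery.csv`, `report.md` and `manifest.json`.

## Fitting notes

- The endowment inversion defaults to the exact algebraic inverse
  `E = (R2 − I − 3·I·Δ)/(Δ − 1)`; the published rearrangement (which drops
  the `− I` term) is available as `printed_eq2` and differs from the exact
  inverse by exactly `I/(Δ − 1)`.
- The default ARS objective scores a (τ, ψ) point by the number of trials
  where its preferred candidate disagrees with the candidate inferred from
  behaviour; exact ties between grid minima resolve to archetype
  coordinates first, then smallest ψ / smallest τ. The preference-gap
  residual (predicted minus observed preference score) is kept as an audit
  objective, but it is degenerate as an estimator — it vanishes wherever
  the model is merely indifferent between candidates — so it cannot
  recover heuristic-strategy agents.
- A lowest-assumed-trust agent is only identifiable when its fairness norm
  keeps predicted returns positive on the largest candidates (Δ ≳ 0.62 for
  the shipped blocks); the default mixture respects this.

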