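# leapfrog-explore

Simulation and analysis toolkit for the two-option "leapfrog" explore/exploit
task. The package provides:

- **`leapfrog.env`** — the leapfrog reward environment: two options whose
  values alternate in superiority via stochastic +20 jumps to the lower
  option, under a constant per-trial hazard (*independent* condition) or a
  linearly ramping hazard that resets after each jump (*dependent* condition).
- **`leapfrog.agents`** — generative choice models: a *reflexive* agent
  (constant exploration probability), an *ideal reflective* agent that tracks
  the probability its favorite option has been overtaken via a parity
  recursion over unobserved jumps, and a *gambler's-fallacy reflective* agent
  whose believed jump hazard grows with the time since it last observed a
  jump.
- **`leapfrog.metrics`** — explore/exploit labeling, performance and
  exploration rates, exploration hazard curves (rate vs. lag since the last
  exploratory choice), and trials-since-observed-jump covariates.
- **`leapfrog.classify`** — per-participant BIC comparison of an
  intercept-only vs. a nonnegative-slope logit-linear hazard model
  (reflexive vs. reflective classification), plus cohort-level 2×2
  chi-square tests.
- **`leapfrog.groupstats`** — trial-wise logistic regressions with a
  participant random intercept (clustered-robust fallback), 2×2
  between-subjects ANOVAs, and pooled-variance t-tests with Cohen's d.
- **`leapfrog.cohorts`** — synthetic age-group-like cohorts built as
  mixtures of the three agent kinds with lognormal reaction times, including
  ready-made single-condition (58+52 participants) and 2×2
  (70/68/69/69) study designs.
- **`leapfrog.cli`** — a `leapfrog` command with `simulate`, `analyze` and
  `replicate` subcommands.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests (e.g.
the parity recursion against brute-force enumeration of jump sequences), and
`tests/test_acceptance.py` with end-to-end checks: simulator fidelity,
hazard-curve signatures, ≥90% strategy-recovery accuracy, type-I error
calibration of the group-interaction test over 500 null cohorts, and
directional replication of both study designs. The full run takes a few
minutes on one CPU.

## CLI

```bash
# synthetic single-condition study (58 young-like + 52 old-like participants)
leapfrog simulate --study exp1_like --seed 1 --out runs/exp1

# full analysis bundle: summaries, hazard curves, BIC fits, classification,
# trial-wise regressions (and ANOVAs for two-condition designs)
leapfrog analyze --trials runs/exp1/trials.csv --out runs/exp1/analysis

# end-to-end synthetic replication of both designs with directional checks
leapfrog replicate --seed 0 --out runs/replication
```

Study recipes can be customized via `--config` (JSON or YAML), either by
overriding the built-in designs (e.g. `{"exp1_like": {"n_young": 10}}`) or by
providing a full `cohorts` list (see `leapfrog.cohorts.StudySpec`).

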