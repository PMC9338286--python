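# stimchoice

Simulation and analysis of sequential two-offer choice sessions with
per-session stimulation contrasts.

The package provides, end to end:

- **Synthetic sessions** (`stimchoice.simulate`): counterbalanced offer-type
  designs placed around choice indifference, probit-governed trial-by-trial
  choices with order/side/hysteresis biases, error trials and response times,
  and three configurable stimulation effects — a range-proportional value
  shift, an additive order-bias shift, and a multiplicative steepness change.
- **Probit choice models** (`stimchoice.models`): maximum-likelihood fits of
  five models sharing the predictor `a0 + a1*log(qB/qA) + a2*x2` (order bias,
  side bias, and juice/side/order choice hysteresis), with complete-separation
  detection and the derived statistics `rho = exp(-a0/a1)` (relative value),
  `eta = a1` (steepness), and the tagged bias coefficient.
- **Session pipeline** (`stimchoice.session`): stimOFF/stimON split, per-group
  fits, parameter deltas, value ranges (`dV_A`, `dV_B`, `dV`), error rates and
  response-time summaries.
- **Population statistics** (`stimchoice.population`): exact/approximate
  two-tailed Wilcoxon signed-rank and paired t tests, 3-SD outlier screening,
  90% confidence ellipses, effect rectification, per-level Pearson
  `r(delta rho, delta V)` range-bias correlations, and the max-normalized
  cross-condition effect table.

## CLI

All stages run from one YAML configuration (see `examples/experiment.yaml`):

```sh
# everything: simulate -> analyze -> population -> effects
stimchoice run --config examples/experiment.yaml --out out/ --seed 7

# or stage by stage
stimchoice simulate --config examples/experiment.yaml --out out/
stimchoice analyze  --in out/trials.tsv --out out/
stimchoice population --in out/session_deltas.tsv --out out/population.tsv
stimchoice effects    --in out/session_deltas.tsv --out out/effects.tsv
stimchoice fit-session --in out/trials.tsv --model order
```

Artifacts are plain TSV (trial table, long-format fits, per-session deltas,
population panels, effect table) plus YAML/JSON manifests; identical
config+seed reproduces identical files.

## Trial-table schema

One row per trial, tab-separated, `NA` for missing:

```
session_id  trial_index  condition_window  condition_level  q_A  q_B  order
side_A  forced  stim_on  choice  error_code  rt_ms
```

`order` is `AB`/`BA` (which juice appears first), `side_A` the side of juice
A's target, `forced=1` marks a null offer (0 drops), and error trials carry
an `error_code` with `choice=NA`.

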