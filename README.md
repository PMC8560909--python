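# bistableflow

Directed information flow and predictive-coding modelling of bistable
visual perception in intracranial EEG.

## The scientific problem

When an ambiguous image supports two interpretations, perception alternates
spontaneously between them, and most observers spend longer in one
("preferred") percept than the other. A long-standing hypothesis is that
this long-term perceptual bias is implemented by top-down signalling:
higher-order cortex feeds a prior back to sensory cortex, stabilizing the
favored interpretation, while bottom-up prediction-error traffic dominates
when the non-preferred interpretation is seen.

This package implements the full analysis chain needed to test that
hypothesis on multichannel electrophysiology:

1. **Behavior** — segmentation of button-press streams into percepts,
   signed-rank and sign tests for individual and group-level bias, and
   one-way intraclass correlation for cross-session reliability.
2. **Preprocessing** — per-block detrending, line-noise band-stop,
   heartbeat-artifact template subtraction, common-average referencing,
   log high-gamma envelope extraction, and low-pass/downsampling.
3. **Switch/maintain classification** — paired comparison of high-gamma
   envelopes between percept-switch and percept-maintain periods per
   channel, with χ² overlap statistics across images and a dorsoventral
   rank-sum test.
4. **Directed flow** — bivariate vector-autoregressive (VAR) Granger
   causality (GC) in time and frequency (Geweke decomposition), with
   permutation nulls: an electrode-label shuffle for feedforward/feedback
   asymmetry, a trial-label shuffle for percept-dependent coupling, sign
   tests for lobe-level direction bias, and a cluster-based correction for
   signed frequency-resolved effects.
5. **Computational model** — a three-level hierarchical predictive-coding
   attractor network whose long-term prior ("Bias") input reproduces both
   the dominance-duration asymmetry and the directed-flow asymmetries.
6. **Synthetic data + pipeline** — a generator producing percept schedules,
   VAR recordings with known condition-dependent directed coupling,
   event-locked high-gamma modulation, line noise, and heartbeat artifacts
   with a simultaneous ECG channel, plus a seeded CLI pipeline that runs
   every stage end to end.

Raw patient ECoG cannot be redistributed, so the synthetic generator is a
first-class component: every statistical claim in the test suite is checked
against generator ground truth.

## Core statistics

For a channel pair, a VAR(p) model is fitted per direction from trial-wise
lag-moment (Gram) matrices; time-domain GC is `ln(σ²_reduced / σ²_full)`,
the log ratio of reduced-model to full-model innovation variance. Spectral
GC uses the Geweke decomposition of the fitted transfer function on an
evenly spaced frequency grid; its mean over the grid recovers the
time-domain value. Permutation nulls are computed directly in moment space
(electrode-label swaps are an index permutation of the moment matrix;
trial-label shuffles are a re-summation), which makes hundreds of
permutations cheap. Calls are two-sided at α = 0.05 via the 2.5th/97.5th
percentiles of the null.

The model (`bistableflow.hpc`) integrates six rate populations (two
percepts × {sensory, concept, prior} levels) with sigmoid activation,
slow adaptation, Ornstein–Uhlenbeck noise, rectified prediction errors
ascending and predictions descending the hierarchy, mutual inhibition at
the concept level, and a constant `Bias` input to one prior population.

## Worked example

Directed-flow asymmetry on synthetic trials with a planted feedback
(channel 1 → channel 0) connection:

```python
import numpy as np
from bistableflow.synthetic import simulate_var_trials
from bistableflow.granger import asymmetry_test

A = np.zeros((2, 2, 2))
A[0, 0, 0] = 0.4   # occipital channel AR
A[1, 1, 0] = 0.4   # frontal channel AR
A[0, 1, 0] = 0.5   # frontal -> occipital (feedback)
trials = simulate_var_trials(A, n_trials=80, n_samples=64,
                             rng=np.random.default_rng(0))
trials -= trials.mean(-1, keepdims=True)
out = asymmetry_test(trials, order=2, n_perm=500, seed=1)
print(f"GC ff={out.gc_ff:.4f}  GC fb={out.gc_fb:.4f}  "
      f"call={out.call}  p={out.p:.4f}")
```

```
GC ff=0.0001  GC fb=0.2335  call=fb  p=0.0020
```

Simulating the hierarchical predictive-coding model with its default
(biased) parameters:

```python
from bistableflow.hpc import HierarchicalPerceptModel

res = HierarchicalPerceptModel().simulate(600_000, seed=42)
print(res.summary())
```

```
Hierarchical predictive-coding attractor model
==================================================
steps:                     600000 (dt = 1.0 ms)
episodes (pref/nonpref):   109 / 110
median duration pref:      3.39 s
median duration nonpref:   1.96 s
rank-sum z, p:             11.37, 6.2e-30
flow asymmetries (preferred - nonpreferred):
  prediction_prior_to_concept      +0.0216
  prediction_concept_to_sensory    +0.0136
  error_sensory_to_concept         -0.0110
  error_concept_to_prior           -0.0678
```

The preferred percept dominates for longer, top-down prediction signals are
stronger while it is seen, and bottom-up prediction-error signals are
stronger while the non-preferred percept is seen — the model's signature
directed-flow pattern.

## Pipeline CLI

The `bistable-flow` command runs the whole chain from synthetic raw data to
a report, deterministically from one master seed:

```bash
cat > demo_config.json << 'JSON'
{"out_dir": "demo", "master_seed": 5, "n_participants": 6,
 "n_presentations": 2, "presentation_length_s": 45.0,
 "n_perm": 100, "model_steps": 200000, "max_order": 4}
JSON
bistable-flow run-all -c demo_config.json
bistable-flow report demo
```

```
... INFO bistableflow.pipeline: running stage gen-data
... INFO bistableflow.pipeline: running stage preprocess
... INFO bistableflow.pipeline: running stage behavior
... INFO bistableflow.pipeline: running stage classify
... INFO bistableflow.pipeline: running stage granger
... INFO bistableflow.pipeline: running stage simulate-model
done: gen-data, preprocess, behavior, classify, granger, simulate-model -> demo
report written to demo/report
```

The run directory contains `config.json`, a `manifest.json` with per-stage
seeds and artifact checksums, stage outputs (`raw/`, `clean/`, `events/`,
`behavior/`, `classify/`, `granger/`, `model/`), and `report/` with CSV
tables and a markdown summary. Individual stages can be run with
`bistable-flow gen-data|preprocess|behavior|classify|granger|simulate-model`,
and `--seed`/`--out` override the config.

## Reproduction

The Monte-Carlo validation battery (oracle equivalence of the GC engine,
the spectral/time-domain identity, empirical type-I error and family-wise
error of every permutation test, their power, heartbeat-removal quality,
and the model's duration/flow asymmetries) lives in
`bistableflow.validation` and is exercised both by
`tests/test_acceptance.py` and by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints each quantity and writes them as JSON
(`{"name": {"value": ..., "n": ...}}`). All randomness derives from
`--seed`; the full run takes about a minute on one CPU. See
`docs/methods.md` for the model equations, parameter choices, and known
limitations.
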