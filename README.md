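# spikefield

When does a field-potential measure carry the same information as the
spikes underneath it?  High-gamma activity (HGA, the 50–150 Hz amplitude
of the local field potential) is widely used as a proxy for local spiking,
especially in human intracranial work where sorted units are rarely
available.  `spikefield` is a simulation and decoding suite for studying
when that proxy works: it implements the full analysis chain used to
compare spike- and HGA-based representations in a single-exposure visual
memory task (novel vs. repeated images at varying delays), together with
a forward model of a cortical sheet whose channels pool local spiking —
so the whole pipeline runs end to end with no external recordings.

The organizing idea is the distinction between coding schemes:

* **magnitude codes** — the variable modulates overall population firing
  rate (e.g. repetition suppression for novelty/recency).  Spatial
  averaging preserves, and even denoises, such signals, so channel-level
  measures can be *more* data-efficient than matched numbers of units;
* **clustered pattern codes** — the variable modulates *which* neurons
  fire, and like-tuned neurons sit together.  Pooling blurs but does not
  erase the pattern;
* **salt-and-pepper pattern codes** — like-tuned neurons are interleaved
  below the pooling scale, so the channel average washes the code out.

## What is implemented

* **Synthetic task & population** (`task`, `population`, `simulate`) —
  paired novel/repeated image sequences at controlled n-backs (the number
  of intervening trials), memorability-driven response gain, five-category
  blocked structure; a neuron sheet with exponentially decaying repetition
  suppression `1 − s0·exp(−(n−1)/τ)`, Poisson spiking, Gaussian channel
  pooling, and an optional continuous-voltage mode (spike trains convolved
  with a biphasic kernel plus 1/f background) with simulated choices.
* **Spectral chain** (`spectral`) — type-I Chebyshev low-pass below
  250 Hz, downsampling to 500 Hz, 60 Hz harmonic regression, 8-cycle
  Morlet spectrograms on a quadratically spaced 2–200 Hz grid,
  percent-change baseline normalization in [−200, 0] ms, canonical band
  averages (θ, α, β, γ, HGA, broadband).
* **Pseudopopulation alignment** (`pseudopop`) — image pairing across
  sessions by n-back and memorability rank, linear subsampling across the
  memorability range, channel rows repeated per sorted unit so both
  measures have matched population sizes.
* **Metrics** (`metrics`) — sliding-window PSTHs, the repetition effect
  d′ = (μ_nov − μ_rep) / ((σ_nov + σ_rep)/2), time-course and
  memorability correlations.
* **Decoders** (`decoders`) — the spike-count classifier (uniform weights
  1/N, bias at the class-mean midpoint), neuron-dropping curves with
  power-law fits `y = a·x^b + c` and the population size needed for 75%
  accuracy, the diagonal-covariance Fisher linear discriminant, readout
  rescaling to behavior with the prediction-quality statistic
  PQ = 1 − MSE_neural/MSE_benchmark, RSA matrices, and the five-way
  prototype category decoder.
* **Pipeline & CLI** (`pipeline`, `cli`) — config-driven experiments and a
  `framework-report` that evaluates all three coding schemes and issues
  alignment verdicts.

## Worked example

```python
from spikefield import ExperimentConfig, run_novelty_experiment

res = run_novelty_experiment(ExperimentConfig(), seed=1)
print(res["sizes"])
print([round(a, 3) for a in res["curves"]["spikes"]["accuracy"]])
print([round(a, 3) for a in res["curves"]["channels"]["accuracy"]])
print(round(res["efficiency_ratio"], 2), res["verdict"])
```

prints

```
[1, 2, 4, 8, 16, 32, 48]
[0.585, 0.642, 0.689, 0.739, 0.807, 0.846, 0.875]
[0.69, 0.739, 0.783, 0.852, 0.89, 0.904, 0.9]
3.93 aligned
```

Reading: a cross-validated novel-vs-repeated classifier was trained on
growing subsets of 48 units (spike counts) or 48 matched channel
observations (the pooled HGA proxy).  Channel-based decoding reaches any
given accuracy with fewer observations; inverting the power-law fits at
75% accuracy gives N@75% ≈ 8.7 units vs. ≈ 2.2 channels, an efficiency
ratio of 3.93 — the magnitude-coded novelty signal survives spatial
pooling and is captured *more* efficiently by the field measure, so the
verdict is "aligned".

The same pipeline from a shell:

```bash
spikefield framework-report --seed 1 --outdir out/
```

writes `report.json`, `ndc_curves.csv` and the archived `config.yaml`;
two runs with the same config and seed produce byte-identical outputs.

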