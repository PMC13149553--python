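# speedcode

Quantitative analysis of how single-neuron firing encodes locomotion
speed, for electrophysiologists working with head-fixed rodents on
treadmills or turntables: spike-time tables, a signed speed trace
(forward positive, backing away negative), and a stimulus schedule go
in; classified neurons, lag-resolved firing–speed correlations, and
fitted encoding curves come out.

## The model

Running-related neurons ("R-neurons") increase their firing seconds
before running begins, and their rate maps onto speed through a
single-phase association (saturating exponential):

    v = v_m · (1 − e^−(f − f0)/τ)

with *f0* the initial firing rate (spikes/s), *v_m* the asymptotic
maximum speed (cm/s), and *τ* the firing effect constant — the rise in
firing above f0 at which speed reaches 63.2 % of v_m. The same law
with stimulation frequency as abscissa (effect constant τ_s) describes
optogenetically evoked running and backing-away dose–response curves.

The pipeline implements:

- running-bout detection (0.5 cm/s threshold) and spontaneous /
  stimulus-evoked trial labelling;
- two-stage R-neuron classification (one-sided Wilcoxon signed-rank:
  no sensory response on no-run trials, then pre-running firing above
  the stationary baseline);
- peri-event histograms, Gaussian spike-density functions, the
  Baseline + 2·SD firing–running window, and min–max-scaled
  population heatmaps;
- the cross-correlation function between binned firing rate and speed
  over lags of [−10, 10] s (0.1 s steps), with peak/plateau/FWHM
  statistics and a circular-shift permutation test;
- lag-aligned single-phase encoding fits (with a linear-model
  comparison), population normalization that isolates τ, and
  parameter-relation summaries;
- optogenetic trial analysis: peak-speed extraction and behaviour
  labelling, block-averaged dose–response fits (τ_s, v_m),
  frequency→firing-rate conversion ratios, latency curves;
- a synthetic-session generator (inhomogeneous-Poisson spikes driven
  by the inverse encoding model with a firing-leads-speed lag) that
  provides ground truth for every stage.

## Worked example

```python
from speedcode.config import AnalysisConfig
from speedcode.pipeline import run_pipeline
from speedcode.report import population_summary
from speedcode.synthetic import PopulationSpec, generate_population_session

spec = PopulationSpec.tea(n_neurons=12, fractions=(0.5, 0.25, 0.25))
session, truth = generate_population_session(spec, seed=7)
config = AnalysisConfig(n_permutations=200, rng_seed=7)
report = run_pipeline(session, config)
summary = population_summary(report)
```

prints (via the accompanying format calls):

```
R-neurons in summary: 6 (ground truth: 6)
mean r_max:        0.727 +/- 0.028
mean optimal lag:  2.192 s (injected mean: 2.177 s)
neuron n000: tau=19.81 (true 19.35) spikes/s, v_m=34.03 (true 33.65) cm/s, p_perm=0.0050
```

All six simulated running-related neurons (and none of the sensory or
unrelated ones) are recovered; the positive optimal lag means firing
leads speed by about two seconds; and the fitted firing effect
constant and speed asymptote match the generator's ground truth
within a few percent. p_perm is the add-one permutation p-value of the
firing–speed correlation (200 circular shifts here, so 1/201 is the
smallest attainable value).

The same stages are available from the shell:

```sh
speedcode simulate --seed 3 --out session/ --n-neurons 12 --fractions 0.5,0.25,0.25
speedcode report --seed 3 --out results/ session/
speedcode stim-fit --seed 0 --out stimfit.json trials.tsv
```

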