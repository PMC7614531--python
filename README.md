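# neurocascade

Interpretable cascade models of dendritic integration, with a fully
synthetic, ground-truth-known test bed.

A CA1-like pyramidal neuron turns ~2,000 excitatory and ~200 inhibitory
input spike trains into one somatic voltage. `neurocascade` asks how much of
that transformation is captured by small trees of interpretable *subunits*,
and whether fitting such models can *discover* the neuron's synaptic
organization — which synapses form clusters on which dendritic branches —
from input-output data alone. It is aimed at computational neuroscientists
studying dendritic computation and at anyone who wants a controlled test bed
for architecture-discovery methods on neural input-output data.

The somatic subthreshold voltage is decomposed additively,

```
v_soma(t) = v_noNa(t) + v_Na(t)
```

into a slow, global, saturating component (`v_noNa`) and a transient
component of dendritic-spike-driven spikelets (`v_Na`). Cascade models are
rooted subunit trees: node 0 is a linear root; each subunit is either
*static* — synaptic drive filtered with kernels built from K = 30 raised
cosine bases in log time, then a tanh, optionally multiplexed over N_ch
channels —

```
y_n(t) = sum_j w_nj tanh( ybar_n(t) + x^e_nj(t) + x^i_nj(t) + b_nj )
```

or *dynamic* — a gated recurrent unit (hidden size G) with affine readout,
able to produce transient responses to sustained input. Synapses reach
subunits through an assignment matrix `C_syn` (columns sum to one) and
nonnegative weights `w_syn`. Organization discovery optimizes connection
parameters `omega` through a tempered softmax whose inverse temperature
grows as `beta(theta) = exp(theta/724)` from 1 to ~1000 over optimizer
steps, hard-maxed at test time.

The package provides:

* `neurocascade.inputs` — place-cell input simulator: 160 Gaussian basis
  functions over (position, theta phase), phase precession, Gamma(3, 6)
  rates (0.5 Hz mean + 0.1 Hz baseline = 0.6 Hz per input), GLM spiking
  with refractoriness (exact thinning).
* `neurocascade.morphology` / `teacher` — synthetic dendritic tree, synapse
  placement (240 clustered into 4/8/12 clusters on single branches), and a
  fully parameterized generative teacher for `v_noNa`, `v_Na`, `v_soma`,
  somatic spikes and `v_AP`.
* `neurocascade.cascade` / `fitting` — model structures, numpy forward
  pass, and gradient training (built-in reverse-mode autodiff, Adam,
  mean-squared-error loss at learning rate 0.005) plus annealed
  organization discovery.
* `neurocascade.metrics` — variance explained, spike detection and
  binarization, precision/recall, the coincidence factor Gamma (±4 ms),
  GRU spike decoders, ROC/AUROC, spike-rate cross-correlation.
* `neurocascade.rsa` — synaptic dissimilarity matrices (subunit / weight /
  distance / cluster, with distance-orthogonalization) and their Pearson
  comparisons.

## Worked example

Simulate a small teacher dataset, fit a static single-subunit cascade to the
slow voltage component, and evaluate on held-out trials:

```python
import numpy as np
from neurocascade.dataset import DatasetConfig, make_dataset
from neurocascade.cascade import single_subunit_architecture
from neurocascade.fitting import TrainConfig, TrainableCascade, initialize, fit
from neurocascade.kernels import KernelBank
from neurocascade.metrics import variance_explained

cfg = DatasetConfig(n_exc=96, n_inh=8, n_clusters=4, n_clustered=64,
                    n_train=8, n_test=2, trial_duration_ms=2000.0,
                    branches_per_subtree=4, trial_start="field",
                    cluster_span_steps=3)
ds = make_dataset(cfg, seed=7)

bank = KernelBank()
arch = single_subunit_architecture(ds.placement, "static", n_ch=2)
tc = TrainConfig(seed=5, epochs=400, batch_trials=1)
model = TrainableCascade(arch, initialize(arch, tc, bank=bank), bank=bank)
model, log = fit(model, ds.train, "vnona", tc)

m = model.to_model()
preds = [m.forward(t.exc_spikes.binned(), t.inh_spikes.binned())
         for t in ds.test]
ve = variance_explained(preds, [t.v_nona.values for t in ds.test])
print(f"held-out variance explained (v_noNa): {ve:.3f}")
```

This prints

```
held-out variance explained (v_noNa): 0.997
```

— a single static subunit explains ~99.7 % of the slow component's variance on
unseen trials, reflecting that the teacher's `v_noNa` really is one global
saturating nonlinearity. Fitting the same model to the `v_Na` target instead
leaves most variance unexplained, and the gap between dynamic multi-subunit
and static or single-subunit fits on `v_Na` is the package's central
qualitative result (see `tests/test_acceptance.py`).

A CLI mirrors the library (`neurocascade simulate|fit|discover|evaluate|rsa|
fixtures`); run configurations are YAML files, outputs are tab-separated
text.

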