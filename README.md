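# popdann

Domain-adaptive neural networks for simulation-trained population-genetic
inference.

## The problem

Supervised deep-learning methods in population genetics — sweep
classifiers, selection-coefficient and recombination-rate estimators — are
trained on coalescent simulations and applied to real data. When the
simulations are mis-specified (wrong demography, unmodeled background
selection, wrong recombination rate, genealogy-inference error), the
trained model inherits those biases. This package treats the problem as
*unsupervised domain adaptation*: labeled simulated data form the **source
domain**, unlabeled "real" data the **target domain**, and a
**gradient-reversal layer (GRL)** drives the network toward features that
cannot distinguish the two.

The network has three components: a feature extractor G_f shared by a label
predictor G_y and a domain classifier G_d, joined through the GRL. The GRL
is the identity in the forward pass; during backpropagation it multiplies
the incoming gradient by −λ, so one combined update per minibatch moves the
feature extractor along

    ∂L_y/∂θ_f  −  λ · ∂L_d/∂θ_f

(label loss L_y: cross-entropy or MSE; domain loss L_d: cross-entropy;
λ = 1, equal weights). Each minibatch has two components: 64 labeled source
examples through G_y, and a 32 + 32 source/target mixture through G_d.

Three tasks are supported end to end:

* **sweep classification** and **selection-coefficient regression** from a
  genealogy at a focal site, encoded as three stacked (n−1)×(n−1)
  lower-triangular channels — F (branch counts per inter-coalescent
  window, a bijective encoding of the ranked tree shape), W (window spans
  in generations, W[i,j] = t_{n−j} − t_{n−1−i}) and R (F restricted to
  branches carrying the derived allele);
* **recombination-rate regression** from genotype matrices with positions.

A built-in coalescent simulator (msprime) generates matched source/target
domains for every mis-specification scenario studied here: genealogy
inference error only, bottlenecks of increasing severity, a
background-selection surrogate, a mis-specified recombination rate, an
"extreme" combination, and the European-demography recombination
experiment. A four-scenario benchmarking protocol (source-matched /
target-matched / standard / domain-adaptive) contextualizes every result.

## Worked example

`examples/domain_adaptation_benchmark.py` runs the demography experiment at
reduced size: target data follow the packaged European out-of-Africa model,
source data an equilibrium population at the Watterson-matched Ne:

```
pilot Watterson Ne for the source domain: 6,089
        standard:  MAE 1.40e-08  bias -1.36e-08  (trained 34 epochs, best at 23)
 domain_adaptive:  MAE 1.40e-08  bias -1.39e-08  (trained 35 epochs, best at 24)
Welch t on absolute errors (standard vs domain-adaptive): t = -0.01, p = 0.992
```

The pilot estimate shows why the source domain is mis-specified: the
Watterson-implied equilibrium Ne (~6,100) is what a practitioner would
adopt, yet the target data come from a bottleneck-and-growth history. The
standard model then underestimates ρ on target data (strong negative
bias): bottleneck-era linkage disequilibrium looks like low recombination
to a model trained at equilibrium. At this reduced single-seed size the
two models tie on MAE; the domain-adaptive advantage emerges with more
data and replication — the acceptance tests run the same experiment at
4,000 + 4,000 examples over three seeded replicates, where the
domain-adaptive model wins the MAE comparison. Other examples encode a
genealogy (`encode_genealogy.py`), estimate the Watterson Ne
(`watterson_ne.py`) and run the mis-specification severity suite
(`sweep_classification_misspec.py`).

A thin CLI wraps the same library calls:

```
popdann --seed 1 simulate --european -L 300000 -n 32
popdann encode region.trees
popdann --seed 1 benchmark --preset relernn_demography --n-source 1500
```

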