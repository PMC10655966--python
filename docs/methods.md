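# Methods

This note documents the models, the simulation scenarios, the parameter
defaults and their rationale, and what the package's tests do and do not
establish.

## Domain-adaptive networks

Simulation-trained inference is cast as unsupervised domain adaptation: a
feature extractor G_f feeds both a label predictor G_y (the inference task)
and a domain classifier G_d (source vs target), with a gradient-reversal
layer (GRL) between G_f and G_d. Forward, the GRL is the identity;
backward, it multiplies gradients by −λ. Each training step processes one
two-component minibatch: (1) `batch_size` labeled source examples through
G_y (cross-entropy for classification, MSE for regression) and (2) a
source/target mixture of the same total size through G_d (cross-entropy).
Both backward passes accumulate into G_f before a single Adam update, so
the feature extractor follows ∂L_y/∂θ_f − λ·∂L_d/∂θ_f. The source
examples of the domain component are drawn from the same pool as the
labeled component but shuffled independently.

Defaults, all configurable in `TrainingConfig`:

| parameter | default | rationale |
|---|---|---|
| batch size | 64 | standard minibatch size for these tasks |
| λ | 1 | equal loss weights; a warm-up schedule is deliberately not used |
| optimizer | Adam, lr 1e-3 | framework-conventional default |
| domain mixture | 0.5 (32 source + 32 target) | symmetric mixture; the proportion is not dictated by the method |
| early stopping | patience 5 (benchmarks use 10), max 100 epochs | stops on the **label-predictor** validation loss, never the domain loss |
| epoch | one pass over labeled source; target cycled with reshuffling | keeps 10:1 source:target runs well-defined |

With λ = 0 the domain branch contributes exactly zero feature-extractor
gradient, and the training trajectory of G_f + G_y is bit-identical to
standard (non-adaptive) training under the same seeds — a property the
test-suite asserts and which the implementation preserves by giving each
component and each random stream its own seeded generator.

### Network architectures

The layer dimensions of the original task networks are not part of the
method; the stacks here are deliberately small so that training runs on a
single CPU core in seconds to minutes. All layers are implemented in a
purpose-built numpy backprop core (`popdann.nn`): dense, strided valid
convolutions (1-D/2-D), ReLU, global average pooling, softmax/MSE losses
and Adam, verified against central-difference gradients at 1e-8 relative
error. There is no batch normalization and no dropout in the default
stacks; inference is therefore exactly deterministic.

* Genealogy input (n−1, n−1, 3): two strided 3×3 convolutions (width 16,
  then 32), global average pooling, a dense bottleneck of 32 features.
  Channels are scaled before entry: F and R by 1/n, W by 1/(4·Ne_ref)
  with Ne_ref the source present-day size.
* Genotype input: the default pipeline summarizes each (sites × samples)
  matrix into a fixed-length **LD/diversity profile** — mean adjacent-pair
  r² (site lags 1, 2, 3, 5, 8) in 12 pairwise-distance bins spanning
  1/15 of the region, an 8-bin folded site-frequency spectrum, and four
  scalars (segregating sites, mean derived frequency, mean and median
  inter-site gap) — feeding a two-layer dense feature extractor.
  Recombination leaves its footprint in the distance-resolved LD decay and
  demography in the SFS/diversity terms, so both the label signal and the
  domain shift survive the summarization. This profile is a deterministic,
  haplotype-permutation-invariant function of the (genotypes, positions)
  input; a raw-channel encoding (−1/1 genotypes + positions + gaps into a
  strided 1-D convolutional stack) is available via
  `NetworkSpec(input_encoding="raw")` but needs far more training data
  than the desk-scale defaults provide.
* Heads: label predictor Dense(32→64)-ReLU-Dense(64→out); domain
  classifier GRL-Dense(32→32)-ReLU-Dense(32→2).

Regression targets are standardized: selection coefficients are trained
and evaluated as log10(s); recombination rates are trained in units of
1e-8/bp and reported in natural units. Parameter counts per component are
exposed by `DannNetwork.parameter_counts()`.

## Genealogy encoding

A contemporaneously sampled binary genealogy with n leaves and strictly
increasing coalescent times 0 = t₀ < t₁ < … < t_{n−1} (TMRCA) is encoded
by three (n−1)×(n−1) lower-triangular channels, 1-based i ≥ j, row 1 the
most ancient window:

* W[i,j] = t_{n−j} − t_{n−1−i};
* F[i,j] = number of branches whose closed lifespan [child time, parent
  time] contains [t_{n−1−i}, t_{n−j}] — branches born or dying exactly at
  a window endpoint count, which makes the diagonal identity
  F[k,k] = k+1 exact;
* R[i,j] = the same count over derived-carrying branches: the mutation
  (stem) branch plus every branch inside the derived clade, i.e. branches
  all of whose descendant leaves are derived.

F is a bijective encoding of the ranked tree shape; `decode_F` verifies
this constructively for n ≤ 6 by exhaustive search over all ranked shapes
(1, 1, 2, 5, 16 shapes for n = 2…6), and the test-suite checks both
identities encode∘decode and decode∘encode. The public oracle primitive
`branch_span_count` recomputes any F/R cell by brute-force lifespan
enumeration, independently of the cumulative-count encoder.

Simultaneous coalescent times (possible in ingested discrete-generation
trees) are broken by adding k·ε in node-index order, ε = 1e-9 × TMRCA.
Serially sampled tips, polytomies beyond ε-resolution, and multiallelic
focal sites are out of scope. Sweep examples take the segregating site
nearest the sweep position as the focal site, since a fixation-sampled
sweep allele is no longer segregating.

## Simulation scenarios

All simulation uses msprime (binary mutation model; coordinates 0-based
half-open; rates per bp per generation; "central nucleotide" = ⌊L/2⌋).
Source domains are always well-specified equilibrium models with true
genealogies; target domains carry the mis-specification:

* **equilibrium source**: Ne = 10,000, μ = ρ = 1.25e-8, 100-kb regions.
* **tree inference only**: the target genealogy passes through the
  inference-error surrogate — lognormal(0, σ_bl) branch-length factors
  followed by leaf-depth re-ultrametrization, and independent
  nearest-neighbour interchanges with probability p_nni per internal edge.
  Defaults σ_bl = 0.3, p_nni = 0.05, chosen to produce F/W distortions of
  the same qualitative kind as ARG inference error; the encoded F-distance
  from the truth grows monotonically with p_nni (tested).
* **bottlenecks**: Ne drops to 8,000/5,000/2,000/500 between generations
  1,000 and 2,000 (instantaneous step changes), plus inferred trees.
* **background selection surrogate**: the linked diversity reduction of a
  constrained central region (DFE: gamma, mean −0.03, shape 0.2,
  dominance 0.25) is emulated by a region-wide Ne rescaling with
  B ~ U[0.7, 0.95] per region; the manifest records each B. Exact forward
  simulation of the DFE is delegated to external tools via the
  tree-sequence ingest path (`mode="external"`). The surrogate preserves
  the property the method needs: a systematic, learnable source/target
  distribution shift (tested with a linear domain probe).
* **extreme**: 500-bottleneck + background selection + target ρ = 1e-7
  against source ρ = 1.25e-8.
* **recombination experiments**: 300-kb regions, 32 haploid samples,
  μ ~ U[1.875e-8, 3.125e-8], ρ ~ U[0, 6.25e-8]. The background-selection
  variant constrains the central 100 kb. The demography variant draws
  target data from the packaged European out-of-Africa model (two demes,
  ancestral Ne 7,310, out-of-Africa bottleneck 1,861, second epoch from
  1,032 with 0.307%/gen growth, recent 1.95%/gen growth; African deme
  14,474 with 1.66%/gen recent growth; symmetric migration 2.5e-5,
  1.5e-4 during the bottleneck epoch; generation time 25 y — parameters
  in `data/european_demography.yaml`). The source Ne is computed the way
  a practitioner would: mean per-region Watterson θ̂_W of pilot target
  data divided by 4μ̄, ≈ 6,000. The migration with the African deme
  matters: the single-population marginal yields ≈ 5,100 instead.

Sweeps use the structured-coalescent genic-selection model: hard sweeps
start at frequency 1/(2Ne), soft sweeps at f_init; the sampling condition
is fixation (end frequency 1 − 1/(2Ne)) by default, with a segregating
mode (f ∈ [0.05, 0.95]) mirroring real-data applications. Sweep dominance
defaults to 0.5 (genic selection). Failed sweep trajectories are retried
up to 10 times before raising. The structured sweep coalescent cannot
process demographic events mid-sweep, so sweeps under non-constant
demographies run in two stages: the sweep phase under the present-epoch
constant Ne, then the remaining history under the full demography, with
any epoch change that would have fallen inside the sweep window deferred
to just after it (exact whenever the sweep completes before the first
event; neutral examples always carry the exact demography).

Every example is reproducible from (scenario seed, domain, index) via
seed-sequence spawning. Dataset bundles honor the split presets
(90:2:8, 88:2:10, 87.5:2.5:10), the target class mixture, and the
source:target size ratio; target labels are retained only in the held-out
test set, and for classification the target test set is always balanced
regardless of the training mixture.

## Benchmarking protocol and metrics

Four scenarios per experiment, all evaluated on the identical target test
set (the source-matched benchmark on the matched source test set):
source-matched, target-matched (the hypothetical in-domain ceiling, trained
on the labeled target test pool with a held-out tail), standard, and
domain-adaptive. Reports embed the resolved configuration and a content
hash of the dataset; replicate seeds (default 3) give means and ranges.

AUPRC is computed by step integration over the precision-recall curve
(the average-precision form, evaluated at distinct-threshold boundaries);
MAE/RMSE/bias are direct; Welch's unequal-variance t uses the
Welch–Satterthwaite degrees of freedom. scikit-learn and scipy serve as
independent cross-checks in the tests (agreement to 1e-8), never as the
implementation. Standard vs domain-adaptive comparisons apply Welch's t to
per-example absolute errors. Selection coefficients are compared on the
log10 scale; recombination rates in natural units.

## Desk-scale study sizes

The default experiment sizes are deliberately small — thousands of
examples, 32 taxa, feature-profile inputs — so that a full benchmark runs
on one CPU core in minutes. At these sizes the directional conclusions
(standard model biased downward under demographic mis-specification;
domain adaptation reduces target MAE; no harm when domains coincide;
domain-classifier loss starting low and rising toward ln 2 under
mis-specification) reproduce reliably, but absolute error magnitudes are
not comparable to models trained on hundreds of thousands of examples at
128 taxa. Genotype matrices are stored with at most `max_sites = 480`
sites (uniform thinning above that), which loses a little information at
the highest mutation rates.

## Known limitations

* The background-selection surrogate reproduces the diversity reduction
  and its domain signal, not the local SFS distortions of true purifying
  selection; use the external ingest path for forward-simulated data.
* The inference-error surrogate is calibrated qualitatively, not against a
  specific ARG-inference tool.
* No multi-population targets with migration, no gene conversion, no
  admixture, no serially sampled tips.
* The numpy training core is single-threaded; full-scale (10^5-example,
  128-taxon) training is out of its intended range.
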