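# wormcode

Quantifies how much information — in bits — single-worm gene-expression
readouts encode about a discrete environmental variable, the bacterial food
concentration experienced by *C. elegans* under broad-range dietary
restriction (six levels from ad libitum, 1.12×10¹⁰ cells/mL, down to
complete deprivation).

The measurements are per-neuron fluorescence intensities of transcriptional
reporters (e.g. *daf-7* in the ASI sensory neurons, *tph-1* in ADF and NSM),
one vector **g** per worm, collected across populations held at each food
level *f*. The package is for experimentalists and modellers who have (or
want to simulate) such population readouts and ask: how many food states can
this expression code actually distinguish, and do the neurons encode
redundantly or synergistically?

## The model

The expression code is treated as a discrete memoryless channel. Conditional
response densities p(**g**|f) are estimated per food level by multivariate
Gaussian kernel density estimation evaluated on a shared hypercubic grid
(GS bins per readout dimension spanning the pooled data range), giving an
F×M channel matrix. From it:

- **Mutual information** I(F;G) = Σ_f p(f) Σ_g p(g|f) log₂ [p(g|f)/p(g)].
- **Channel capacity** C = max_{p(f)} I(F;G), computed by the Blahut-Arimoto
  alternating optimization together with the capacity-achieving input
  distribution p\*(f). C ≤ log₂ 6 ≈ 2.585 bits for the six-level design.
- **Redundancy** R = Σ_N I_N − C, where I_N is the information of neuron N's
  marginal response at p\*. R > 0: the neurons repeat each other; R < 0:
  synergy — the joint response carries more than the sum of its parts.
- **Shuffle information** I_sh: the information of a surrogate channel in
  which each p(**g**|f) is replaced by the product of its own marginals,
  destroying within-condition (noise) correlations. Noise correlation
  = C − I_sh and signal correlation = I_sh − Σ_N I_N, so
  signal + noise = −R.
- **Uncertainty and bias**: the estimate is recomputed on the five 80%
  complements of a stratified 5-fold split (spread = sampling uncertainty)
  and on growing data fractions, extrapolated linearly in 1/n to the
  infinite-sample limit (jack-knife bias correction).

Upstream of all this, `wormcode.quantify` turns a 3-D fluorescence z-stack
plus a cell location into a background-subtracted integrated intensity
(brightest-K voxel integration minus K × the mode of the surrounding
intensity histogram), and `wormcode.fed` assembles, exclusion-filters and
merges per-cell values into the one-row-per-worm expression tables the
density estimation consumes. A synthetic-data module generates worm
populations with known coding structure — and a Monte-Carlo oracle for their
true information — so the entire pipeline is testable without microscope
data.

## Worked example

`examples/05_redundancy_decomposition.py` builds two synthetic two-neuron
populations and runs the full density → capacity → decomposition chain:

```
shared-gradient population (4 states x 300 worms):
  I_joint      = +1.098 bits
  sum I_N      = +1.799 bits  (0.915, 0.884)
  I_shuffle    = +1.203 bits
  redundancy   = +0.701 bits -> redundant
  signal corr  = -0.596 bits, noise corr = -0.105 bits

correlation-coded population (2 states x 300 worms):
  I_joint      = +0.505 bits
  sum I_N      = +0.022 bits  (0.008, 0.014)
  I_shuffle    = +0.022 bits
  redundancy   = -0.483 bits -> synergistic
```

In the first population both neurons track the same food gradient, so each
alone carries ~0.9 bits but jointly they only reach 1.1 — the overlap is the
+0.70 bits of redundancy. In the second, food state is written purely in the
sign of the inter-neuron correlation: marginals are uninformative (0.02
bits), yet the joint response distinguishes the states (0.51 bits), a
synergistic code that the shuffle surrogate destroys.

The other examples cover the food-series dilution arithmetic (`01`), image
quantification (`02`), FED table assembly (`03`), capacity against the
Monte-Carlo oracle (`04`) and jack-knife bias correction (`06`). A thin CLI
mirrors the shell workflow:

```sh
wormcode simulate FED.dat --config default --seed 1
wormcode density N2 2.0e9 20 pdf PDF 0 1.0 --fed FED.dat
wormcode capacity N2 pdf PDF 20 0
wormcode plan
```

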