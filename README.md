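# neurogain

Whole-brain modelling toolkit for studying how gain neuromodulation switches
a structurally connected network of neural-mass oscillators between
segregated and integrated functional states.

The pipeline covers:

- **`neurogain.connectome`** — loading, mean-strength normalization,
  null models (degree- and strength-preserving randomization, full weight
  shuffling, binarization/homogenization) and structural analysis of weighted
  undirected connectomes: node strength, nodal efficiency, weighted
  clustering, normalized weighted rich-club curves with surrogate p-values
  and rich-club/feeder/local node categories, and s-core decomposition.
- **`neurogain.synthetic`** — generation of surrogate structural matrices
  with planted modular organization and a detectable rich-club core
  (log-normal weights, ~40 % density, 90 nodes by default), plus signal
  fixtures (coherent / antiphase / independent noise / block-correlated)
  with known functional properties.
- **`neurogain.neural_mass`** — a stochastic network of three-population
  cortical-column models (pyramidal cells plus excitatory and inhibitory
  interneurons, an extra slow long-range output pair per node) coupled
  through the normalized connectome, integrated with a numba-accelerated
  Euler scheme at 1 ms. Per-node sigmoid slope (`r0`, the gain knob) and a
  global coupling scalar (`alpha`) are the experiment parameters.
- **`neurogain.hemodynamics`** — flow/volume/deoxyhemoglobin ODEs driven by
  pyramidal firing rates, a nonlinear BOLD readout, zero-phase 3rd-order
  Bessel band-pass (0.01–0.1 Hz) and decimation to the analysis TR (2 s).
- **`neurogain.functional`** — Kuramoto phase synchrony of narrow-band
  analytic phases (per-node spectral peak ± 3 Hz), Pearson FC thresholded
  against Fourier-phase surrogates with BH-FDR control, weighted global
  efficiency, consensus Louvain modularity, and sliding-window functional
  connectivity dynamics (FCD) with the Clarkson distance.
- **`neurogain.protocols`** — the three experiments: uniform `(alpha, r0)`
  sweeps, incremental node-by-node neuromodulation ranked by a structural
  metric, and fixed-size (24-node) subset neuromodulation relative to random
  null subsets, with trapezoidal AUC summaries and independent-samples
  t-tests.

## CLI

A single `neurogain` entry point with sub-commands:

```bash
# synthetic structural matrix (CSV + label file)
neurogain synth connectome --n 90 --density 0.4 --seed 1 --out sc.csv

# structural analyses (CSV outputs per node)
neurogain connectome metrics  --input sc.csv --out results/
neurogain connectome richclub --input sc.csv --surrogates 1000 --seed 0 --out results/
neurogain connectome score    --input sc.csv --cuts 1.48 1.54 --out results/
neurogain connectome surrogate --input sc.csv --kind dspr --seed 0 --out surro.csv

# one simulation (summary CSV + decimated trace export)
neurogain simulate --sc sc.csv --alpha 0.65 --r0 0.33 --duration 660 --seed 1 --out run/

# protocols (desk-scale defaults; raise duration/seeds for full runs)
neurogain protocol sweep --sc sc.csv --alpha-grid 0,0.5,1 --r0-grid 0,0.5,1 --seeds 0,1,2 --out sweep/
neurogain protocol incremental --sc sc.csv --metric strength --direction high_to_low --out inc/
```

## Known limitations

- **External data.** The human AAL90 matrix could not be fetched in the
  build environment (no network), so the human-connectome acceptance test
  (`test_human_aal90_structural_metrics`) fails with an explanatory message
  unless the matrix is supplied.
- **Gain-target ordering on synthetic connectomes.**
  `test_property_g_gain_target_ordering` asserts that modulating
  high-strength / club nodes first shifts synchrony more than modulating
  low-strength / periphery nodes first. On the synthetic connectome family
  the measured ordering is consistently *reversed*: at the protocol's
  operating point the strongest nodes already sit high on their sigmoid, so
  raising their gain sharpens saturation instead of recruiting them, while
  suppressing weakly driven periphery nodes removes incoherent drive and
  raises global synchrony. The uniform-gain effects (segregated at low gain,
  synchronized at high gain, over-synchronization of homogeneous and
  randomized matrices) do reproduce. The hub-first advantage appears to
  depend on the empirical human connectome, which cannot be shipped here;
  the test is left failing rather than weakened.

## Repository layout

```
src/neurogain/      package modules (one per pipeline stage)
tests/              pytest suite; tests/test_acceptance.py holds the
                    acceptance criteria
scripts/acceptance.py   acceptance report generator
```
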