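# pecnet

Source-space **p**ower-**e**nvelope **c**onnectivity and brain-**net**work
analysis for task EEG, with a synthetic cohort generator that plants known
ground truth.

## The problem

Scalp EEG mixes every cortical source into every channel (volume
conduction), so raw sensor correlations are dominated by spurious zero-lag
coupling.  The pipeline implemented here follows the standard remedy:

1. reconstruct source activity with a weighted minimum-norm estimate
   (wMNE, regularization fraction δ = 1/100, Euclidean norm over the three
   dipole orientations);
2. measure coupling as **power-envelope connectivity (PEC)**: for analytic
   signals X(t), Y(t), orthogonalize one against the other,

       Y⊥(t) = imag( Y(t) · X(t)* / |X(t)| ),

   which removes the zero-phase-lag (leaked) share of Y, then correlate
   the log-power envelopes; averaging both directions gives a symmetric
   68×68 ROI matrix per frequency band, i.e. 68·67/2 = **2278** features;
3. binarize at the strongest 10% of connections and compute five graph
   metrics — clustering coefficient CC, characteristic path length L,
   small-worldness σ = (CC/CC_rand)/(L/L_rand) against 100 degree-matched
   connected random networks, and global/local efficiency;
4. compare groups (Shapiro–Wilk/Levene gates, Kruskal–Wallis with
   Bonferroni post hocs, edge-wise one-way ANOVA with Bonferroni over the
   2278 edges);
5. classify two groups by leave-one-subject-out CV with **in-fold**
   feature selection (Corr / Fisher / ReliefF / LARS) crossed with four
   classifiers (logistic regression, AdaBoost, decision tree, random
   forest), reporting the accuracy-vs-feature-count curve, the optimal
   count K = argmax, and an occurrence-ranked feature set.

No patient data ships with the package.  Instead `pecnet.synthetic`
generates cohorts of band-limited oscillatory sources whose slow
log-envelopes carry *exactly* planted pairwise correlations, mixed to
sensors through random lead fields with additive noise — so leakage
rejection, coupling recovery, statistical calibration and classification
can all be validated against known truth.  See `docs/methods.md` for the
model, parameter meanings and caveats.

## Worked example

Plant an envelope correlation of 0.5 between two regions, estimate it back
from the raw signals, and characterize a random 68-node network:

```python
import numpy as np
from pecnet import (SimulationConfig, generate_source_signals,
                    analytic_signal, pec_pair)
from pecnet.topology import graph_metrics

cfg = SimulationConfig(n_rois=2, dipoles_per_roi=1, n_sensors=4,
                       band=(13.0, 30.0), coupling_spec=((0, 1, 0.5),),
                       dipole_noise=0.0)
src, gt, _ = generate_source_signals(cfg, subject_seed=42, duration=60.0)
z = analytic_signal(src, axis=-1)
print(f"planted rho  : {gt.coupled_pairs[0][2]:.3f}")
print(f"realized rho : {gt.coupled_pairs[0][3]:.3f}")
print(f"estimated PEC: {pec_pair(z[0], z[1], cfg.fs):.3f}")

rng = np.random.default_rng(0)
w = rng.uniform(0, 1, (68, 68)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
m = graph_metrics(w, density=0.10, n_random=100, seed=0)
print(f"CC={m.CC:.3f}  L={m.L:.3f}  sigma={m.sigma:.3f}  "
      f"Eglobal={m.Eglobal:.3f}  Elocal={m.Elocal:.3f}")
```

prints

```
planted rho  : 0.500
realized rho : 0.500
estimated PEC: 0.447
CC=0.095  L=2.395  sigma=0.963  Eglobal=0.471  Elocal=0.113
```

The realized latent correlation equals the request exactly (the generator
matches second moments by construction).  The estimated PEC sits slightly
below 0.5: orthogonalized envelope correlation carries a small, known
attenuation (quantified in `docs/methods.md`).  A structureless random
graph has σ ≈ 1 against its degree-matched null, as it should; a
Watts–Strogatz ring under the same null gives σ > 5.

The full pipeline runs from one config:

```bash
pecnet init-config --out cfg.yaml
pecnet run --config cfg.yaml --out runs/demo
```

which writes per-stage outputs (HDF5 signals, delimited-text PEC matrices
and metric tables, classification JSON) plus `manifest.json` with
parameters, seeds and output hashes; re-running recomputes only stages
whose parameters changed.

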