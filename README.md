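# quantos

Probabilistic evaluation of photoreceptor ribbon synapses from two-channel
immunofluorescence images.

Counting synapses between photoreceptors and bipolar cells is central to
studying retinal development, degeneration (e.g. the *rd1* mouse) and
regeneration after stem-cell-derived retinal transplantation. The standard
readout — punctate pre-synaptic (RIBEYE/CtBP2) and post-synaptic (mGluR6)
immunostaining — is usually reduced to a binary colocalization call that is
exquisitely sensitive to arbitrary thresholds. `quantos` instead assigns
every candidate marker pair a posterior probability of being a synapse, so
counts, likelihood landscapes and maturity scores all come from one
transparent model. It is aimed at retinal biologists quantifying
synaptogenesis and at methods developers who need a fully seeded synthetic
benchmark for punctate-pair detection.

## The model

Candidate pairs are pre/post marker centroids within 1.2 µm. For candidate
*x* with class *C* ∈ {synapse, noise}, a Naïve Bayes classifier computes

    p(C | x₁…xₙ) = p(C) · ∏ᵢ p(xᵢ | C) / p(x)

* **Likelihoods** `p(xᵢ | C)` are kernel-density estimates (boundary-
  corrected where the parameter has hard support) of 34 graphical
  parameters — 14 *Signal*, 14 *Morphology* and 6 *Geometry* — measured for
  both markers on the unaltered image, trained from anatomically defined
  classes: staining inside a manually drawn outer-plexiform-layer mask is
  the *ideal synapse* class, everything outside is *ideal noise*. The
  fitted pair geometry of real training data (distance Gaussian
  0.51 ± 0.17 µm, predominantly vertical angles) is the generator default.
* **The prior** corrects for chance colocalization: simulated uniform
  marker fields calibrate a "random factor" (≈ πd² µm²) converting the
  product of local marker densities (5 × 5 µm window) into the expected
  chance-pair count *r*; the synapse prior is 0.5 if *r* < 2, else 1/*r*.
* Pairs with posterior > 50% are called synapses.

Around the classifier: ROI extraction with channel-specific adaptive
protocols, average-synapse imaging with rotational alignment and radial
profiles, ROC evaluation against ground truth (DeLong CI), photoreceptor
counting, a mature/immature classifier, and the downstream Bayesian models
— a marginalized Poisson–Gamma–Gompertz synaptogenesis hierarchy, a
hierarchical Gamma GLM for mERG b-wave amplitudes, and a robust Student-t
comparison — all reported with 89% highest-density intervals.
See `docs/methods.md` for the full account.

## Worked example

```python
from quantos.benchmark import train_default_model, evaluate_benchmark
from quantos.classifier import calibrate_random_factor

model = train_default_model(base_seed=100)     # 8 replicate training scenes
prior = calibrate_random_factor(seed=11)
print(f"random factor: {prior.random_factor:.3f} um^2")

d = model.pair_densities["synapse"]["distance"]
print(f"synapse distance: {d.params['mu']:.3f} +/- {d.params['sigma']:.3f} um")

roc, table = evaluate_benchmark(model, prior, base_seed=200, subset="all")
print(f"AUC {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
      f"{roc.n_positive} positives / {roc.n_negative} negatives")
```

prints

```
random factor: 4.542 um^2
synapse distance: 0.516 +/- 0.173 um
AUC 0.957 (95% CI 0.931-0.983), 480 positives / 110 negatives
```

The random factor matches the analytic chance-pairing slope π·(1.2 µm)² ≈
4.524 µm²; the distance Gaussian fitted by the training stage recovers the
generator's displacement distribution (0.51 ± 0.17 µm) from detected ROI
pairs; and the full-parameter classifier separates true pairs from clutter
on held-out scenes with AUC ≈ 0.96.

The same steps are available from the shell:

```bash
quantos simulate --seed 1 --out scene/
quantos train --pre scene/pre.tif --post scene/post.tif --mask scene/opl_mask.tif --out model/
quantos classify --pre scene/pre.tif --post scene/post.tif --model model/model.json --out result/
```

Every stage writes a manifest (config hash, seeds, output checksums) so any
result is regenerable from the manifest alone.

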