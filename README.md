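# smhairpin

Analysis toolkit for single-molecule studies of amyloid β-hairpin
assembly. The biological system is the Aβ(14–23) segment (HQKLVFFAED), a
core fibril-forming stretch of amyloid-β, probed both as a linear
monomer (M, Cys-HQKLVFFAED) and as a β-hairpin mimic (H) in which two
Aβ(14–23) units are joined by a YNGK turn. Hairpin–monomer (H-M) and
hairpin–hairpin (H-H) complexes are characterised by three
single-molecule techniques plus coarse-grained simulation, and this
package implements the complete quantitative workflow for all of them:

- **Force spectroscopy** (`smhairpin.force`): detection of specific
  unbinding events in AFM force–distance retraction curves, worm-like
  chain fitting

  F(x) = (k_B·T / L_p) · [ ¼ (1 − x/L_c)⁻² − ¼ + x/L_c ],

  contour-length filtering against the PEG tether (L_c ≈ 33 ± 5 nm),
  Gaussian histogram fits of rupture forces, replicate aggregation and
  two-sample Kolmogorov–Smirnov comparison.
- **Dwell-time (lifetime) analysis** (`smhairpin.dwell`): one-step burst
  extraction from framed fluorescence intensity traces (100 ms frames)
  and lognormal fitting of the dwell-time histogram; the reported
  lifetime is the lognormal mean exp(μ + σ²/2).
- **AFM morphology** (`smhairpin.morphology`): cross-section profiles and
  particle-height statistics distinguishing fibrils, globular (spherical
  cap) and disk-shaped aggregates.
- **Dihedral PCA free-energy landscapes** (`smhairpin.dpca`): (cos, sin)
  featurization of backbone dihedrals (terminal residues excluded), PCA,
  and ΔG(V1,V2) = −k_B·T·ln(P(V1,V2)/P_max) with persistence-based
  minima detection.
- **Monte Carlo pulling** (`smhairpin.mcpull`): a Gō-like Cα model of
  the H-M and H-H dimers with virtual springs on the N-terminal pulling
  groups receding at constant velocity; Metropolis dynamics and
  rupture-force statistics.
- **Synthetic data** (`smhairpin.synthetic`): generators for every input
  (curves, traces, topographs, dihedral trajectories, CG dimers) with
  ground-truth labels, so every pipeline is testable end to end.

Analysis stages are scikit-learn-style estimators (`RuptureDetector`,
`WLCFitter`, `GaussianHistogramFit`, `BurstDetector`,
`LognormalLifetime`, `ParticleDetector`, `DihedralPCA`) with thin
functional wrappers, and compose with sklearn pipelines.

## Worked example

Simulate an H-M force-spectroscopy experiment (2000 approach–retraction
cycles at 9% specific yield, rupture forces Normal(164, 17) pN on a
PEG tether with L_c ~ Normal(33, 5) nm, 10 pN instrument noise) and run
the full analysis:

```python
from smhairpin.synthetic import FDGenParams, gen_fd_curves
from smhairpin.force import analyze_curves

curves, truth = gen_fd_curves(FDGenParams(n_curves=2000, seed=1))
res = analyze_curves(curves, lc_window=(23, 43), noise_floor_pn=20)
print(f"{res['n_specific']} specific events ({res['yield']:.1%} yield)")
print(f"rupture force {res['force_fit'].mean:.1f} +/- {res['force_fit'].sd:.1f} pN")
print(f"contour length {res['lc_fit'].mean:.1f} +/- {res['lc_fit'].sd:.1f} nm")
```

```
170 specific events (8.5% yield)
rupture force 163.9 +/- 18.8 pN
contour length 33.5 +/- 5.9 nm
```

The detected yield falls in the 8–10% range typical of such
experiments, and the Gaussian-fitted force and contour-length means
recover the generator's ground truth (164 pN, 33 nm) within statistical
error — the contour length agreeing with the tether length is precisely
the specificity fingerprint used to accept events.

The same pipelines are available from the command line:

```sh
smhairpin simulate fd --preset HM --n 2000 --seed 1 --out curves/
smhairpin fspec --curves curves/ --lc-window 23:43 --noise-floor 20 --out results.json
smhairpin simulate traces --preset HM --seed 1 --out traces/
smhairpin tapin --traces traces/ --out lifetimes.json
```

Every result JSON embeds the seed, a configuration hash and the package
version.

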