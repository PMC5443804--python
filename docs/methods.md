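# Methods

This note documents the models implemented in `smhairpin`, the defaults
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Units and constants

Lengths are nm, forces pN, times ms, energies k_B·T. The Boltzmann
constant is 0.0138065 pN·nm/K; the default temperature is 298 K ("room
temperature"), giving k_B·T = 4.114 pN·nm.

## Worm-like-chain force spectroscopy

**Model.** The interpolation formula
F(x) = (k_B·T/L_p)·[¼(1−x/L_c)⁻² − ¼ + x/L_c] relates the extension x
of a polymer tether to the restoring force through its persistence
length L_p and contour length L_c. F(0) = 0, F is strictly increasing,
and F diverges as x → L_c; extensions ≥ L_c are a domain error. The
inverse x(F) used by the curve generator is obtained by bisection, which
is robust because F is monotonic.

**Event detection.** The far-from-surface baseline is the median of the
final 20% of the retraction trace, and the noise scale is the scaled MAD
of the same region. The force is smoothed with a 7-sample moving
average, and a rupture candidate is a drop between smoothed levels one
window apart exceeding max(6·√2·σ_s, 15 pN), from a pre-drop level above
5·σ_s, landing within 3·σ_s of baseline, at tip–surface distances beyond
10 nm (the short-range zone is where nonspecific adhesion lives and is
excluded outright). When several drops qualify, the one at the largest
distance is kept: with a serial tether geometry the last unbinding is
the specific one. These thresholds make the false-event rate on pure
10 pN noise ≲ 10⁻³ per curve while detecting essentially every event
above ~50 pN.

**Rupture distance refinement.** Rupture occurs somewhere between the
last attached and the first detached sample; the midpoint of that
interval is the unbiased estimate, and the rupture force is the fitted
WLC force evaluated there. Evaluating at the last attached sample
instead would bias the force low by ~(dF/dx)·Δx/2, a few pN where the
force–extension curve is steep — comparable to the standard error of
the study-scale force histograms, hence worth removing.

**WLC fit.** Nonlinear least squares (scipy `curve_fit`) over the ramp
from where the smoothed force leaves the noise band to the last attached
sample. L_p is fitted freely within [0.1, 2] nm by default — the
tether's persistence length is not known a priori — and can be fixed via
`fix_lp`. L_c is bounded below just above the largest extension in the
segment. Flat or too-short segments raise a `FitError` with diagnostics.

**Statistics.** Specific events are those with fitted L_c inside the
tether window (default 23–43 nm, i.e. 33 ± 2 SD of the PEG
polydispersity) and rupture force above a 20 pN instrument-noise floor.
Force and contour-length histograms are fitted with a Gaussian by least
squares (Freedman–Diaconis bins unless a width is given; fewer than 3
populated bins is an error; a large fit residual flags non-Gaussian,
e.g. bimodal, samples — the residual, not the mean, is the reliable
signal there). Replicate means aggregate as arithmetic mean ± sample SD,
and groups are compared with the two-sample Kolmogorov–Smirnov test.

## Dwell-time (lifetime) analysis

A bound complex appears as a one-step rise of fluorescence above
background and an abrupt fall after the dwell. Per trace, background is
the median and its spread the scaled MAD; bursts are maximal runs of
frames above background + 5·MAD_sd. Runs touching the trace boundaries
are censored (dropped, not truncated — a truncated dwell would bias the
mean low), and runs whose plateau coefficient of variation exceeds 0.2
are rejected as multi-step (a two-level staircase has CV ≈ 0.33 at equal
steps, a genuine plateau ~0.03 at typical signal-to-noise). A trace
whose majority value is pinned at its maximum is treated as
detector-saturated and raises.

Dwell times are integral multiples of the frame time (100 ms default);
sub-frame events are emitted by the generator flagged `sub_resolution`
and appear as single-frame dwells, so quantization bias is bounded by
one frame and is ≲ 2% of the H-M mean lifetime.

**Lognormal fit.** The reported "average lifetime" is the lognormal
distribution mean exp(μ + σ²/2) (the median and mode are exposed too).
The default estimator fits the lognormal pdf to the dwell histogram by
iteratively reweighted least squares: one unweighted pass, then weights
from the model-predicted Poisson SD per bin. Weighting by observed
counts would bias the fit low; no weighting roughly doubles the
estimator variance. Because quantized dwells sit on a frame lattice,
automatic bin widths are rounded up to a lattice multiple and edges
offset half a quantum — otherwise bins alternately cover one or two
lattice points and the histogram acquires a sawtooth that corrupts the
fit. A closed-form ln-space moment estimator (`method="mle"`) is
available and agrees with the histogram fit.

## AFM morphology

Features are measured on 2-D height maps with the image median as
baseline (the support surface dominates the field), which makes all
height readings invariant to adding a constant plane. Cross-sections are
bilinearly interpolated along a segment, with the baseline from the
profile's outer 10% at each end, and report peak height and FWHM.

Particles are 8-connected regions more than `min_height` above baseline
(≥ `min_area_px` pixels). The default per-particle height is the map
value at the pixel nearest the region centroid: for symmetric features
the centroid is the particle center, and because the sampled pixel is
chosen independently of the roughness at that pixel the estimate is
unbiased for flat-topped disks and carries only a sub-pixel curvature
bias (~(pixel/2)²/R_sphere, ≈ 0.01 nm at 2 nm pixels for the ~2.65 nm
caps studied here). The common alternative — the region maximum — is
biased high by the expected extreme of the roughness over the region
(~0.15 nm for a disk spanning ~200 pixels at 0.05 nm roughness), which
is fatal when the features themselves are only 0.85 nm tall; it remains
available as `height_method="max"` for cross-checks against
cross-section peak readings. Overlapping features merge into one region
by construction (documented, not resolved); touching-border regions are
flagged.

## Dihedral PCA and free-energy landscapes

Backbone φ/ψ angles are mapped to (cos θ, sin θ) pairs, removing the
±180° discontinuity; terminal-residue angles are excluded via the
trajectory's terminal mask. PCA is the standard covariance
eigendecomposition (sklearn), with a deterministic sign convention: the
largest-magnitude loading of each component is made positive. The
landscape is ΔG(V1,V2) = −ln(P/P_max) in k_B·T over a 50×50 grid padded
5% beyond the data range (the bin count is free; nothing in the method
fixes it). Empty bins carry +∞ as a sentinel rather than a capped
number so that minima searches only ever see populated bins; by
construction the global minimum is exactly 0 at the most-populated bin,
and ΔG is invariant to frame permutation and to doubling all counts.

Minima are found by watershed flooding in order of increasing ΔG with
topographic persistence: when two basins meet, the meeting level is
their saddle and the shallower basin's persistence is saddle − birth.
Reported minima need persistence ≥ `depth_threshold` (default 0.5 k_B·T);
the global minimum has infinite persistence and is always reported.
Bins visited by fewer than `min_count` frames (default 5) do not
participate — single-frame tail bins are sampling noise, and without
the cutoff every isolated outlier would register as a minimum. Basins
disconnected from the global minimum (their barrier region was never
sampled, i.e. is effectively infinite) are reported with infinite
persistence. Consequently a uniformly sampled landscape yields exactly
one (trivial) minimum, and a K-state mixture yields K minima whose ΔG
differences recover −ln(p_i/p_j).

## Coarse-grained Monte Carlo pulling

The dimers are modelled at one bead per residue with a Gō-like energy
(in k_B·T at 298 K): stiff harmonic bonds (k = 300 k_B·T/nm²) between
consecutive beads at their native spacing, 12–10 wells
ε·[5(r₀/r)¹² − 6(r₀/r)¹⁰] on native contacts (minimum −ε at the native
distance r₀), and a (σ/r)¹² soft-sphere repulsion (σ = 0.3 nm, ε = 1)
between all remaining pairs. Pair distances are clipped below 0.05 nm so
the energy is large but finite for any configuration, never NaN.

**Contact sets.** The hairpin is 25 beads — the printed sequence
C-HQKLVFFAED-YNGK-HQKLVFFAED includes the N-terminal Cys, and the
sequence arithmetic (1+10+4+10) fixes the convention at 25, the monomer
(C-HQKLVFFAED) at 11. The H-M dimer intercalates the monomer
antiparallel between the hairpin strands with 5 inter-chain contacts at
ε = 3 plus one Lys–Asp salt-bridge contact at double depth (2ε); the H-H
dimer places two hairpins side by side with 4 inter-chain contacts
across the facing strands. Each hairpin carries 3 intra-molecular
cross-strand contacts at 6 k_B·T — deeper than the interface contacts so
that the cooperatively folded hairpin survives pulling and the
inter-chain interface, not the fold, is what ruptures, mirroring the
experiment. These counts parameterize the reported hydrogen-bond
inventories of the two complexes; the model makes no attempt to
reproduce atomistic structure or absolute forces, only the relative
mechanical stability of the two interfaces.

**Pulling protocol.** Metropolis dynamics with single-bead Gaussian
displacement moves (step 0.06 nm, ≈ 40–50% acceptance). One sweep is N
attempted moves. Two virtual springs (default 60 pN/nm) connect the
pulling groups — the N-terminal beads of each chain — to anchors that
start at the group positions and recede symmetrically along the
inter-group vector by `velocity_v` (default 0.02 nm/sweep) of total
separation per sweep. The recorded force is the spring constant times
the mean extension of the two springs. A contact counts as formed while
r < 1.5·r₀; rupture is the first sweep at which the formed fraction of
inter-chain contacts falls below `contact_break_fraction` (default
0.25), and the rupture force is the maximum recorded force up to that
sweep. Velocity is in nm/sweep: Monte Carlo time has no physical clock,
so the experimental retraction speed has no literal translation and
pulling-rate statements are comparisons between runs of this simulator
only. The spring stiffness, move set and rupture criterion are this
package's own definitions.

`sample_equilibrium()` runs the identical move set with no springs
(anchors frozen), which is how the engine's detailed balance is verified
against Boltzmann statistics on a two-bead toy.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses rely on:
WLC-shaped specific events with truncated-normal rupture forces and
tether contour lengths on a distance-sampled grid plus Gaussian
instrument noise, at an exact specific yield (`round(n·fraction)`
curves); triangular short-range (< 10 nm) adhesion on nonspecific
curves; one-step bursts with lognormal dwells quantized to whole frames
over Gaussian background; topographs as the pixel-wise maximum of
analytic feature profiles (spherical cap, flat disk, elliptical-section
ridge) plus Gaussian roughness; von Mises state mixtures for dihedral
trajectories. Everything is bitwise-reproducible under a fixed seed and
carries ground-truth labels.

The study-condition defaults encode the experimental parameters: H-M/H-H
rupture forces 164 ± 17 / 100 ± 6 pN, lifetimes 617/344 ms, tether
33 ± 5 nm, 10 pN noise, 9% specific yield, 500 nm/s retraction, 100 ms
frames, n = 297/274 dwell events and 180/175 force events, aggregate
heights 2.65 ± 0.61 (caps) and 0.85 ± 0.08 nm (disks). The lifetime
tables report only means, so the lognormal shape parameter is a choice:
σ = 0.8, giving the broad right-skewed histograms characteristic of
single-molecule dwell data; the generator accepts the distribution mean
directly (μ = ln m − σ²/2).

Deliberately not modelled: tip-shape convolution (lateral sizes are
reported as-is; a stated fibril "diameter" on such maps is a
tip-convolved width, so the generator takes apex height and ridge width
independently), EMCCD camera noise beyond Gaussian background, dye
photophysics (blinking/bleaching), cantilever mechanics and thermal
calibration, multi-rupture sawtooth curves, and loading-rate
(Bell–Evans) spectroscopy. Passing the recovery tests therefore shows
the pipelines are unbiased under the stated noise model, not that they
are robust to every instrumental artefact of real recordings.

## Problem sizes and tolerances in the validation suite

Recovery checks run at the study's own scale (2000 curves with ~180
events, 297/274 dwells, 100 particles, 50,000 dihedral frames) and
compare recovered means to the injected truth within 3 standard errors,
averaging a handful of generator seeds to estimate the recovery
variance. The Monte Carlo ordering check (H-M stronger than H-H) uses
50 independent pulls per system and a one-sided Mann–Whitney test at
p < 0.01; absolute rupture-force values are not comparable to
experiment and only the ordering is asserted. The analytic identities
(F(0) = 0, F(L_c/2) = 1.25·k_B·T/L_p, ΔG = 0 at P_max, two-state gap
ln 4) are exact up to statistical tolerance of the constructions that
exercise them.

## Known limitations

- The WLC fit treats the tether as a single ideal chain; linker/anchor
  elasticity and multiple parallel tethers are out of scope.
- Burst detection assumes a stationary background per trace; slow drift
  would need detrending upstream.
- Particle statistics assume mostly-empty surfaces (median baseline);
  crowded fields shift the baseline and merged regions are counted once.
- The landscape minima depend on bin occupancy through `min_count`;
  extremely sparse trajectories will under-report shallow states.
- The pulling model's absolute forces depend on arbitrary well depths
  and spring/velocity choices; only contrasts between models sharing
  those choices are meaningful.
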