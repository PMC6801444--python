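# Methods

This note documents the models, conventions, numerical choices and
limitations of `chiralmem`. Units are nm, ns and degrees throughout;
energies are in kBT at 303.15 K unless a configuration overrides the
temperature.

## Geometric conventions

**Helix frame.** The helix axis is the first principal direction (SVD) of
the C-alpha cloud, oriented so that `axis · (CA_last − CA_first) > 0`
(N- to C-terminus). A frame is flagged ambiguous when the relative gap
between the two leading singular values falls below 5% — then the "axis"
is not meaningfully separated from the second principal direction.

**Rotation angle.** `theta` is the signed angle about the *oriented* axis,
right-hand rule, from the half-plane containing +z to the half-plane
containing the Trp CG atom, wrapped to [0°, 360°). This construction is the
unique dihedral of the three named elements (axis, CG, +z); it is invariant
under translation and rotation about z, and a mirror through the plane of
axis and z maps `theta -> 360° − theta`. An absolute wrapped convention is
required because the state thresholds (135°, 180°, 225°) are absolute.
If CG projects onto the axis (norm < 1e-9 nm) the angle is undefined and an
error is raised rather than returning an arbitrary value.

**Descending/ascending sides.** The vertical plane containing the helix
axis and z splits space. A surface point at azimuth `phi` (measured like
`theta`) has vertical velocity ∝ `−omega·sin(phi)` under rotation rate
`omega = d theta/dt`. The adsorption rotation sense is a property of the
enantiomer (L: `omega < 0`, D: `omega > 0`), so the descending half
(velocity into the membrane) is `sin(phi) < 0` for L and `sin(phi) > 0`
for D. We deliberately derive the side from the chirality's known rotation
sense rather than the instantaneous angular velocity: per-frame velocities
are dominated by noise, while the pathway-level sense is fixed. Each
ambient lipid is labeled by the side of its chiral C2 carbon (or its center
of mass, `side_basis="com"`). A lipid exactly in the dividing plane — a
measure-zero event that must still be deterministic — is labeled ascending
and flagged. Helices within 1° of vertical have no well-defined dividing
plane and raise an error.

**Surface fragments and Trp orientation.** The nonpolar residues (Leu,
Trp) of an amphipathic helix stack into ridges on the hydrophobic face. We
detect fragments as maximal chains of nonpolar residues stepping +3
(preferred) or +4 in sequence — one helical turn — provided the
helical-wheel drift of the step stays inside a configurable angular band
(default 100°; the step drifts are 60° and 40° on an ideal helix). For the
C6 sequence this yields exactly four fragments with Trp on a longest
(4-residue) one. The fragment tangent at Trp is the derivative of a
quadratic arc fitted through the fragment's C-beta positions (the chord for
2-residue fragments); `t·l` dots it with the indole long axis CD1→CH2.
Values near +1 are the cis ("well-orientated") groove-aligned arrangement;
near 0 / −1 perpendicular or trans ("bad-orientated").

## Contact statistics

* `ambient_cutoff` = 0.3 nm, nearest heavy-atom criterion (peptide–lipid).
* `contact_cutoff` = 0.5 nm between heavy atoms; a (residue, lipid) pair
  contributes at most one contact.
* Classification: side from the lipid's des/asc label; type from the
  nearest head/tail lipid atom (head → polar, tail → hydrophobic). Mixed
  pairings (nonpolar residue–head atom, charged residue–tail atom) are
  assigned by the lipid-atom class by default; `mixed_mode="strict"`
  counts only (nonpolar, tail) and (polar, head) pairs, for sensitivity
  analysis. The chiral C2 atom participates in distance tests but belongs
  to neither class; classification falls to the nearest classified atom.
* `S_rot = w_dp·N_dp + w_dh·N_dh + w_ah·N_ah + w_ap·N_ap`. The shipped
  default weights (+1, +1, −1, −1) encode the driving-force reading —
  descending-side contacts pull the rotation forward, ascending-side
  contacts resist it — and are configuration, not constants: every output
  records the weights used.
* Trp–head contacts: distinct lipids with ≥ 1 head-group atom within the
  contact cutoff of any Trp heavy atom; capped at one per lipid by
  construction.
* Side switching: a lipid switches when its des/asc label changes and the
  new label persists ≥ `debounce` frames (default 5 — no persistence rule
  is canonical, so the value is exposed; debouncing is needed because a
  lipid sitting near the dividing plane flickers at frame rate).
* Distances use minimum-image convention whenever a box is present.

The pseudo-lipid head set is {P, N} and the tail set {CT1, CT2}; for real
POPC structures the head set should be declared as phosphate + choline +
glycerol atoms and the tails as the acyl chains (config-declared atom-name
sets).

## First-passage kinetics

FPT is the first time `dz` reaches the threshold (default 1.5 nm), linearly
interpolated between the bracketing frames — interpolation removes the
frame-stride quantization bias. Traces that never cross are right-censored
at their end time; traces starting below the threshold return FPT = 0 with
a `start_below` flag.

The empirical CCD is the Kaplan–Meier product-limit estimator (via
lifelines), which reduces to 1 − ECDF without censoring. Parametric fits
maximize the censored likelihood (events contribute `log f`, censored
samples `log S`); "fitted" could also mean least squares on the log-CCD,
so that mode is provided (`method="lsq-log"`) but MLE is the default
because finite trajectory spans make censoring first-class. Optimization
is Nelder–Mead on unconstrained transforms (log time constants, logit
weight) from 8 quantile-based multistarts (fast constant from the
lower-half mean, slow from the top-decile mean) to avoid local optima and
label switching; the exp1 optimum is polished by Newton iterations on the
analytic score. Standard errors are asymptotic, from the inverse numerical
Hessian of the negative log-likelihood at the MLE on the natural scale; a
seeded bootstrap (`bootstrap_se`, default 500 resamples) is available as an
alternative for small samples. Mixture fits are flagged degenerate when
`tau_fast/tau_slow > 0.8` or the fast weight leaves (0.005, 0.995) —
an effective single exponential. AIC is reported for exp1/exp2/gamma
comparison.

## Umbrella reweighting and the barrier

Reduced bias of window *i* at sample *n*: `u_in = beta [ k_i/2 (dz_n −
c_i)² + offset_i ]`. Window free energies `f_i` are solved two ways, both
in-repo:

* **MBAR** (binless): minimize the convex objective
  `sum_n log sum_i N_i exp(f_i − u_in) − sum_i N_i f_i` (L-BFGS-B with
  analytic gradient), then polish by self-consistent iteration to
  `max |Δf| < 1e-7` kBT.
* **WHAM**: self-consistent iteration on a 120-bin dz histogram to the
  same tolerance.

Unbiased per-sample weights `w_n ∝ 1 / sum_i N_i exp(f_i − u_in)` give the
2D PMF by weighted histogramming on a default 30 (dz) × 36 (theta) grid
over [1.0, 2.5] nm × [0°, 360°); the sampled-bin minimum is set to 0 and
unsampled bins are masked, never interpolated. The PMF is exactly gauge
invariant under constant bias offsets. Conditional expectations
`E[O | dz bin]` use the same weights, reported with the weighted standard
deviation (the physical fluctuation of O) and a Kish effective sample
count. Each window discards a leading `discard_fraction` (default 10%,
mirroring the usual equilibration discard) and can be thinned by its
estimated statistical inefficiency (`subsample=True` by default; the
initial-positive-sequence autocorrelation estimator).

Adjacent-window dz-histogram overlap is checked: zero overlap is an error
naming the gap; overlap below 1% is a warning.

**Barrier.** On the binned surface, bins are activated in order of
increasing free energy and merged by union-find (8-connected,
theta-periodic); the first bin whose activation connects the two basin
minima (each obtained by steepest descent from its seed) is the saddle,
and its level is exactly the minimax path cost. The barrier is
`F(saddle) − F(pre-basin minimum)`, measured from the approach side
(larger dz) because the adsorption experiences it in the direction of
decreasing dz. Basins that merge below any saddle give barrier 0 — the
downhill/funnel case.

## States, window statistics, reports

Pre-adsorption: `theta > 225°` (L) / `theta < 135°` (D); post-adsorption:
`theta < 180°` (L) / `theta > 180°` (D). The inequalities are strict;
boundary frames and the gap between regions are labeled `neither` and
excluded from state averages. The two policies map onto each other under
the parity transform `theta -> 360° − theta` (the single wrap point
`theta = 0` is the one measure-zero exception created by the strict
thresholds). Per (window, state): mean, SEM = s/√n, and n; states with
n < 2 report the mean with a masked SEM. Welch unequal-variance t-tests
are run between all window pairs within a state and reported as raw
p-values at nominal level 0.1; no multiplicity correction is applied and
the output metadata says so, so downstream users can correct.

Report bundles (JSON + CSV) are pure functions of inputs and
configuration: fixed float formatting, sorted keys, and a config-hash +
seed stamp on every table make reruns byte-identical. `t·l` histograms use
a 0.05 bin width by default (configurable); contact counts use integer
bins.

## Synthetic generators: what they emulate, and what they do not

The generators replace multi-microsecond all-atom MD with ground-truth-known
stand-ins:

* **Peptide**: ideal α-helix (rise 0.15 nm, twist 100°/residue; C-alpha
  radius 0.23 nm, C-beta 0.34 nm) with a rigid 3-atom indole proxy (CG,
  CD1, CH2; CD1→CH2 = 0.55 nm). Only the indole long-axis direction enters
  any statistic, so a full side-chain model would add atoms but no
  information. The D model is the exact mirror (y negated), which keeps
  bond lengths bit-identical between enantiomers.
* **Bilayer**: jittered-lattice pseudo-POPC, 64 lipids per leaflet at 0.68
  nm² per lipid; heads at |z| ≈ 1.9 nm, C2 at 1.55 nm, tails below —
  the z-ordering (head outside C2 outside tail) is asserted.
* **Reference surfaces**: sums of periodic (von-Mises-shaped in theta)
  Gaussian basins, an optional theta-gated ridge, a linear tilt and
  quadratic walls. The `barrier` preset places the pre-adsorption basin at
  (2.2 nm, 90°), the adsorbed basin at (1.2 nm, 230°) and the ridge gap at
  (1.8 nm, 150°), then rescales the whole surface so its dense-grid
  minimax barrier equals the requested saddle height (default 4.3 kBT)
  exactly — the calibration is part of the surface's definition, computed
  at construction by the same minimax search the analysis uses, on a
  301 × 240 grid. The `downhill` preset is a single funnel (monotone in
  dz); `escape_well` is a single basin just above the FPT threshold whose
  fluctuation-driven escape gives approximately exponential FPTs.
* **Kinetics**: overdamped Langevin by Euler–Maruyama, `dx = −mu ∂u/∂x dt
  + sqrt(2 mu (T/T_surf) dt) xi`, theta wrapped. Defaults: dt = 0.01 ns,
  200 ns span, mobility 0.012 nm²/(kBT·ns) in dz and 50 deg²/(kBT·ns) in
  theta — chosen so the downhill preset adsorbs on the ~20 ns scale within
  a 200 ns trajectory, matching the fast-channel phenomenology. The
  discretization bias of Euler–Maruyama is O(dt) (≈ 2% on the stationary
  variance at relaxation time 0.2/ns·dt = 0.01); dt is config-exposed and
  the equilibrium check in the tests uses a smaller step accordingly.
  Setting the simulation temperature to 0 removes the noise but keeps the
  drift.
* **Umbrella sampler**: per window, 32 independent Metropolis random-walk
  chains (proposals: 0.05 nm in dz, 15° in theta) started from the biased
  dz marginal and the conditional theta distribution at the window center
  (inverse-CDF on a 0.5° grid); the first max(200, 10%) steps of each
  chain are discarded as burn-in and the kept steps interleaved. Any
  correctly weighted sampler suffices for reweighting — MD realism is not
  required, only Boltzmann-consistent window samples.
* **Contact fixtures**: per frame, K ~ Poisson(mean) lipids are placed
  with a head atom inside the Trp contact cutoff and the rest with all
  head atoms outside it; the realized geometric count is verified (and the
  frame redrawn on failure), so the count distribution holds by
  construction, not intent.

What passing tests on these generators **does not** show: force-field
realism, lipid conformational flexibility, membrane deformation,
water-mediated effects, or peptide internal dynamics (the helix is rigid).
The pipeline's correctness claims are about the estimators and geometry —
parameter recovery at known ground truth, brute-force oracle equivalence,
and symmetry identities — not about reproducing membrane physics.

Binary trajectory ingestion (XTC/DCD) is out of scope for this version;
real trajectories enter through the in-memory frame API or the columnar
text trace format (`time_ns, dz_nm, theta_deg`).

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
kinetic recoveries use 2000–5000 draws, the umbrella pipeline 16 windows ×
20000 samples in the test suite (40000 in the reproduction script, 8000 in
shared test fixtures), brute-force oracle sweeps
200 random ≤ 5-lipid placements, and the end-to-end bundle a reduced
pipeline (windows of a few thousand samples). These sizes put Monte-Carlo
error comfortably inside the stated tolerances while keeping the whole
suite in the minutes range.

## Known limitations

* The exp2 likelihood surface is flat when the two time constants approach
  each other; the degeneracy flag (ratio > 0.8) is a heuristic, and
  standard errors near that regime are unreliable (use the bootstrap).
* The minimax barrier is measured on a binned surface: bin-average
  smoothing biases the saddle slightly downward and quantizes its location
  to bin centers (0.05 nm × 10° at the default grid).
* WHAM here solves a 1D (dz) histogram for the window free energies; it
  agrees with binless MBAR to well under 0.2 kBT on overlapping ladders
  but inherits histogram-width sensitivity for poorly overlapping ones.
* The ambient filter and contact counting are O(n_peptide × n_lipid)
  pairwise scans — appropriate for the ≤ 10³-atom synthetic systems, not
  tuned for large real membranes.
* `statistical_inefficiency` uses the initial-positive-sequence estimator
  on the flattened sample stream; for heavily correlated single-chain
  input, inspect per-chain autocorrelation before trusting error bars.
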