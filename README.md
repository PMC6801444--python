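# chiralmem

Analysis pipeline for **chirality-dependent adsorption of an amphipathic
helix onto a phospholipid bilayer**.

Mirror-image peptides (all-L vs all-D enantiomers) can adsorb onto a chiral
membrane with different kinetics even though their intramolecular energetics
are identical. For the 18-residue cationic helix Ac-RLLRLLLRLWRRLLRLLR-NH2
("C6", Arg/Leu/Trp only) on a POPC bilayer, the L enantiomer adsorbs in a
downhill, single-exponential fashion while the D enantiomer shows an extra
slow, activated channel tied to a free-energy bottleneck along the coupled
descent-and-rotation pathway. `chiralmem` implements the quantitative
analysis behind that picture as a tested, reusable library — and, because
multi-microsecond all-atom trajectories are not shippable, pairs it with
seeded synthetic generators whose ground truth is known exactly.

## What it computes

**Coordinates.** `dz` is the z-distance between the centers of mass of
peptide and bilayer (the adsorption progress coordinate, membrane normal =
z); `theta` is the rotation of the helix about its own axis, measured as the
dihedral of (helix axis, Trp CG, +z), wrapped to [0°, 360°). The L
enantiomer rotates with decreasing `theta` during adsorption, the D
enantiomer with increasing `theta`; the parity map is `theta -> 360° -
theta`.

**First-passage kinetics** (`chiralmem.kinetics`). FPT = first time `dz`
reaches 1.5 nm (linear interpolation between frames; censored at the
trajectory end otherwise). The survival function (complementary cumulative
distribution, CCD) is estimated with the Kaplan–Meier product-limit
estimator and fitted by censored maximum likelihood under

```
S(t) = exp(-t/tau)                                   (exp1)
S(t) = w exp(-t/tau_fast) + (1-w) exp(-t/tau_slow)   (exp2, w normalized)
S(t) = Q(k, t/s)                                     (gamma)
```

with asymptotic standard errors from the observed information, multistart
optimization, AIC for model comparison, and a degeneracy flag when the
mixture collapses.

**Umbrella reweighting** (`chiralmem.pmf`). Harmonic windows along `dz`
(default: 16 windows uniform on [1.0, 2.5] nm) are combined with in-repo
**WHAM** and **MBAR** solvers (self-consistent to |Δf| < 1e-7 kBT) into a
2D potential of mean force over `(dz, theta)` in kBT at 303.15 K. The
adsorption barrier is a **minimax path**: the lowest free-energy level at
which the pre- and post-adsorption basins connect through sampled bins
(8-connected, theta-periodic); the saddle is the connecting bin and the
barrier is measured from the approach-side basin. Arbitrary per-sample
observables can be reweighted into unbiased conditional expectations
`E[O | dz]`.

**Contact statistics** (`chiralmem.contacts`). *Ambient* lipids are those
within 3 Å (nearest heavy atoms) of the peptide. Each lipid is labeled
**descending** or **ascending** by the side of the vertical plane through
the helix axis on which its chiral C2 carbon falls, with the descending side
defined by the chirality's rotation sense. Residue–lipid contacts (any
heavy-atom pair within 5 Å) are classified by side and by interaction type
(lipid head → polar, tail → hydrophobic) and combined into the rotational
driving-force score

```
S_rot = w_dp N_dp + w_dh N_dh + w_ah N_ah + w_ap N_ap
```

(default weights +1, +1, −1, −1; configurable, always recorded). Also:
Trp–head-group contacts (at most one per Trp–lipid pair), the side census
`Δn_des−asc = n_des − n_asc`, and debounced side-switch counting.

**Trp orientation** (`chiralmem.geometry`). The nonpolar residues stack
into four surface fragments on the C6 helix; `t·l` is the dot product of
the fragment tangent at Trp with the indole long axis CD1→CH2 (≈ +1 cis /
"well-orientated", ≤ 0 perpendicular or trans / "bad-orientated").

**States and reports** (`chiralmem.report`). Pre-adsorption (θ > 225° for
L, θ < 135° for D) and post-adsorption (θ < 180° for L, θ > 180° for D)
states, per-window means with SEM = s/√n, Welch unequal-variance tests
(raw p-values, flagged as uncorrected), and a byte-reproducible JSON+CSV
report bundle stamped with the config hash and seeds.

**Synthetic systems** (`chiralmem.synthetic`). Ideal α-helix models (0.15
nm rise, 100° twist, pseudo side chains, rigid 3-atom indole proxy), exact
mirror-image D models, pseudo-POPC bilayers (two 64-lipid leaflets,
head/C2/tail pseudo-atoms), analytic 2D reference surfaces (downhill
funnel; two-basin surface whose minimax saddle is calibrated to 4.3 kBT by
dense grid search), overdamped Langevin traces, Metropolis umbrella
windows, and Poisson-calibrated Trp-contact frame ensembles.

## Worked example

```python
import numpy as np
import chiralmem as cm

surface = cm.ReferenceSurface.barrier()        # two-basin landscape, 4.3 kBT saddle
config = cm.LangevinConfig(seed=0)             # 200 ns traces, dt = 0.01 ns
traces = cm.simulate_traces(surface, config, n_traj=50)

fpts = [cm.extract_fpt(t, threshold=1.5) for t in traces]
print(f"{sum(not s.censored for s in fpts)}/50 trajectories adsorbed within 200 ns")

windows = cm.sample_umbrella(surface, n_samples=20000, seed=0)
pmf = cm.estimate_pmf(windows, estimator="mbar")
report = cm.find_barrier(pmf, seed_pre=(2.2, 90.0), seed_post=(1.2, 230.0))
print(f"barrier: {report.barrier:.2f} kBT at dz = {report.saddle[0]:.2f} nm")

peptide = cm.build_peptide(chirality="D")
frames = cm.place_contact_fixture(peptide, 1.54, n_frames=2000, seed=0)
counts = [cm.trp_head_contacts(f, cm.ContactPolicy()) for f in frames]
print(f"mean Trp-head contacts: {np.mean(counts):.2f}")
```

prints

```
5/50 trajectories adsorbed within 200 ns
barrier: 4.15 kBT at dz = 1.83 nm
mean Trp-head contacts: 1.57
```

The activated surface lets only a fraction of unbiased trajectories adsorb
within the 200 ns span (the slow, barrier-limited channel); the umbrella
pipeline recovers the calibrated 4.3 kBT saddle near its true location
(dz = 1.8 nm) from biased sampling alone; and the geometric contact counter
reproduces the planted Poisson mean (1.54) of Trp–head contacts.

A command-line surface wraps the same functions:

```bash
chiralmem simulate traces --preset downhill --seed 1 --out traces.csv
chiralmem fpt traces.csv --out fpt.csv
chiralmem fit-ccd fpt.csv --model exp1 --out fit.json
chiralmem simulate umbrella --preset barrier --seed 1 --out windows/
chiralmem pmf windows/ --estimator mbar --out pmf_out/
chiralmem report --preset barrier --seed 1 --out bundle/
```

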