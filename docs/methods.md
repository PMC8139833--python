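# Methods

## Model

A single chromosome is a bead-spring chain of `N` beads of diameter
`sigma` (reduced length unit; 10 nm), one bead per ~600 bp.  Energies, in
units of `k_B T`:

* **Stretching** `E_s = sum_i k_s (r_i - 2a)^2`, `k_s = 100`, rest length
  `2a = sigma` (the rest length is not stated numerically by the model's
  source; touching spheres are the natural choice for tangent beads).
* **Bending** `E_b = sum_i k_b (1 - cos theta_i)`, with `theta` the angle
  between successive bond vectors (zero when straight) and
  `k_b = l_p kT / sigma = 2`, targeting a persistence length of two beads.
* **Chromatin–chromatin Lennard-Jones** between *all* bead pairs
  (adjacent pairs included), depth `epsilon_matrix[type_i, type_j]` and
  cutoff 2.5 `sigma` (self-attractive) or `2^(1/6) sigma` (repulsive-only
  WCA truncation).  Energies are truncated *and shifted* to zero at the
  cutoff so the energy is continuous; forces come from the unshifted
  derivative and are unaffected.  A uniform matrix is the main model;
  distinct LAD/non-LAD entries support heterochromatin-like variants.
* **Wall**: each bead repels from its nearest envelope point through a
  WCA potential of the gap `g = R_c - |r|` (`eps = 1`, cutoff
  `2^(1/6) sigma`).
* **Lamin beads**: a static, deterministic golden-angle (Fibonacci)
  lattice on the sphere, one bead per `sigma^2` of surface area, so
  bonding is geometry-limited rather than lattice-limited.  LAD beads
  feel an attractive LJ (`eps_lm = 1`, cutoff 2.5 `sigma`); non-LAD beads
  a WCA repulsion (`eps_ln = 1`).  Lamin beads do not interact with each
  other and never move.
* **LAD–lamina bonds**: `E_bond(r) = -k_bond (r_b - sigma)^2
  + k_bond (r - sigma)^2` with `k_bond = 10`, `r_b = 2.5 sigma`; zero at
  `r = r_b`, minimal (−22.5 kT) at contact.  A bond forms whenever an
  unbonded, bond-eligible LAD bead has a lamin bead within `r_b`
  (nearest wins; index ties go to the lowest lamin index) and can break
  only while stretched beyond `r_b`, with probability `exp(-U_bond/kT)`,
  `U_bond = 10`, per integration step.  Each LAD bead carries at most one
  bond in total (a bead stands for one tether-protein-scale unit; the
  one-per-pair reading would allow several, and the choice is noted as
  open).  Bond attempts run every step, so the effective breaking *rate*
  is `exp(-U_bond/kT)/dt`; observables compared across timesteps should
  keep this in mind.

Bond eligibility: a fraction `psi` of LAD beads, chosen uniformly at
random (exactly `round(psi * n_LAD)` beads), may bond.  The LAD/non-LAD
typing comes from a BED-like annotation (0-based half-open, majority
(>=50%) bp-overlap rule per bead, ties labeled LAD) or from the synthetic
generator below.

## Integration

Overdamped (position-only) Langevin dynamics:

```
r(t+dt) = r(t) - (dt / gamma m) grad E + sqrt(2 kT dt / gamma m) * xi
```

with unit-variance Gaussian `xi` per component.  (The classic
`sqrt(6 kT dt/gamma m)` prefactor with uniform variates has the same
second moment; `noise="uniform"` selects it.)  Reduced time unit:
`tau = 3 pi eta sigma^3 / kT`, the bead damping time (~2 µs in water).

**Timestep.**  The tabulated default `dt = 0.01 tau` is kept in the
parameter container, but a position-Langevin Euler update is only
conditionally stable: the bond springs give `2 k_s dt = 2` at
`dt = 0.01` (the stability boundary), and the LJ core curvature exceeds
`2/dt` for thermally visited separations at any `dt >~ 5e-4`.  The
pipeline therefore integrates **production at `dt = 1e-4 tau` for
confined systems** (`2e-4` suffices for free chains) — where every
thermally visited configuration is inside the stable domain and contact
statistics are converged in `dt` — and **equilibration stages at
`dt = 1e-3 tau` with per-step displacements capped at 0.25 sigma**, which
bounds core-collision overshoots while the protocol is only steering the
system toward its organization mode; a short capped segment at the
production step bridges the two.  A force blow-up guard raises an error
when the deterministic drift of any bead exceeds `sigma/2` in one step
(thermal noise alone may legitimately exceed that at large `dt`, so the
guard watches the drift).

**Neighbor search.**  Verlet lists built from linked cells (skin 0.8
sigma, rebuilt when any bead has moved half a skin), stored per bead `i`
as ascending `j > i`.  Because accumulation order is fixed this way, the
cell-list trajectory is bit-for-bit identical to a quadratic all-pairs
reference with the same RNG — a property the test suite checks directly.

**Equilibration protocol.**  (i) *Push-off*: noise-free, displacement-
capped descent (bonding inert) until no pair or wall gap is tighter than
0.85–0.9 sigma; the initial state — a folded random walk spanning the
nucleus, center of mass at the origin, exact bond lengths — is locally
over-dense and needs this inflation.  (ii) *Repulsive stage*: WCA
chromatin, lamina interactions and bonding active.  (iii) *Attractive
stage*: configured epsilon, cutoff 2.5 sigma.  Stages run window by
window until the windowed mean radius of gyration changes by <1% over
two consecutive windows; the attractive stage additionally honors a
minimum window count, because R_g is nearly blind to peripheral-layer
formation (the chain spans the nucleus throughout; at N = 2000 the
peripheral state needs ~60k attractive steps at `dt = 1e-3` while R_g
plateaus within ~20k).

## Synthetic LAD patterns

The generator emulates the two statistics of the Drosophila ChrX LAD
annotation: 48% LAD content, mean domain 90 kbp = 150 beads.  LAD block
lengths are geometric with mean 150; non-LAD blocks geometric with mean
`150 (1-f)/f`, so the expected LAD fraction is `f`.  At full scale
(37,333 beads) the realized fraction is within ±0.03 of target; at the
desk scale N = 2000 a chain holds only ~13 blocks, so the realized
fraction fluctuates by ~±0.14 between seeds — real biological replicates
do not show this, and it adds seed-to-seed spread to desk-scale state
diagrams.  The generator does not reproduce the ChrX domain-size
*distribution* tails or positional structure, only the two moments above.

## Observables

* **Radial profile** `phi(r)`: bead volume per thin equal-thickness
  spherical shell, frames averaged, `r` normalized to the envelope.  Its
  volume-weighted mean equals the global `phi` identically.
* **Classification**: thresholds on the profile (defaults: peripheral =
  peak beyond 0.8 with the `r < 0.5` mean under 10% of the peak; central
  = peak inside 0.6 with the outermost bin under 50% of the peak; a
  center-of-mass offset above 0.15 R_c marks wetting droplets, grouped
  with central).  Before thresholding, the profile is re-binned onto 10
  equal-volume shells: the innermost thin shells hold so little volume
  that a single bead there produces a spurious phi spike which must not
  decide the peak position.  The source work classifies "from the
  plots"; these explicit thresholds are this package's own, are config
  keys, and reproduce the example profiles.
* **Contact maps / P(s)**: contact iff `r_ij < 2.5 sigma`, `|i-j| > 1`;
  symmetric binned frequency matrix with unit diagonal; `P(s)` the mean
  contact frequency versus contour separation.
* **Persistence length**: `<cos theta(s)>` fitted by `exp(-s b / l_p)`
  over `s = 1..10`, nonlinear least squares on the correlation itself
  (the better-sampled short separations carry the weight; log-space
  fitting lets the noisy slow-mode tail dominate).  `b` is the measured
  mean bond length (~1.045 sigma — the adjacent-pair LJ core shifts the
  spring equilibrium outward), since persistence length is an arc-length
  property.  The standard measurement samples with the Brownian
  integrator across several independent chains and averages: chain-scale
  tangent modes decorrelate too slowly for one long run.
* **Flory exponents**: the subchain estimator fits `<R_g^2(s)> ~ s^(2nu)`
  over `s in [10, N/2]`.  It recovers 1/2 (ideal), ~1 (rod) and ~0.59
  (self-avoiding, pivot-equilibrated), but for a collapsed chain it
  *cannot* give 1/3: globule subchains are Gaussian until they saturate
  at the globule size (crossover `s ~ 25` at N = 500), and the fit lands
  near 0.25.  The collapsed exponent is therefore measured as chain-size
  scaling, `R_g ~ N^nu` across N = 250..1200 globules, which yields
  ~0.31; chains shorter than ~150 beads are excluded because a 2-sigma-
  persistence-length chain cannot fold into so small a globule.
* **Angular segregation**: same-type fraction among 10 nearest angular
  neighbors of peripheral beads (r > 0.8 R_c, positions projected to the
  unit sphere), normalized by its mean under 100 type shuffles.

## Equilibration accelerators for free chains

Brownian dynamics cannot equilibrate the large-scale statistics of an
N = 500 chain in desk time (subchain relaxation grows as `s^2 tau`), so:
self-avoiding chains are equilibrated by Metropolis **pivot moves**
(rigid tail rotations accepted on the cross-half WCA + pivot-joint
bending energy change — the standard SAW equilibrator), interleaved with
short Brownian segments that restore bond-length statistics; collapsed
chains start from a compact folded walk at globule density (~0.85
beads/sigma^3) and are annealed by capped Brownian dynamics — a
globule's large-scale structure is fixed by its density, not by its
history.  Pivot equilibration is *not* used for the persistence-length
measurement, which is defined over the Brownian-sampled ensemble (a
fully pivot-equilibrated self-avoiding chain develops a power-law
tangent-correlation tail that inflates the short-range exponential fit).

## Desk scale and run lengths

State-diagram work runs at N = 2000 with `R_c` set from `phi` by the
closed-form inverse of the volume-fraction relation (the transitions are
controlled by the intensive `(phi, psi, epsilon)`).  Default run lengths
(RunSettings): push-off to the 0.85-sigma contact target; repulsive stage
up to 6 × 10k steps; attractive stage 6–12 × 10k steps at `dt = 1e-3`
(≥ 60 tau, the observed peripheral-layer formation time at this N);
production 10k steps at `dt = 1e-4`, sampled every 1k.  Profiles average
~10 production frames.

## Known limitations

* The organization modes at N = 2000 form on 10–100 tau timescales;
  states pinned by many tethers (low-psi transitions toward central
  organization) coarsen much more slowly, since detachment requires rare
  breaking of stretched bonds (`e^{-10}` per step each), and may remain
  kinetically trapped in wall-attached configurations over desk-scale
  runs.
* The capped larger-step equilibration slightly over-heats core contacts
  relative to Boltzmann; production sampling at `dt = 2e-4` is unbiased.
* A single chromosome only; no territories, no A/B compartments beyond
  the LAD/non-LAD dichotomy, no hydrodynamic interactions, no explicit
  tether proteins.
* The bond-breaking test is per integration step, so kinetic (not
  equilibrium) bond observables depend on `dt`.
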