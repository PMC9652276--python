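# Methods

`phytohop` is a desk-scale computational model of the photoactivation of the
*Deinococcus radiodurans* bacteriophytochrome (DrBph): the photoisomerization
of its biliverdin (BV) chromophore around the C15=C16 methine-bridge double
bond (torsion D6), and the subsequent relaxation of the chromophore-binding
pocket through the early and late Lumi-R intermediates.  It replaces the
atomistic QM/MM machinery such a study would normally require with (i) a
three-coordinate two-electronic-state model of the chromophore and (ii) a
statistical generator of binding-pocket feature trajectories, while keeping
the full analysis pipeline (trajectory ensembles, lifetime fits, quantum
yield, clustering, contact statistics, surrogate IR difference spectra,
relaxation kinetics) identical in structure to what would run on atomistic
data.

## The reduced photoisomerization model

Coordinates: the double-bond torsion `theta6` (D6), the adjacent single-bond
torsion `theta5` (D5, the hula-twist partner), and the D-ring
carbonyl...His290 hydrogen-bond distance `r_hb`.  Angles are degrees on
(-180, 180], distances angstrom, energies kcal/mol.

Two diabatic states are used.  The reactant diabat `V11` has its torsional
minimum at the planar (Pr-like) geometry; the product diabat `V22` is offset
by the vertical excitation energy `E_vert` (40.8 kcal/mol = 1.77 eV, red
light) at the Franck-Condon point and descends along `theta6`.  They cross
where `(V6_S0 + V6_S1*s6)/2 * (1 - cos theta6) = E_vert`; the packaged
amplitudes place this crossing at ~90.6 deg, reproducing a decay funnel at
D6 ~ 90 deg.  A Gaussian diabatic coupling (`w0` = 2.8 kcal/mol, width 7.5
deg) is centred slightly beyond the crossing (98 deg), which puts the
minimum-gap point of the adiabatic surfaces a couple of degrees *before* the
ground-state ridge: trajectories therefore hop on the reactant side of the
ridge, and only the hotter ones carry enough torsional momentum to commit to
the photoproduct.  This placement is what gives the model its small quantum
yield with realistic hop geometries.

State-common terms carry the chemistry of the pocket:

* an H-bond Morse well in `r_hb` (depth `D_hb`), with a planarity coupling
  `-lambda_hb * depth(r_hb) * ((1+cos theta6)/2)^2`: the stronger the
  His290 H-bond, the stiffer the planar D6 well on the ground state and the
  higher the torsional barrier on S1.  The planarity factor is restricted to
  the cis (reactant) side -- it vanishes at the isomerized geometry --
  because the H-bond is lost in the photoproduct; a symmetric `cos^2` form
  would spuriously stabilize a planar product and deepen the product well by
  the full H-bond energy.
* a hula-twist bilinear coupling `chi sin(theta6) sin(theta5)` whose sign
  makes the S1 minimum-energy path rotate D5 opposite to D6 (concerted
  double/single-bond rotation), plus a `V5 sin^2(theta5)` restoring term;
* a smooth periodic one-sided wall `(v_asym/2)(1 - cos theta6) *
  sigmoid(-sin theta6 / 0.08)` that places the product well exclusively on
  the positive-`theta6` (counterclockwise) side.  Clockwise isomerization is
  thereby excluded energetically, not by fiat: the wall is ~14 kcal/mol at
  -90 deg and zero on the forward path.
* a quartic confinement beyond `r_wall` standing in for the pocket around
  the broken H-bond.

Because all of these are state-common they cancel in the S0/S1 gap, so the
seam location is analytic and independent of `theta5` and `r_hb`.

The *relaxed torsional barrier* is measured on a <=0.25-degree `theta6` grid
with `(theta5, r_hb)` minimized in closed form at each point (the inner
problem is separable), as the largest climb of the relaxed adiabatic profile
from the Franck-Condon side to the photochemical funnel (the minimum-gap
point, located by parabolic interpolation so the measurement is continuous
in the parameters).  `scale_d6_barrier` adjusts only `s6` (bracket scan +
bisection) and reproduces any requested barrier to 0.01 kcal/mol; the
packaged set-A model has exactly 1.6 kcal/mol at `s6 = 1`.

## Sampling and surface hopping

Ground-state sampling runs velocity-Verlet dynamics on the lower adiabatic
surface with a stochastic velocity-rescaling (canonical) thermostat at 300 K,
20 ps per chain with the first 10 ps discarded, several chains in lockstep;
vertical-excitation initial conditions copy positions and momenta from
uniformly drawn frames and start on S1 with coefficient vector (0, 1).

The surface-hopping engine integrates nuclei with BAOAB Langevin steps
(dt = 0.1 fs; gamma = 0 reduces exactly to velocity Verlet) on the active
adiabatic surface.  Electronic coefficients are advanced by local
diabatization: the rotation between successive adiabatic bases is built from
the 2x2 mixing angles, the trapezoidal local-diabatic Hamiltonian is
exponentiated exactly, and the result is rotated back -- unitary to machine
precision and robust at the near-degenerate funnel.  Fewest-switches hops
are drawn from the population flux out of the active state and can be gated
by a maximum S0/S1 gap (the 0.5 eV variant; in the packaged model hop gaps
are ~0.1-0.2 eV, so the gate never triggers and the gated dynamics is
bit-identical).  Energy-based decoherence damps the non-active amplitude
with time constant `(hbar/|dE|)(1 + C/E_kin)`, C = 0.1 hartree.

Two conventions deserve emphasis:

* **Hop-energy release into the H-bond coordinate.**  On an accepted hop the
  electronic energy gap is exchanged with the `r_hb` momentum only (the
  carbonyl recoil that breaks the His290 H-bond at the funnel -- the model's
  analogue of the H-bond loss at the conical intersection), rather than
  along the gradient-difference direction.  This leaves the torsional
  momentum thermal at the hop (small quantum yield) and frustrates most
  upward S0->S1 hop attempts, so ~96-98% of trajectories decay through
  exactly one hop.  The gradient-difference and isotropic rescaling
  conventions remain available as settings; frustrated hops never alter
  velocities.
* **A hot excited-state bath.**  While on S1 the Langevin bath acts at
  `T_excited` = 700 K (300 K on S0).  This emulates the vibrationally hot
  chromophore after photon absorption in a model with only three modes: a
  ~41 kcal/mol photon deposited into an atomistic chromophore keeps the
  reactive torsion substantially hotter than the 300 K protein during the
  few-picosecond excited-state episode.  The value was calibrated (together
  with `w0`, `gamma`, the inertias and the diabat amplitudes) against the
  ensemble observables below; in particular it controls the slope of the
  barrier--lifetime law, which at 300 K would be far steeper than the
  behaviour this class of system exhibits.

Each trajectory owns an independent, counter-seeded random stream, so
ensembles are reproducible, order-independent, and a single trajectory is
bit-identical to the corresponding ensemble member.  Trajectories stop once
they have settled on S0 in the reactant (|D6| < 45 deg) or product
(|D6| > 120 deg) well for 0.5 ps.  The inner loop is compiled with numba;
a 500-trajectory, 15 ps ensemble takes on the order of a minute on one CPU.

## Calibration

The packaged parameter files are the result of the documented calibration:
with the relaxed S1 barrier pinned at 1.6 kcal/mol (by solving for
`lambda_hb` at `s6 = 1`), the remaining knobs were tuned so that 500-
trajectory ensembles reproduce, at the packaged protocol: S1 lifetime
tau_A ~ 2.24 ps (set A) and tau_B ~ 0.48 ps (set B, weak H-bond,
`D_hb` 2 vs 6 kcal/mol), quantum yield ~15%, hop geometries with median
|D6| ~ 88 deg, zero clockwise products, and a log-linear barrier--lifetime
law whose extrapolation to a 6.2 kcal/mol barrier is of order 100 ps.
`photoanalysis.calibrate_model` packages the loss (squared relative errors
of the lifetimes and yield, a quadratic hop-geometry penalty, a hard
clockwise penalty) and a coordinate search with shrinking multiplicative
steps; the accepted-iterate loss sequence is returned for audit.

## Ensemble analysis

Populations are trajectory fractions per state on the stored time grid with
a seeded bootstrap band (1000 resamples).  The S1 decay is fitted with a
delayed exponential `P(t) = 1` for `t < t0`, `exp(-(t-t0)/tau)` after it;
the latency absorbs the Franck-Condon dwell before the seam is first
reached, and bootstrap refits give the CI on tau.  A trajectory is reactive
when its final |D6| exceeds 120 deg and stays there for the final 0.5 ps
(both configurable); direction is the sign of the D6 displacement at the
first accepted hop; trajectories still on S1 at the horizon are censored
from classification and logged.  The quantum yield carries a Wilson 95%
interval.  The barrier scan rescales the barrier, re-runs the full protocol
per point with a horizon that grows with the expected lifetime
(15/28/45/70 ps at 1.6/2.8/4.0/5.2 kcal/mol -- the problem sizes used
throughout this package's own runs), and fits a weighted regression of
ln(tau) on the barrier with a prediction interval for the extrapolation.

## The pocket generator and its analyses

The generator emulates the *statistical* structure of binding-pocket
trajectories, not their mechanics: named donor-acceptor distances and two
indicator flags are drawn from per-state emission distributions collected in
one annotated config (`params/pocket_default.yaml`).  Early-Lumi-R frames
come from a three-cluster mixture with weights 0.18/0.81/0.01 (Cl1 lacks the
water H-bond to the D-ring carbonyl; Cl2 has a broken Tyr263...Asp207
contact; the short N_D...Tyr263 bond is the early hallmark).  Relaxation
replicas switch irreversibly early->late at an exponential time with mean
0.4 us, sampled every 100 ps over 2 us; the late state has a bimodal
O_D...Arg466 distance (a mobile Arg466), a weakened Asp207-Arg466 salt
bridge, and the pyrrole water replacing Tyr263 at the D-ring.  What passing
tests show is therefore parameter *recovery* -- the analysis stack re-derives
the planted structure -- not agreement with real force-field dynamics: the
generator has no autocorrelation within a state, no back-transitions, and
no coupling between features beyond cluster/state identity.

Analyses: kernel densities with a dip-type unimodality test (see below);
contact counts for the salt bridge with the 3 A atom-pair rule (H-bonds
otherwise use 3.5 A or indicator columns); PCA (components covering >=90%
variance) + Ward-linkage agglomerative clustering cut at K = 3, with a
k-nearest-neighbour connectivity graph above 4000 frames to keep the
linkage tractable, and first-appearance relabelling for determinism.  The
early->late lifetime is a censored exponential MLE over per-replica first
passages (sustained threshold crossing of Tyr263...Asp207 > 4 A for >= 10
frames, onset unbiased by half a frame interval) with a profile-likelihood
interval; at the packaged 100 ps frame interval and 2 us replicas the
estimator's dominant error is the tau/sqrt(n_events) sampling width.

**Dip statistic.**  No installed library provides a dip test, so the package
implements a paired-branch variant: for each candidate mode point, the
minimal uniform band half-width within which the ECDF admits a convex fit on
the points left of the mode and a concave fit right of it (each branch has a
closed form via the greatest convex minorant of the staircase bounds),
minimized over modes.  The classical dip additionally requires the two
branches to join into a single unimodal CDF; the paired-branch statistic is
a slightly smaller lower bound, but since the p-value is Monte-Carlo
calibrated against the uniform null with the same statistic (on a seeded
subsample of at most 2000 points), the test is exactly calibrated.  A
linear-programming oracle verifies the branch computation in the test suite.

## Surrogate IR spectra

Carbonyl-stretch frequencies come from an additive map: base CO_D/CO_A
frequencies (1720/1745 cm^-1) plus shifts for the isomerized chromophore
(-16/-2), a water H-bond to CO_D (-12) and a His290 H-bond (-4); water
coordination and isomerization red-shift the D-ring carbonyl, so frames that
lose the water H-bond (cluster Cl1) absorb above the water-bonded Cl0/Cl2
frames.  Ensemble spectra are per-frame Lorentzians (HWHM 6 cm^-1) on a
1650-1760 cm^-1 grid (0.5 cm^-1 step); cluster spectra combine by population
weight; the intermediate-minus-Pr difference supports a rigid shift
(positive values move the sample to higher wavenumber; 8 cm^-1 is the
conventional D2O-comparison shift) with interpolation back to the common
grid.  Map values are model conventions chosen for the sign structure of
the carbonyl bands -- the packaged difference spectrum has its positive
(intermediate) CO_D lobe below the negative (Pr) lobe -- not measured
quantities.

## Numerical choices and limitations

* dt = 0.1 fs everywhere; electronic propagation is exact for the
  trapezoidal local-diabatic Hamiltonian; norm drift < 1e-10 per step;
  microcanonical drift < 1e-3 kcal/mol over 10 ps at gamma = 0.
* Degenerate inputs: `r_hb <= 0` and non-finite values are rejected;
  kinetic energy in the decoherence rate is floored at 1e-8 kcal/mol;
  ties in clustering are broken by first appearance.
* The two-state model has an optional third-state hook only in the sense
  that the engine is written for two states by design; triplets, a third
  singlet, atomistic geometry, tongue refolding and later photocycle stages
  are out of scope.
* The quantum yield of the model is sensitive to the ground-state ridge
  height relative to the hot torsional tail; its calibrated value is a
  property of the packaged parameters, not a prediction for mutants.
* Lifetimes beyond ~100 ps are not simulated directly; statements about the
  6.2 kcal/mol barrier come from the fitted log-linear law.
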