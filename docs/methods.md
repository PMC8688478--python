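# Methods

`vesselflow` simulates pulsatile blood flow in compliant (elastic-walled)
vessels with a D3Q19 lattice Boltzmann solver, using a *localized* slip
boundary condition to mimic wall compliance instead of coupling to a solid
mechanics model, and verifies it against the analytical Womersley solutions
for oscillatory flow in rigid and thin-walled elastic tubes.

## Solver

**Lattice and collision.** Standard D3Q19 BGK: populations f_i stream to the
18 neighbours + rest direction and relax toward the second-order
Maxwell–Boltzmann equilibrium

    f_i^eq = w_i rho (1 + c_i.u/Cs^2 + (c_i.u)^2/(2 Cs^4) - |u|^2/(2 Cs^2))

with w_0 = 1/3, w_axis = 1/18, w_diag = 1/36 and Cs = 1/sqrt(3).  Lattice
viscosity nu = Cs^2 (tau - 1/2); `build_units(dx, tau, nu_physical)` picks
the time step dt = Cs^2 (tau - 1/2) dx^2 / nu so a target physical
viscosity is matched exactly.  All runs here use tau = 0.8 (nu_lat = 0.1),
a common stability/accuracy compromise for BGK.  The solver stores
post-collision populations over a flat list of population-carrying sites
and fuses pull-streaming with collision in a single numba kernel
(single-threaded, deterministic).

**Initialization and guards.** Runs start from equilibrium rest
(rho = 1, u = 0).  A low-Mach guard aborts when max |u| exceeds 0.1 Cs
(compressibility error grows as Ma^2; beyond this the weakly compressible
approximation is not trustworthy), and NaN/Inf populations raise a
divergence error naming the step.

**Geometry.** Domains are voxel masks classified into solid / fluid / wall /
inlet / outlet sites; cell centers sit at (i + 0.5) dx and the cylinder
generator passes the axis through a cell-center column so the staircase
cross-section has full symmetry and an exact centerline site.  Fluid sites
are strictly inside r < R; the wall is the single shell of non-fluid sites
with a fluid link.  Wall normals are estimated locally as the negative
normalized lattice-weighted sum of fluid-link directions; on voxelized
cylinders these are radial to ~11 degrees in the mean with a
resolution-independent staircase worst case near 30 degrees.  No global
surface knowledge is used anywhere — this locality is the point of the
method.

**Boundaries.**

* *Rigid walls*: halfway bounceback.
* *Elastic walls*: wall nodes are rebuilt every step in the
  Guo–Zheng–Shi (extrapolation) form at the near-wall branch Delta = 1:
  equilibrium at (rho_f, U_w) plus the designated fluid neighbour's
  non-equilibrium part, collided.  The slip velocity is
  U_w = ((F dx + dr - dx)/dr) U_f, the linear interpolation between the
  fluid node and a hypothetical wall dilated dr beyond it whose velocity is
  F U_f.  The boundary velocity ratio F comes from the elastic-tube
  solution, F = (1 - M) / (1 - M J0(Lambda(1 - dr/R))/J0(Lambda)), reduced
  to a scalar by its modulus (a real-part reduction is available; the two
  differ by <1% at alpha = 3).  F is precomputed and global by default; a
  dynamic mode re-evaluates dr per site each step from the neighbour
  pressure via dE = (1 - sigma^2) R^2 (p - P0)/(Y h), clamped to
  [dx, 0.1 R].  dr below dx is floored to dx, where the slip formula takes
  its natural boundary value U_w = F U_f; the floor is the default static
  behaviour.
* *Inlet/outlet planes*: non-equilibrium extrapolation — equilibrium at the
  target density (pressure BC) or target velocity profile (velocity BC,
  default parabolic weighting normalized to peak 1) combined with the
  interior neighbour's non-equilibrium part.

**Wall shear stress.** The deviatoric viscous stress is recovered locally
from the second moment of the non-equilibrium populations,
sigma' = -(tau - 1/2)/tau Pi^neq (no velocity-gradient stencils), and the
WSS is the tangential traction magnitude |t - (t.n)n| on the estimated
normal.  Evaluating at the adjacent fluid site reads the shear one link
inside the wall and under-reports the Poiseuille wall value by ~12% at
R = 12 dx, so the default estimator linearly extrapolates the stress tensor
to the wall node from the first two fluid sites along the designated link
(interior-mean ratio 0.92 of 2 mu Umax/R at R = 12 dx); the single-point
variant remains available as `mode="adjacent"`.

## Analytical oracle

The elastic-tube fields are the long-wave, linearized solutions for a
single pressure-gradient harmonic in a thin-walled, *untethered* tube:
pressure H e^{i omega (t - (z-z0)/c)} + p0 + k_s(z - z0), the axial and
radial velocities as Bessel-function profiles in Lambda = i^{3/2} alpha,
alpha = R sqrt(omega rho/mu), and physical fields as real parts.  The
elasticity factor M and complex wave speed c solve the thin-shell frequency
equation derived from the axial and radial membrane equations with axial
wall inertia retained (k = rho_wall h/(rho R)) and radial wall inertia
dropped (higher order in the long-wave parameter); eliminating the
stiffness parameter gives a quadratic in M whose physical branch tends to
M = 1 - sigma/2 and c = c0 = sqrt(Yh/(2 rho R)) (Moens–Korteweg) as
alpha -> inf with a massless wall.  An untethered tube's axial wall motion
does *not* vanish with stiffness — M is independent of Y — so the rigid
solution is the M -> 1 limit, not the Y -> inf limit.  Bessel functions of
complex argument come from scipy and are cross-validated against a
truncated power series in the tests.

The drive amplitude H is tied to the configured oscillatory
pressure-gradient amplitude by H = i c k_p / omega, which makes the
oscillatory gradient equal k_p e^{i omega (t - (z-z0)/c)}.  Under this
convention the lowest-velocity phases of the period fall at 0.435 and
0.952 — the verification samples at fractions {0.05, 0.25, 0.45, 0.71,
0.97} therefore bracket the extremes of the cycle.

## Verification protocol

The verification case is a cylinder of radius 3 mm, wall thickness 0.1 R,
Y = 20 kPa, sigma = 0.5, wall and fluid density 1000 kg/m^3, viscosity
0.004 Pa s, driven by an oscillatory pressure gradient of amplitude
50 Pa/m with period pi/2 s (Womersley number 3.0).  Desk-scale resolution:
R = 24 dx, length 6 R, tau = 0.8 (about 4021 steps per period, 258k fluid
sites; a full elastic run takes a few minutes on one core).  The paper-scale
resolutions (R = 50-200 dx) and the patient-specific forearm geometry are
out of scope at desk scale.

The drive is imposed as the *analytic inlet/outlet pressure difference*
Delta_p(t) = Re[H (1 - e^{-i omega L/c}) e^{i omega t}], split
antisymmetrically between the end planes.  Only the differential drives the
incompressible dynamics; imposing the full pressure wave (common mode
~10 Pa against a lattice pressure scale of ~10-100 Pa) would force a large
global density oscillation in a weakly compressible solver.  A linear ramp
over the first half warm-up period avoids shocking the rest state; three
full warm-up periods precede the measured period, with cycle-to-cycle peak
drift > 1% flagging non-convergence (measured drift: 0.6% elastic, 0.1%
rigid).

Profiles are sampled at fluid-cell centers along the central cross-plane
diameter and the centerline (trilinear interpolation, exact at centers) at
five phase fractions of the measured period, and compared against the
elastic analytical solution with the peak-normalized magnitude metric
error[%] = 100 (|V_LBM| - |V_theory|)/max|V_theory|.

## Measured accuracy and known limitations

* Staircase walls are first-order: the bounceback effective no-slip radius
  of the voxelized cylinder is ~R - 0.27 dx, giving ~5% centerline and
  ~8.5% max error against the nominal-radius parabola at R = 10 dx,
  decreasing under refinement.  Wall-node no-slip (the elastic condition at
  F = 0) puts its surface ~dx/2 further out, so the two rigid-wall schemes
  legitimately differ by ~10% of peak at R = 10 dx.
* The boundary velocity ratio must match the resolution: F is the analytic
  velocity ratio across one near-wall spacing, so the appropriate value at
  dE = dx/R = 1/24 is |F| = 0.744, not the 0.85 used at the paper-scale
  resolutions (dE ~ 1-2%).  At R = 24 dx the elastic run achieves 4-5%
  center-plane error at the strong-flow phases with F = 0.744, versus
  14-25% with F = 0.85.  The worst phase is always the one just after flow
  reversal, where the scalar reduction of F discards the complex ratio's
  phase lead.
* The low-velocity phases (0.45, 0.97 of the period) show large *relative*
  errors by construction of the metric (small normalizer), matching the
  expectation that errors are magnified there.
* The synthetic voxel cylinder exercises the full solver path but not
  image-derived geometry irregularity, vessel taper, branching, or
  non-Newtonian rheology; passing verification shows the boundary scheme
  reproduces compliant-tube physics in idealized vessels, not clinical
  accuracy in patient-specific anatomies.
* WSS comparisons between rigid and elastic runs are qualitative: rigid
  walls record higher instantaneous WSS, most prominently at high stress
  magnitudes (measured: top-quartile mean 1.7x at pilot scale).

## Numerical choices

Double precision throughout; no randomness anywhere in the solver
(identical configs give bit-identical outputs).  Per-step cost is one fused
stream+collide kernel pass plus small boundary kernels; the Mach guard and
mass/NaN check run every step.  Degenerate inputs (tau <= 1/2, F outside
[0,1], |sigma| >= 1, r > R, disconnected or laterally unbounded fluid
masks, fluid-free cylinders) raise typed errors rather than proceeding.
Ties in the designated-neighbour choice (fluid link best aligned with the
inward normal) resolve to the lowest direction index.
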