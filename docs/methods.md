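# Methods

## The reconstruction problem

SPECT measures gamma-camera projections `g_i` of a radiotracer distribution
`f_j`. Two physical effects corrupt the photopeak data: tissue attenuation
removes primary photons along each ray, and Compton scatter adds photons
that lost energy but still fall inside the acceptance window. Both must be
modelled for quantitative reconstruction.

The measurement model per detection bin is Poisson,

    E(g_i) = SC_i + Σ_k a^μ_ik f_k,

where `a^μ_ij = a_ij exp(−Σ_k r_ik μ_k)` is the attenuated system matrix and
`SC_i = Σ_j β_ij f_j` the expected first-order scatter. Because SC is linear
in the activity, the log likelihood

    L(f) = Σ_i [ g_i ln(SC_i + (A^μ f)_i) − SC_i − (A^μ f)_i − ln g_i! ]

has score

    ∂L/∂f_j = Σ_i [ g_i (β_ij + a^μ_ij) / (SC_i + (A^μ f)_i) − β_ij − a^μ_ij ],

and the multiplicative update that drives this score to zero is

    f_j ← (f_j / Σ_i a^μ_ij) Σ_i [ g_i (β_ij + a^μ_ij) / (SC_i + (A^μ f)_i) − β_ij ].

This is the scatter-gradient update (`proposed_update`, methods `new1`/
`new3`). Setting β = SC = 0 recovers plain MLEM exactly; freezing SC in the
denominator only gives the conventional scatter-corrected update. We define
β_ij ≡ ∂SC_i/∂f_j — this is the only reading under which the stationarity
condition is the exact gradient of the likelihood, which the tests verify
by finite differences.

Note on the interpretation of the three corrected variants: `conventional`
is exact EM for the model with a *fixed* additive scatter mean (its
likelihood ascent is guaranteed and tested); the scatter-gradient update is
the fixed-point iteration of the full score in which SC varies with f. Its
subtraction term can drive pixels negative; negatives are clamped to zero
by default (`clamp_negative`), which preserves Poisson-mean feasibility.
The paper-gap here — how the original work handled negatives — is resolved
by the clamp and exposed as a flag.

## Projector

Parallel-beam geometry, one ray per detector bin through the bin centre,
Siddon-style intersection lengths as `a_ij` (cm). Conventions: pixel centres
at `(i+0.5)·pixel_size` from the grid corner, the grid centred on the world
origin; detector bins aligned with image columns at 0°, camera rotating
counter-clockwise; sinograms flatten angle-major / bin-fastest. Attenuation
line integrals run from the emitting pixel's centre to the detector and
*exclude* the emitting pixel's own chord (self-attenuation over the
emitting pixel is not modelled; the alternative reading would add at most
half a pixel of water ≈ 1% per pixel and is absorbed by the same
convention on both simulation and correction sides). No collimator blur or
depth-dependent response is modelled.

## Scatter kernel

Single-scatter, collimated-exit model: a photon emitted in pixel j reaches
a site s on detection ray i (geometric spreading 1/d², first-leg
attenuation at 140 keV), Compton-scatters there by the angle θ between
j→s and the ray direction with the Klein–Nishina differential cross
section, passes the energy window with the acceptance of its degraded
energy E′(θ), and is attenuated along the ray to the detector with μ
rescaled to E′ via a built-in water μ(E) table (NIST values, log-linear
interpolation, 50–160 keV). Electron density is inferred from the μ-map as
`ρ_e = ρ_e,water · μ/μ_water(140 keV)` — the μ-map is the only medium
information available.

Normalisation: for a parallel-hole collimator the detector acceptance
solid angle is distance-independent and identical for primary and
scattered photons, so it cancels when the kernel is expressed in the same
chord-length units as the system matrix. The kernel is therefore assembled
per unit emission with the fine-pixel volume and the emission solid-angle
factor only, making β and A^μ directly commensurate in the update rules.
Everything the single-scatter geometry misses (higher orders, out-of-slab
scatter, the absolute collimator constant) is carried by one dimensionless
`scale` factor. The experiment driver calibrates `scale` once per phantom
so that the noise-free scatter-to-primary count ratio of the true activity
equals 0.30, a standard photopeak scatter fraction for Tc-99m with a 20%
window; the same calibrated kernel is used to simulate and to correct
(a `sim_scatter_mismatch` knob de-tunes the simulation side when one wants
correction and simulation models to differ).

Defaults: hard 126–154 keV window (20% at 140 keV; Gaussian acceptance
with 9.5% FWHM optional), single scatter only, `scatter_grid_factor = 2`
(scatter computed on a 2× coarsened grid, emission positions at coarse-cell
centres, kernel expanded back to fine pixels — exact at factor 1, which is
what the brute-force oracle tests use). The kernel is built once per
reconstruction (it depends only on μ, geometry and window); SC is refreshed
from the running estimate every iteration (`sc_cadence`).

The 3-slice mode lets the slices directly above and below each slice emit
into its detection rays: out-of-plane distances are folded into the
scattering angle and the first attenuation leg (in-plane path integral
stretched by the 3-D/2-D length ratio, using the detection slice's μ —
adequate for the near-constant axial profiles the phantoms use).
Contributions with zero emission-to-site distance are skipped (direction
undefined; absorbed by `scale`).

## CT → μ

Standard bilinear mapping: water/air mixtures below the breakpoint (0 HU),
water/bone above, continuous at the breakpoint, floored at zero.
`μ_water(140 keV) = 0.1538 cm⁻¹` from the built-in table; the bone slope is
pinned so 1000 HU lands at cortical bone (≈ 0.295 cm⁻¹ at 140 keV). Both
constants and the breakpoint are calibration fields, not hard-coded.

## Phantoms and simulator

The NEMA IQ phantom uses the standard IEC body proportions (30 × 23 cm
ellipse), six spheres of 10/13/17/22/28/37 mm inner diameter on a
11.44 cm-diameter ring, a 5 cm low-density central insert; the four
smallest spheres are hot at 8:1, the two largest cold. The torso surrogate
is built from ellipses and annuli — body, two lungs, myocardial ring,
gallbladder, liver, spleen — with activities 100/100/40/22/6/6 and a
140 keV μ-map (water for soft tissue, 0.04 cm⁻¹ for lung). It is *not* the
NURBS anthropomorphic phantom: organ shapes are qualitative, but per-organ
means are exact by construction (ownership masks), which is what the metric
tests rely on. Slices are replicated axially (constant-profile slab), so
passing tests say nothing about axially varying anatomy.

The simulator draws per-bin Poisson counts around `A^μ f + β f`, globally
rescaled to a count budget (default 5 × 10⁵ per slice), from one seeded
generator; primary-only and scatter expectations are returned for oracle
tests. The "reference" sinogram contains unattenuated primaries by default,
so plain MLEM on it is a meaningful comparator image (attenuated-primary
mode behind a flag).

What the simulator does not emulate: Monte Carlo photon transport,
multiple-order and out-of-field scatter, collimator septal penetration,
detector blur and dead time. Passing the directional tests shows the
update rules behave as designed under a consistent single-scatter model,
not that the exact published improvement percentages transfer to scanner
data.

## Metrics

Contrast `Ctr = mean(hot)/mean(background) − 1`; MSE is the plain pixel
mean of squared differences against the reference reconstruction; SNR is
mean signal over background standard deviation; CRC = (m_l − m_b)/(m_b(C−1));
CoV = background stdev/mean; CNR = CRC/CoV. Standard deviations use the
population convention (÷ n). Hot ROIs are region masks eroded by one pixel
(skipped when erosion would empty the mask); background ROIs are the body
minus the dilated union of all lesions/organs. Before MSE, images are
normalised to the true activity's mean inside the body mask (the
reconstructions live in count units, the truth in activity units; the other
metrics are scale-invariant). Per-iteration wall time is reported (median)
but never asserted on.

## Numerical choices

* ε = 1e-12 guards every denominator; pixels with zero sensitivity stay 0.
* f⁰ = 1 everywhere; fixed iteration count (default 50; 200 for the
  noise-free recovery check) — no stopping rule, matching clinical MLEM use.
* `ln g!` via `scipy.special.gammaln`; bins with zero model mean and zero
  counts contribute 0, zero mean with positive counts raises.
* The Klein–Nishina total cross section switches from the closed form to a
  low-energy series below E/m_ec² = 1e-3 (the closed form cancels
  catastrophically there); the two branches agree to ~1e-9 at the switch.
* Attenuation line integrals inside the scatter kernel use midpoint
  sampling at half a (coarse) pixel step — the same rule the brute-force
  test oracle implements independently.

## Problem sizes

Unit and property tests run on grids ≤ 16×16. The seeded end-to-end studies
use NEMA at 64×64 × 3 slices and the torso surrogate at 48×48 × 3, with 60
views, 50 iterations, 5 × 10⁵ counts per slice and 5 seeds — sizes at which
every stage (kernel build included) completes in seconds to tens of seconds
on one CPU while the spheres/organs remain several pixels across.

## Known limitations

2-D slice geometry with an axial slab approximation for inter-slice
scatter; single scatter only; no collimator-detector response; electron
density proxied by μ; the surrogate torso is geometric, not anatomical; the
scatter fraction is calibrated, not derived from absolute collimator
efficiency.
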