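# Methods

This note records the models, conventions and numerical choices behind
`slabpol`, in the order the pipeline runs them.

## Units and constants

Internal units are nm, elementary charges (e) and volts throughout.
The single conversion constant is the vacuum permittivity
`ε0 = 0.0552635 e V⁻¹ nm⁻¹` (`slabpol.constants.EPS0`).  MDAnalysis
readers return Å; everything is converted to nm on load.

## Molecular moments and the M-scheme

Molecules are grouped by residue records (GRO/PDB) or by the topology
sidecar's `molecules` block (XYZ).  Per molecule, about a designated
center atom c:

- dipole `μ = Σ qᵢ (rᵢ − r_c)` — independent of the center for
  net-neutral molecules (tested to 1e-12 under translation);
- traceless quadrupole `θ_zz = ½ Σ qᵢ (3 z′ᵢ² − |r′ᵢ|²)` in the
  ½(3z²−r²) Cartesian convention — center-dependent by construction,
  guarded by the isotropy null (⟨θ_zz⟩ → 0 under random rotations).

The center is the molecule's single van der Waals site where one exists
(the O atom of three-site water); multi-site species (the DMSO-like
template) require an explicit `center_atom` — there is deliberately no
silent default, because profile features shift with the center choice.
Lateral periodic images are resolved by minimum image about the center;
the slab axis is never wrapped across the vacuum gap.

## Profiles

Quantities are binned at molecular centers into uniform z bins spanning
the whole box (the requested width is snapped so bins tile the box
exactly; default 0.05 nm).  `P1 = ρ⟨μ_z⟩` and `Qzz = ρ⟨θ_zz⟩` are
sums over molecules divided by `A·Δz·n_frames`; `P = P1 − dQzz/dz` uses
order-2 central differences (one-sided at the ends) with no smoothing —
reproducibility is preferred over aesthetics.  Frames are weighted
equally; no decorrelation analysis is attempted.

## Interfacial potential

With no free charge between the midplane and a wall inside the liquid,
the solvent-polarization potential referenced to the bulk
(`φ(z_mid) = 0`) is

    φ_md = (1/ε0) ∫_{z_mid}^{z_s} P1(z) dz          (signed in z),

so a uniformly polarized layer of thickness L gives `φ = P·L/ε0` and a
layer with negative sites wallward gives `φ0 < 0`.  Only the dipolar
term is integrated: the quadrupole term telescopes to the boundary
difference of `Qzz`, which vanishes when both endpoints lie in empty
bins; it is computed as a diagnostic but never added.

The continuum reference subtracted for charged walls is

    φ_cont = (1/ε0) [ P_mid (z_int − z_mid)
                      + σ_eff (ε_int−1)/ε_int (z_s − z_int) ],

where `P_mid` embeds `ε_mid` via `P_mid = σ_eff (ε_mid−1)/ε_mid` and
`σ_eff = −σ_wall` is the continuum drive along the outward direction
(the same expression for either wall).  The interfacial zone
`(z_int, z_s)` defaults to `ε_int = 1` (effectively nonpolarizable);
the parameter is exposed and a test verifies that doubling it moves
`φ_int` by far less than the potential scale of the interface.

Numerical conventions, chosen for determinism on binned data:

- `P(z_mid)` is estimated as the mean of `P1` over the central half of
  the midplane-to-surface span, not a single bin: at `ε ≈ 80` the
  denominator `σ − P_mid` is ~1% of `σ`, so a single-bin read makes
  `ε_mid` unusable.
- "finally drops/falls below" (the `z_int` rule) is the *last*
  above-to-below crossing scanning outward from the midplane, located
  at the shared bin edge (exact for step profiles).  A bin counts as
  below threshold only beyond a small tolerance (2% of bulk for the
  density rule; `max(2%, 3× bulk bin scatter)` for the P1 rule), so
  profiles sitting exactly at their bulk value do not generate spurious
  crossings.
- `z_s` is the first profile point at which the density vanishes
  (< 1e-4 × bulk).  Because profiles live on bin centers, integrating
  to this point captures the half-filled edge bin correctly.
- The flat (P1-crossing) rule falls back to the density rule when no
  robust P1 crossing exists — the `σ = 0` degenerate case.
- All integrals are trapezoids on the bin-center grid; no splines.

For rough charged surfaces the discrete deprotonation charges enter the
analysis only through `P(z_mid)` and the planes; no separate continuum
placement of those charges is attempted.

## Free energy and the interaction model

`f(σ)` is the cumulative trapezoid of `φ_int(σ)` from σ = 0 (which is
exact for the linear model, hence the 1e-12 closed-form test).  The
linear fit `(φ0, k)` uses the weak-charging window |σ| ≤ 0.3 e/nm²
(configurable); `σ_max = −φ0/k` is suppressed when the slope is within
2 standard errors of zero.  Note the low-charge approximation
`f ≈ φ0σ` carries a relative error `|kσ/(2φ0)|`; the nonmonotonic peak
on the weakly negative branch requires `k < 0` together with `φ0 < 0`.
k is always estimated from data, never hard-coded.  The interaction
model's stationary point `x* = ln(Aκ_el/(−Bκ_int))/(κ_el − κ_int)`
exists only for `B < 0`.

## ITIM

Probe spheres of radius R (default 0.15 nm for water-like solvents,
0.20 nm for the DMSO-like template) descend along one streamline per
node of a lateral grid (default mesh 0.02 nm).  A probe touches an atom
of vdW radius r when the centers are r + R apart; tangency heights are
analytic (`z_a ± sqrt((r+R)² − d²)`), lateral distances are
minimum-image.  The first-touched atom's molecule joins layer 1;
removing assigned molecules and repeating yields deeper layers (default
4).  Ties within 1e-9 nm put both molecules in the layer —
order-independent.  Streamlines run from the empty side toward the
surface analysed, so layer 1 is always wall-adjacent; two-sided systems
are analysed per side.  There is no randomness: assignments are
bit-reproducible, and an independent exhaustive oracle (bisection on
the sphere-overlap predicate) reproduces them exactly on random
configurations.

The instantaneous surface is the probe-center tangency height of the
layer-1 molecules over the grid (gaps marked, fillable by neighbour
averaging).  Intrinsic profiles bin against `ξ = s·(z − h(x,y))` with
the nearest grid node's height, ξ = 0 on the surface and negative into
the liquid.  The Gibbs dividing surface is the equimolar plane of a
density profile, with bulk taken as the central 25% of the occupied
support (bins treated as boxes — midpoint rule, exact for a linear
decay); roughness is the RMS height deviation from it.

## Hydrogen bonds and orientations

A bond requires donor-heavy-to-acceptor-heavy distance < 0.3 nm
(strict) and donor−H···acceptor angle at the H > 150° (strict);
H-to-acceptor distance variants are deliberately rejected.  Donors and
acceptors are enumerated from molecule templates (every H paired with
its nearest heavy atom; negatively charged heavy atoms accept) plus the
descriptor's frozen surface-group inventory.  Surface bonds are type 1
when a surface heavy atom accepts (bridge-type acceptors included) and
type 2 when a surface group donates.  `θ′ = cos⁻¹(⟨μ̂⟩·n_z)` uses the
raw mean of unit dipoles — no renormalisation before the dot product,
the literal reading of the formula.  Donor/acceptor splits take the
molecules acting in that role per frame; ⟨N_H⟩ counts each bond once
per participating molecule and divides by the per-frame layer
population; the bulk reference uses a 0.3 nm slab at the box centre.

## Synthetic generator

The generator emulates the *one-body* statistics the analyses consume:
molecular centers with a prescribed density ρ(z) (uniform or shaped),
orientations from the tilted law `p(cosθ) ∝ exp(a(z) cosθ)` with
uniform azimuth and spin, walls at the liquid edges, and optionally a
frozen rough decorated surface (lattice base atoms on a sinusoidal or
filtered-noise height field, hydroxyl groups at random sites, a
deprotonated fraction carrying −1 e each so that σ = −count/area).
Placement is ideal-gas-like with hard-overlap rejection at 0.22 nm
between centers (and against vdW-carrying surface atoms); liquid–liquid
pair correlations are intentionally absent because every contract under
test depends on one-body fields only.

Orientation sampling uses the closed-form inverse CDF of the tilted
law, so the marginal is exact, and is *stratified*: one z-stratum per
molecule (inverse CDF of ρ), and within each stratum the three
orientation uniforms are Latin-hypercube stratified across frames.
This is the design that makes the generator an oracle at desk scale:
with ~1e5 samples, independent sampling leaves ~25% Monte-Carlo error
on a planted φ0 and ~0.1 V on the capacitor null, which would drown the
quantities under test; stratification drives the estimator error to
the 0.1% level without touching any marginal distribution.  Planted
truths (ρ(z), P1(z) = ρ|μ|L(a), φ0 per wall by quadrature) are recorded
alongside the frames.  Frames are deterministic in (spec, seed).

The linear-response capacitor chooses a uniform bias a* by root-finding
`ρ|μ|L(a*) = σ(ε−1)/ε`, erroring beyond the saturation polarization
ρ|μ|.  Rough surfaces record their construction planes (the extrema of
the solvent-accessible ceiling under the surface atoms) for the
plane-location tests, and can plant a bias within a band below the
*local* ceiling — the rough analogue of a wall layer — used by the
intrinsic-profile and hydrogen-bond trend tests.

What passing on synthetic data does and does not show: the pipeline's
algebra, conventions, estimators and geometry are verified against
closed forms; nothing here validates force fields, many-body structure,
dynamics, or sampling adequacy of real MD trajectories.  Real systems
add pair correlations (layering), finite-time correlations between
frames, and polarizability, none of which the generator emulates.

## Problem sizes

The shipped tests and the acceptance script use 2×2×4 nm³ slabs
(528 molecules, 200 frames) for planted-φ0 and null checks, a 3×3×4 nm³
box for the capacitor null (chosen so the stratified-error budget puts
the 5% `ε_mid` band at a >2σ margin), 100 random ≤12-molecule
configurations for ITIM oracle equivalence at the default 0.02 nm mesh,
and closed-form grids elsewhere.  These sizes are the package's own
validation conditions; larger systems only reduce the estimator noise
further.

## Known limitations

- The topology sidecar is package-specific; engine-native binary
  topologies are not parsed, and no force-field energetics exist.
- Electrode/vacuum-referenced potentials and non-traceless (Bethe)
  quadrupole potentials are out of scope by design.
- `z_int` is not unique physically; the density/P1 crossing rules above
  are one deterministic choice, and charged-surface results inherit a
  dependence on it (the uncharged `φ0` does not).
- ITIM height maps use probe-center heights; subtracting the probe
  radius is a constant shift left to the caller.
- The DMSO-like template is a 4-site stand-in for planting
  opposite-sign asymmetry, not a parametrised solvent model.
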