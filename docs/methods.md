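# Methods

This note records the model assumptions, parameter choices, numerical
conventions, and known limitations of `canopyflux`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Clear-sky irradiance model

Shortwave irradiance on a horizontal surface is the sum of a direct beam
and three diffuse parts:

- **Direct**: I_direct = 0.9751 · I_sc · r₀ · τ_r τ_o τ_g τ_w τ_a · sin θ_a.
  The 0.9751 factor restricts the solar constant (I_sc = 1367 W/m²) to the
  0.3–3 µm band. The five broadband transmittances follow the Iqbal
  parametric ("Model C") forms: Rayleigh and uniformly-mixed-gas
  transmittances from the relative air mass (Kasten formula, standard
  pressure), ozone from the ozone column (atm-cm), water vapour from
  precipitable water (cm), and aerosol from horizontal visibility (km,
  valid 5–180 km).
- **Rayleigh diffuse**: I_dr = I_sc r₀ τ_o τ_g τ_w τ_aa (1−τ_r) sin θ_a /
  (2(1 − m + m^1.02)), with the aerosol-absorption transmittance
  τ_aa = 1 − (1−ω₀)(1 − m + m^1.02)(1−τ_a), ω₀ = 0.9.
- **Aerosol diffuse**: I_da = 0.79 · I_sc r₀ τ_o τ_g τ_w τ_aa F_c (1−τ_as)
  sin θ_a / (1 − m + m^1.02), with forward-scatter fraction F_c = 0.84,
  τ_as = τ_a/τ_aa, and the 0.79 factor for soot-containing urban aerosol.
- **Multiple reflection**: I_dm = (I_direct + I_dr + I_da) ρ_g ρ_a /
  (1 − ρ_g ρ_a), sky albedo ρ_a = 0.0685 + (1−F_c)(1−τ_as). The model
  raises an error if ρ_g ρ_a ≥ 1 (divergent series).

Note the Rayleigh diffuse term deliberately carries no 0.79 factor; only
the aerosol term does. This mirrors the published formulation this package
follows, which differs from the textbook Model C where 0.79 multiplies
both terms.

**Atmospheric defaults.** Ozone (0.35 atm-cm, mid-latitude summer column),
precipitable water (4.0 cm, humid subtropical early summer) and ground
albedo (0.2) were fixed a priori; visibility was then solved once
(`scripts/calibrate_atmosphere.py`) so that the June-15 solar-noon total at
the reference site (32.076° N) equals 920.26 W/m², giving 6.2 km — a hazy
humid urban summer atmosphere. These four values are frozen as the
`AtmosphericParams` defaults and are a site calibration, not physical
constants.

## Solar geometry conventions

Declination and the Earth-orbit eccentricity factor come from the Spencer
truncated Fourier series. "Local solar time" is taken literally: the hour
angle is 15°·(t − 12) with no equation-of-time or longitude correction.
Azimuth is measured clockwise from north in [0, 360), morning values east
(< 180°), resolved from the standard arccos expression with the sign of
the hour angle. The beam direction is the unit vector from Sun to ground
in an (x east, y north, z up) frame. All interfaces speak degrees.

## Crown primitives and surface mesh

Conifer crowns are cones with apex at the tree top and elliptical base
(half-widths a east–west, b north–south) at the clear bole height;
broadleaf crowns are the upper half of an ellipsoid centred at the clear
bole height. Only this upper/outer sheet exists — no base disc, no trunk,
no interior foliage — so rays below the clear bole height pass freely
under a crown. Crowns of neighbouring trees may interpenetrate; occlusion
is resolved by first-hit ray casting, not by geometry clipping.

Meshing samples each footprint with a centre point plus concentric
elliptical rings (ring r at fraction r/n of the half-widths, ξ points
equally spaced in parametric angle), triangulates the samples with planar
Delaunay (`scipy.spatial.Delaunay`), and lifts each vertex onto the crown
surface. The ring count follows the *meridian* arc length (cone slant
height, quarter-ellipse arc for semiellipsoids) so the default target
vertex spacing of 1.36 m is controlled along the 3-D surface rather than
in plan view; ξ follows the footprint perimeter (Ramanujan approximation).
Facet normals are vertex cross products re-oriented outward (non-negative
z on an upper sheet, with the stored winding flipped to agree); zero-area
slivers, which Delaunay produces at the cone apex where the centre sample
*is* the apex, are dropped. At the default spacing a 60-tree conifer stand
resolves into roughly 3×10⁴ facets, and the inscribed-polygon mesh area
converges to the analytic lateral surface from below as the spacing is
refined (within 2 % of the closed-form cone area at 0.15 m).

## Beam tracing

Primary beams form a cell-centered lattice on a horizontal source plane
(conceptually 800 m × 800 m, 100 m above ground; default spacing 0.2 m,
i.e. ℓ = 25 beams/m²), all sharing the current solar direction and each
carrying I_total/ℓ watts. The lattice is culled to cells whose rays can
reach the scene's bounding box (crowns plus the plot's ground rectangle);
cells are always taken from the fixed global lattice, so culling is
provably hit-preserving and is verified against the uncalled lattice in
tests. Ground-reaching beams are tallied but carry no flux; their count is
relative to the culled footprint.

Ray–facet intersection solves the facet-plane equation (t = N·(p₁−o)/F,
F = N·d) with a parallel tolerance of |F| < 10⁻¹² after normalization and
a same-side cross-product inside test; the batched tracer uses the
algebraically equivalent Möller–Trumbore form with barycentric slack
10⁻¹². First-hit resolution takes the minimal positive t, ties to the
lowest facet index. The accelerated path (numba kernel over per-tree
axis-aligned bounding boxes, exploiting the per-tree contiguity of facet
indices) is contract-equivalent to the exhaustive all-pairs path, and the
test suite asserts exact hit-set equality on batches of random scenes.

Each first hit spawns exactly one specular reflection
(r = d − 2(d·n)n, which may re-hit the originating tree but not the
originating facet) and one Snell refraction
(t = e·d + (e·c₁ − c₂)·n, c₁ = −n·d, c₂ = √(1 − e²(1 − c₁²)), e = 0.5;
the transmitted ray skips every facet of the originating tree, modelling
passage through the whole crown onto the trees behind). Secondary origins
are offset 10⁻⁶ m along the new direction to avoid self-intersection.
Recursion stops after this single bounce. Facet normals are stored
outward/upward; where a stored normal does not oppose an incoming ray it
is flipped locally before the reflection/refraction algebra.

## Flux accounting

Per-beam power is fixed at I_total/ℓ regardless of sun obliquity. A first
hit deposits (I_total/ℓ)·cos θ on its facet, θ being the angle between the
beam and the facet normal folded into [0°, 90°] (outward normals against
downward beams would otherwise make every angle obtuse). Second-bounce
hits deposit additionally weighted by ρ (reflected) or τ (transmitted) of
the species class of the crown that redirected the beam; a config switch
(`attribute_to="receiver"`) uses the receiving facet's species instead.
Shortwave band optics: ρ = 0.25 / τ = 0.15 for conifers, ρ = 0.17 /
τ = 0.20 for broadleaves.

Two consequences of this convention are worth stating plainly:

- **Conservation holds only under high sun.** Under a near-zenith sun,
  E_incident ≤ I_total × plot area (each beam deposits at most its own
  power and the beam set over the plot carries exactly I_total per m²);
  the flat-slab fixture recovers I_total × area to within the beam
  discretization (< 2 % at 0.2 m spacing). Under an oblique sun the
  20–30 m tall canopy *silhouette* also intercepts beams whose source
  cells lie outside the plot footprint, so the horizontal-plane bound does
  not apply — this is a property of the fixed per-beam power convention,
  not a tracer defect.
- **Facet-normal weighting penalizes steep crowns at high sun.** A cone
  with half-width a and depth c presents cos θ = a/√(a²+c²) to a vertical
  beam (≈ 0.29 for the single-cone fixture), while ellipsoid tops present
  cos θ ≈ 1. The simulated noon incident flux of a conifer stand is
  therefore *lower* than that of a broadleaf stand of similar cover, and a
  stand's diurnal incident-flux curve is not noon-peaked (the growing
  oblique footprint and near-unity side cosines outweigh the higher noon
  irradiance). Published stand-scale results that show noon-peaked,
  conifer-dominant fluxes are consistent instead with an effective
  cos θ = sin(solar altitude) weighting — i.e. cosines taken against
  vertical (projected) normals. `canopyflux` keeps the facet-normal
  formulation because it is the stated model and the geometrically
  meaningful one; the acceptance suite records which published orderings
  survive it (conifer reflected > transmitted does; noon maxima,
  June ≥ October, conifer > broadleaf incident, and broadleaf
  transmitted > reflected do not) rather than silently switching
  weightings to force agreement.

## Synthetic stands

The generator reproduces the three study-plot archetypes from their
published attribute *ranges* only (per-tree layouts are unpublished):
uniform independent draws of height, clear bole height and the two crown
half-widths within each range (half-widths are half the published crown
widths; the range construction already guarantees height > bole height),
and stem placement by minimum-spacing rejection sampling — 4 m for the
conifer stand, 5 m for broadleaf/mixed, chosen so canopy closure lands in
the dense-conifer / more-open-broadleaf regime on a 50 m × 50 m plot. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical tree
tables. What the generator does *not* emulate: spatial clustering beyond
minimum spacing, attribute correlations (e.g. taller trees having wider
crowns), segmentation error, or understory vegetation — so tests passing
on synthetic stands certify the pipeline's mechanics and orderings, not
site-specific absolute fluxes.

## Problem sizes used in the checks

The behavioural acceptance checks run at a reduced operating point chosen
once: 0.4 m beam spacing (the published sensitivity range is 0.1–0.4 m)
and the default 1.36 m mesh spacing for the 20-seed ordering ensembles; a
15-tree, 25 m × 25 m stand for the 0.4→0.2→0.1 m beam-refinement check;
2–4-tree scenes for the exact brute-force/accelerated equivalence sweeps.
The flat-slab conservation check runs at the full 0.2 m standard spacing.

## Known limitations

- Single-bounce specular transport only: no diffuse (cosine-lobe)
  scattering, no third-order rays, no in-crown Beer–Lambert attenuation.
- Diffuse sky irradiance enters the per-beam power but is transported
  along the direct beam direction, as in the source model.
- Ground interacts only through the albedo term of the irradiance model;
  ground-reflected rays are not traced.
- The hemispherical-photo module implements only the downstream
  interception arithmetic; sky-view fraction and direct transmissivity are
  inputs, not derived from imagery.
- No equation-of-time/timezone astronomy: schedules are in local solar
  time.
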