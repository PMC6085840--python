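# Methods

## Physical model

The sensor is a multimode silica fiber (core radius 5 µm) whose cladding is
locally removed and replaced by a 50 nm gold film, immersed in 1X
phosphate-buffered saline (n = 1.334).  Light guided by total internal
reflection carries an evanescent tail into the film and excites surface
plasmons at the gold/buffer interface; the plasmon resonance shows up as a
wavelength-selective absorption of the transmitted power.  A neuron's
transmembrane potential, applied to the gold as an electrode potential,
charges the interfacial double layer and modulates the film's free-electron
density, hence its Drude plasma frequency and the resonance position.

### Materials

Gold follows a single-Lorentz-pole Drude–Lorentz dispersion under the
`e^{−iωt}` convention (loss ⇔ Im ε > 0),

    ε(ω) = ε∞ − ω_D²/(ω² + iγ_D ω) − Δε·ω_L²/(ω² − ω_L² + iγ_L ω),

with the standard FDTD-oriented parameter set fitted to tabulated
experimental gold optical constants (Vial et al. 2005): ε∞ = 5.9673,
ω_D = 1.328×10¹⁶ rad/s, γ_D = 1.000×10¹⁴ rad/s, ω_L = 4.085×10¹⁵ rad/s,
γ_L = 6.588×10¹⁴ rad/s, Δε = 1.09.  At 633 nm this gives
ε = −11.74 + 1.22i, within a few percent of the measured values; the test
suite pins the agreement at 15% against a committed n,k table.  Silica uses
the Malitson Sellmeier fit; the cladding is depressed-index silica whose
index step is fixed by the numerical aperture at 633 nm; the buffer is a
constant-index dielectric.  All dispersion models declare a validity window
of 300–2000 nm and refuse wavelengths outside it.

### Charge model and its calibration

The double layer of areal capacitance C charged to potential V stores
surface charge σ = C·V, equivalent to an electron-density change
ΔN = C·V/(e·d) inside a charged layer of thickness d.  Defaults:
C = 0.2 F/m² (20 µF/cm², the canonical electrode double layer) and
d = 0.8 nm (the Debye screening length of 150 mM saline).  The sign
convention (positive electrode potential depletes electrons) is a config
flag.  Three localisation modes decide how ΔN enters the optics:

* **filmwide** (default): the density change ΔN = C·V/(e·d) modifies the
  plasma frequency of the *entire* 50 nm film.  This is the uniform-field
  treatment under which the sensor concept was analysed, and is what the
  default calibration assumes.  It is *not* charge-conserving: it scales
  the stored charge by the film/double-layer thickness ratio t/d ≈ 60.
* **surface_layer**: the same ΔN confined to an explicit sub-layer of
  thickness d at the gold/buffer interface (an extra layer in planar
  stacks; a thickness-weighted effective-medium correction of the film in
  the 2-D solver).  Charge-conserving.
* **uniform_film**: the stored charge spread through the film,
  ΔN = C·V/(e·t).  Charge-conserving.

An important scaling fact, established while calibrating: for any
charge-conserving localisation the resonance shift depends on the areal
charge C·V/e only — the layer thickness cancels (ΔN ∝ 1/d, perturbed
optical path ∝ d) — and because the perturbation lives inside the metal,
where the plasmon field is weak, the −100→+100 mV peak shift saturates
near 0.25 nm even at C = 50 µF/cm².  Sub-nanometre shifts for ±100 mV are
in line with published electro-optic SPR measurements.  Nanometre-scale
shifts require the film-wide treatment; with the default calibration the
planar engine yields 1.40 nm for the polished design and 1.42 nm for the
other two.  The package keeps the charge-conserving modes available so the
physically conservative answer is one config switch away.

## Geometry and meshing

Three cross-sections ("designs"): an annular gold shell on the bare core
(`full_clad_removed`); a fiber polished flat to the top of the core, gold
slab on the flat at y = +r, cladding intact below (`half_clad_removed`);
and a fiber polished through the axis, flat at y = 0
(`half_core_removed`).  Cross-sections are discretised on rectilinear
tensor grids, geometrically graded so that at least 5 cells span the gold
thickness along its normal; the computational window is a square of side
4× the core radius; material assignment is by cell centre with optional
4×4 sub-cell averaging of ε (on by default — it restores roughly
second-order convergence of region areas and interface-sensitive
eigenvalues against the staircase error).

## Planar engine

Reflectance uses Abelès characteristic matrices with the branch
Im k_z ≥ 0.  The fiber is idealised as the plane silica | gold [| charged
sub-layer] | buffer stack; a guided ray at internal angle θ (from the wall
normal) undergoes N(θ) = L/(D·tan θ) wall reflections over the sensing
length L, of which a design-dependent fraction f strikes the gold (f = 1
for the annular design; f = ½ for the two polished designs, whose gold
covers one side; the half-core design has transverse extent D = r instead
of 2r).  Transmission integrates R_p and R_s (50/50 unpolarised, p-only
configurable) over the guided range [θ_c, 89.5°] by 64-point
Gauss–Legendre quadrature with launch weighting P(θ) ∝ sin θ cos θ
("mode_power", the diffuse-source meridional distribution; a uniform-angle
option exists).  Absorbance is 1 − T over the sensing length — a total,
not per-length, quantity.

Defaults that are design choices of this package (they are stated nowhere
for the original device): numerical aperture 0.37, the standard value for
high-NA multimode sensor fiber — it sets the guided band
n_eff ∈ [1.409, 1.456] whose plasmon phase-matching window spans
~620–710 nm and puts the polished design's zero-volt absorption peak at
660 nm, inside the biological optical window; and sensing length 50 µm,
the neuron-contact scale, giving of order one gold bounce per ray so the
resonance dip does not saturate.  At millimetre sensing lengths the dip
saturates and the gold interband baseline below 550 nm dominates the
spectrum — with a 10 µm core, a millimetre of exposed gold is simply not a
wavelength-interrogating sensor any more.

## Modal engine

The 2-D solver discretises the curl-curl equation for the transverse
electric field on a staggered (Yee-like) grid, eliminating E_z through
∇·(εE) = 0; ε_x, ε_y live on the respective field points
(thickness-weighted averages of the neighbouring cells) and ε_z on cell
vertices.  The window boundary is a perfect electric conductor — adequate
for bound and plasmon-hybrid modes; leaky-mode absorbers are out of scope
and leaky losses are therefore not captured.  Eigenpairs come from sparse
shift-invert Arnoldi iteration (ARPACK) targeted at an effective-index
guess (the dielectric band edge by default, plus a second solve near the
analytic SPP index for the plasmonic branch); eigenvectors are
power-normalised, residuals are checked against 1e−8, and phase indices
above the largest material index are discarded as discretisation
artefacts.  Modes with Re n_eff between the cladding/buffer index and the
core index count as guided; absorbance aggregates their absorbed fractions
1 − e^{−αL}, α = 4π·Im n_eff/λ, with equal launch weights.

Validation (standing tests, not one-offs): a homogeneous map reproduces
the analytic PEC-box fundamental with O(h²) convergence; the 5 µm / NA
0.22 step-index fiber fundamental matches the exact hybrid-mode (HE11)
Bessel dispersion root to better than 1e−4; an extruded
silica | gold | water slab matches the 1-D transfer-matrix dispersion root
of the same PEC-terminated stack to 1% in both Re and Im of n_eff.  The
1-D oracle is formulated with PEC terminations matching the 2-D window
because the open stack's surface plasmon is leaky into silica
(Re n_spp < n_silica), so an open-pole comparison would be ill-posed
against a windowed solver.

For the multimode sensor cross-section the modal absorbance versus
wavelength is a comb of discrete mode/plasmon crossings whose individual
teeth shift with mesh; spectral positions are therefore summarised by the
absorbance-weighted centroid.  The centroid of the polished design agrees
with the planar stack's critical-angle resonance wavelength within 25 nm,
and the sign of its voltage-induced displacement matches the planar
engine's peak shift.

A note on the Kretschmann validation configuration: through a silica
prism the water-side SPP phase-matches only ~2° from grazing incidence,
where the 50 nm film's radiative loading displaces the reflectance dip by
about 2°.  The textbook dip-versus-phase-matching agreement (here 0.16°)
holds in the standard launch through a dense-flint prism (n = 1.723), and
that is the configuration the validation suite uses.

## Synthetic action potentials

Two generators, both deterministic: a piecewise-analytic template spike
(fast depolarising double-exponential plus a slower after-hyperpolarisation)
and a standard squid-axon Hodgkin–Huxley point neuron (C_m = 1 µF/cm²,
g_Na = 120, g_K = 36, g_L = 0.3 mS/cm², E_Na = 50, E_K = −77,
E_L = −54.387 mV) integrated with fixed-step RK4 under a current pulse.
Either waveform's full excursion is affinely mapped onto the configured
electrode range, ±100 mV by default, and applied to the gold with unity
coupling (`coupling_factor` records the neglected cleft attenuation).
What these waveforms emulate is the stereotyped shape and millisecond
timescale of a spike; they contain no channel noise, no electrode drift
and no extracellular attenuation, so a passing tracking test demonstrates
the transduction chain's linearity, not in-vivo detectability.

Intensity traces evaluate 1 − A(V(t)) at the excitation wavelength either
per sample or through a cubic spline over ≥5 potential knots (default 9;
the two paths agree to 1e−4 and the spline path is flagged in the trace's
provenance).

## Numerical choices

* Complex square roots take the decaying branch Im ≥ 0 everywhere.
* Peak localisation: grid argmax refined by a three-point parabola (exact
  on parabolas, exact at symmetric-triangle vertices); a maximum on the
  grid boundary raises rather than returning a fake peak.
* Spectra are grid-converged: refining the default 0.25 nm step moves the
  interpolated peak by < 0.05 nm.
* The 1-D dispersion-root search uses complex secant iteration on the
  transfer-matrix determinant, seeded at the analytic single-interface SPP
  index.
* Richardson-style two-resolution checks guard the solver's convergence
  order in the suite.

## Known limitations

* The film-wide charge model reproduces nanometre shifts at the cost of
  violating charge conservation; screening physics says the excess charge
  lives within ~1 Thomas–Fermi length of the surface, and the
  charge-conserving modes predict responses an order of magnitude smaller.
* The three designs respond almost identically per se (1.40 vs 1.42 nm):
  the ray bookkeeping distinguishes them only through bounce counts and
  the baseline, so reported cross-design shift ratios larger than ~1.05
  are outside what this planar engine can produce.
* No skew rays, no coherent inter-bounce interference, no surface
  roughness or adhesion layers, no PML (leaky losses absent from modal
  results), no thermal or electrochemical dynamics beyond the static
  capacitance map, no detector or shot noise.
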