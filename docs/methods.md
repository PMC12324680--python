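# Methods

## Field model

Each winding is discretized into filamentary circular loops, one per turn,
in square packing: layer *j* sits at radius `inner_radius + (j + ½)t` for
wire pitch *t*, each layer holds `floor(w/t)` turns spanning the winding
width, and a partial last layer fills from the axial start. Two choices
matter and are deliberate:

* **Mirror assembly.** The second winding is the mirror image of the first
  about the pair midplane. For full layers this is indistinguishable from a
  translated copy, but a partial last layer breaks a single winding's axial
  symmetry; mirroring restores the pair's, which is what makes the radial
  component vanish on the midplane. `pair_field` exploits this analytically
  (one winding evaluated at ±x, radial parts differenced), so
  `Br(0, r) = 0` holds *exactly* in floating point, not just to roundoff.
* **Centroid spacing.** The partial layer pulls a winding's turn centroid
  ~0.4 mm off its layout window center; layouts are re-centered so that the
  configured spacing is centroid-to-centroid of the turns.

Loop fields use the standard elliptic-integral closed form (see README) with
`scipy.special.ellipk/ellipe`; the exact on-axis branch is taken for
r < 10⁻¹² m to avoid the x/r factor, and points within 10⁻⁹ loop radii of
the filament raise a singular-point error. The convention ambiguity between
k and k² in transcribed formulas is settled by a brute-force Biot–Savart
segment-sum oracle (10⁵ straight segments, midpoint rule) kept in the test
suite, which agrees with the elliptic form to better than 10⁻⁶ relative at
random off-filament points — the oracle, not any transcription, is the
ground truth.

Homogeneity over a sample region is reported as `max |Ba − Ba(center)|`
(axial divergence) and `max |Br|` (radial divergence), the most literal
uniformity metrics; the mean axial field is reported alongside. The default
dish region is a cylinder of radius 17.5 mm and height 5 mm centered on the
midplane (a 35 mm dish with ~5 mm of medium), sampled on a 0.5 mm lattice
(3853 transverse points × 11 planes). A flat midplane disk has exactly zero
radial divergence by symmetry; the volume is what makes the radial number
nonzero.

**Known limitation — dish-scale uniformity.** The Helmholtz condition
cancels the field curvature at the center; the residual fourth-order term
still grows as (ρ/a)⁴. At dish edge ρ/a ≈ 0.40, this is intrinsically ~1.3 %
of the 2 mT center field (≈26 μT for an *ideal* point-loop pair, ≈28 μT for
the distributed winding). Uniformity figures in the few-μT range are only
achievable over a smaller central region (ρ ≲ 10 mm, where the ρ⁴ scaling
brings the deviation under ~3 μT); the package reports the full-dish
numbers as computed and makes the region configurable.

`helmholtz_spacing` finds the spacing zeroing the analytic on-axis second
derivative by bracketed root-finding (brentq on [0.2a, 5a], relative
tolerance 10⁻¹²); the distributed-winding variant minimizes the axial
divergence over a stated region by bounded scalar minimization and tracks
the mean turn radius (41.6 mm for the reference winding) rather than the
holder bore.

## Electrical model

A series RL branch with parameters R, L taken from measurement when
available. The measured 130 ms on+off toggle is ~400 time constants — it is
a property of the power supply, not of L/R — so it is treated as an input,
and the switching limit is the conservative largest integer frequency whose
period fits it: `floor(1/toggle) = 7 Hz` at 130 ms.

`estimate_inductance` is advisory (±tens of percent): Wheeler's multilayer
formula `L[μH] = 31.5 a²N²/(6a + 9l + 10b)` (SI meters) per winding, plus
Maxwell's coaxial-loop mutual term for the series pair. For the reference
geometry the per-winding estimate (~1.2 mH) lands within a factor 1.5 of
the measured 870 μH, while the series-pair estimate is ~2.6 mH; the printed
resistance and voltage drop are consistent with the *pair* (ΔV/I = 2.75 Ω ≈
R = 2.74 Ω), while the printed inductance is most consistent with a single
winding. Both readings are exposed via the `configuration` switch; measured
values always take precedence.

Wire resistance is predicted from ρL/A with the **bare-conductor** diameter
(0.644 mm for 22 AWG) rather than the 0.71 mm insulated packing pitch; the
two are separate `WireSpec` fields. Prediction for the reference pair:
2.59 Ω vs 2.74 Ω measured (+5.6 %, plausibly leads plus winding slack).

## Thermal model

Worst-case lumped balance: all I²R power enters the water, giving
ΔT = P/(ṁ c_p) with water properties c_p = 4181.3 J kg⁻¹ K⁻¹,
ρ = 997 kg m⁻³. At the 1 A / 1 L·min⁻¹ operating point this is 0.039 K —
the water flow makes Joule heating irrelevant to the culture.

Dew point uses the Magnus relation with the Sonntag 1990 constants
(a = 17.62, b = 243.12 °C), accurate to ~0.1 °C across incubator
conditions; 37 °C / 60 % RH gives 27.9 °C, which is why the cooling water
must run *warm* (at or near incubator temperature), not cold. The
condensation verdict compares the coolant inlet temperature (the coldest
wetted surface, since the water only warms downstream) with the dew point
plus an optional margin. Transient behavior, channel CFD and the incubator's
own humidity control are out of scope.

## Alignment score

Structure tensor from Gaussian-derivative gradients (σ_gradient = 1 px) with
Gaussian window smoothing, reflect boundary handling. Coherency is the
normalized eigenvalue anisotropy, clipped to [0, 1] and defined as 0 where
the tensor energy vanishes. The per-image score is 100 × the energy-weighted
mean coherency over pixels whose energy exceeds the 50th percentile of the
(masked) image — the percentile makes the score exactly invariant to global
intensity scaling, and the reflect-mode filters make it exactly invariant to
90° rotation.

**Window scale.** The smoothing window defaults to σ_window = 12 px for
scoring (the low-level `structure_tensor` keeps a generic 2 px default).
This is the one genuinely open design choice and it is load-bearing: with a
fiber-sized window every fiber is locally anisotropic, so any fibrous image
scores ≥ ~55 % regardless of whether the fibers agree in orientation, and
the score cannot work as a 0–100 % *alignment* level. With a window spanning
several fiber spacings, crossing orientations cancel inside the window and
the score becomes a measure of mutual alignment: measured on the synthetic
generator, smoothed isotropic noise scores ~12, isotropic fibers (κ = 0)
~27, strongly aligned fibers (κ = 1000) ~97, perfect stripes 100, and the
mean score is strictly monotone in the orientation concentration κ
(Spearman ρ = 1.0 over κ ∈ {0, 1, 2, 4, 8, 1000}, 10 seeds each). For real
micrographs the window should be set to a few times the fiber spacing in
pixels; it is exposed in the config and CLI.

## Synthetic fiber images

The generator emulates fluorescent F-actin micrographs: bright anti-aliased
line segments (Gaussian cross-profile, smooth end caps) summed over a dark
background with additive Gaussian noise, clipped nonnegative. Orientations
follow an *axial* von Mises distribution via angle doubling
(θ = μ + φ/2, φ ~ vonMises(0, κ)), the standard construction for
180°-periodic orientation data; κ = 0 is isotropic. Defaults — 150 fibers of
length 120 px and width 1.5 px in a 256×256 frame, noise SD 5 % of fiber
amplitude — give dense, partially overlapping fibers comparable to a
confluent stress-fiber field at typical magnification. A seed is mandatory
and images are bit-identical per seed.

What the generator does *not* emulate: cell boundaries and masks, curved or
branching fibers, intensity falloff, photobleaching, out-of-focus light, or
the empirical score distribution of real cell populations. Passing tests
therefore demonstrate that the pipeline recovers orientation order from
fiber-like images and that its statistics behave correctly — not that it
reproduces any particular biological dataset's numbers.

## Group statistics

Mann–Whitney U from pooled midranks. Exact two-sided p by enumerating all
C(n_a+n_b, n_a) labelings when min(n) ≤ 8 and the pool is tie-free (the
two-sided p counts labelings with U at least as extreme on either side);
otherwise the normal approximation with tie correction and a 0.5 continuity
correction. Both branches are cross-checked against an independent
implementation in the test suite, and the normal branch tracks exact
enumeration within 0.02 at n = 8 + 8. A fully constant pooled sample
returns p = 1 with a warning. Reported alongside: group medians and their
ratio, means and SDs (medians are the robust location summary for the
non-normal score distributions this pipeline produces).

Fluorescence ratios use first-order ("compound") error propagation,
sd = ratio·√((σ_e/μ_e)² + (σ_c/μ_c)²), and replicate ratios combine by
inverse-variance weighting with combined sd = (Σ sd_i⁻²)^{-½}; replicates
must carry positive uncertainties to be weighted.

## Numerical and I/O choices

SI units internally everywhere (T, m, A, s); mT/μT/mm only at interfaces
and in serialized reports. Field maps sample a square lattice (step
0.5 mm default) restricted to the region; identical (x, r) pairs are
evaluated once and scattered back, so area averages remain lattice-weighted
while axisymmetry keeps the cost at ~10⁴ elliptic evaluations per map
(well under a second). Configs are strict YAML with unit-suffixed keys;
unknown keys, missing sections and out-of-range values are all reported at
once. All randomness flows through explicit integer seeds; there is no
global RNG state.

Problem sizes used by the shipped checks — 0.5 mm lattices (3853-point
disk, 42383-point cylinder), 10⁵-segment oracle sums at 100 points,
10 seeds × 6 concentrations for parameter recovery — keep the whole suite
in the tens of seconds on one core while leaving the discretization errors
well below the tolerances being tested.
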