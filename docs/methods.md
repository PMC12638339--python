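# Methods

## Model

All simulations evolve a single magnetization vector **M** (units of M0)
under the Bloch equations in the rotating frame of the water resonance.
RF pulses are sequences of piecewise-constant segments: constant amplitude
ω₁ = γB1 (rad/s) and a linear phase ramp φ(t) = φ₀ + 2π f_RF t (the carrier
frequency offset is realized as phase modulation). Each segment is solved
exactly: transforming into the frame rotating with the carrier makes the
effective field (ω₁, 0, 2πΔf − 2πf_RF) constant, so the segment is one
axis-angle rotation. This propagator is verified in the test suite against
fixed-step RK4 integration of dM/dt = Ω(t) × M at ≤1 µs steps (agreement
better than 1e−6, in practice ~1e−13).

Relaxation is applied only during free precession (T2 decay of the
transverse part, T1 recovery of Mz toward 1); pulses act as
relaxation-free rotations of their stated duration. At the T2 ≫ pulse
duration regime of these protocols the error is negligible.

### Sign conventions, and where the published parameters disagree

Rotations are right-handed; spins at off-resonance Δf precess by +2πΔf·t
about +z; the second-subpulse phase offset Δφ₂ of a binomial pulse is a
jump applied on top of the boundary-continued carrier ramp. Only |Mxy| is
reported, so handedness must merely be self-consistent.

The binomial water-excitation literature quotes phase offsets in more than
one sign convention, and the 1.5 T parameter table this package defaults to
mixes them: under *any* single convention, the LIBOR offset (290°, optimized
by the same study that tabulated it) and the LIBRE formula value
(2π·f_RF·τ = 252.72° at 540 Hz / 1.3 ms) cannot both excite water — they
require opposite signs. We verified this by exhaustive scan over precession
sign, phase sign, subpulse-carrier sign, phase-continuation rule, gap and τ.
The package therefore fixes its own convention to the one in which the LIBOR
design reproduces (its phase sweep yields a wide fat-suppression band with
an argmax near 280–290°), and applies the LIBRE formula phase with the
opposite sign (effective jump −2πf_RF τ ≡ 107.28°), which is the unique
reading under which LIBRE functions as a water-excitation pulse here.
`libre_phase_offset` still returns the published-formula magnitude
(252.72° → "253°") for table compatibility. BORR's 180° is the same either
way.

### The LIBOR inter-subpulse gap

The protocol table lists a total RF duration of 2.7 ms for 2 × 1.3 ms
subpulses. We model LIBOR with the implied 0.1 ms inter-subpulse gap
(free precession, carrier phase coherent across the gap) because the pulse's
documented behavior is only jointly consistent with it: the calibrated
amplitude factor (1.55 vs 1.45 without the gap), the depth of the −220 Hz
null (residual 0.4% vs 8.3%), and — decisively — the steady-state behavior:
at TR 4.9 ms the fat resonance sits near a pass-band of the bSSFP
off-resonance profile, which amplifies a shallow single-pulse null to
15–20% of the pass-band signal, destroying fat suppression; with the gap
the steady-state fat residual is ~1%. BORR and LIBRE are modeled with
contiguous subpulses: with a 0.1 ms gap BORR becomes physically unable to
rotate water by 50° at any amplitude (its on-resonance rotation saturates at
46°), contradicting its routine scanner operation, and LIBRE degrades. The
gap is a per-pulse parameter (`PulseParams.gap`, default 0; the LIBOR table
default 0.1 ms).

## Calibration and reported factors

`calibrate_amplitude` finds the B1 amplitude at which the post-pulse polar
angle arccos(Mz) of on-resonance water equals the nominal angle α
(relaxation off), by a coarse bracket scan (amplitude factors 0.05–8 in
0.05 steps, catching saturation below the target) followed by a bracketed
Brent root solve to 1e−6 rad. The reference amplitude is that of an
on-resonant rectangular pulse of equal active duration (α_rad / 2τ);
the reported **power factor** is the amplitude ratio, and the
scanner-interface angle is α × factor. Rotation is monotonic in amplitude up
to its first maximum (property-tested), so the first bracket is unique.

With the package's convention, the calibrated amplitude factors at the
table settings are LIBOR 1.55, LIBRE 3.12, BORR 3.18. The corresponding
published values are 1.56, 2.48 and 2.82. LIBOR agrees to 0.8%. The
LIBRE/BORR values could not be reproduced by *any* self-consistent
calibration we constructed: for a 1-1 binomial at 540 Hz, no phase offset,
gap or nearby τ yields a factor below ≈3.1 while preserving fat suppression,
under iterative calibration to a true 50° water rotation. A single-pass
amplitude rescale sin(α)/|Mxy| evaluated at the uncorrected nominal
amplitude gives 2.47 for LIBRE — matching its published 2.48 to 0.3% — but
that one-shot estimate is not a fixed point of calibration (iterating it
converges to 3.12) and does not reproduce the other two pulses' values, so
the package does not adopt it. The mean intra-TR RF-power ratios
(`relative_rf_power`, Σω₁²·dt per TR) inherit this: we obtain BORR/LIBOR
4.2 and LIBRE/LIBOR 4.1 versus the published relative SAR of 3.3 and 2.5.
The orderings — LIBOR lowest power, BORR highest — reproduce throughout.

## Phase-offset sweep

`phase_offset_sweep` emulates the LIBOR design procedure: for each phase
offset on a 0–360° grid (10° steps, 37 points) the amplitude is recalibrated
to 50° at 0 Hz, the single-pulse response is computed over −800..800 Hz
(10 Hz steps, 161 points, both endpoints inclusive), and the suppression
band is extracted. The **suppression band** is the maximal contiguous run of
grid points with |Mxy| ≤ 10% of the grid maximum that contains the point
nearest −220 Hz (zero width if that point is above threshold; for an
identically zero response the band spans the whole grid). The optimum is the
bandwidth argmax, ties broken by the phase closest to the centroid of the
longest maximal plateau; phases whose calibration fails count as zero
bandwidth. The sweep optimum lands at 280° (290° for a gapless pulse),
inside the published 270–310° window. At the table settings the calibrated
LIBOR single-pulse band is [−260, −190] Hz (70 Hz wide; 80–110 Hz at the
sweep optimum).

## Steady-state sequences

**bSSFP**: one excitation per TR with alternating 0/180° RF phase and
matching receiver demodulation (the published rectangular-pulse stop-band
near −220 Hz at TR 2.47 ms is only consistent with alternation, which puts
stop-bands at ±1/(2TR) ≈ ±202 Hz). The pulse sits symmetrically in the TR
with free precession (TR − pulse)/2 on each side; the echo is recorded at
TE = TR/2 from the pulse center.

**FISS**: modules of NR = 4 alternating-phase α excitations bracketed by α/2
catalyzation/restoration pulses placed TR/2 from their neighbors; after each
module the transverse magnetization is nulled (perfect RF + gradient
spoiling) and the module base phase advances by the quadratic 117° law
ψ_k = ψ_{k−1} + k·117°, demodulated at receive. Under perfect spoiling the
output is independent of the spoiling increment (property-tested); the law
matters only for a future non-ideal-spoiling mode. The returned signal is
the mean demodulated TE sample of the final module.

Both simulators run the prescribed 1000 excitations, but start from the
*exact* periodic steady state, obtained by noting that one period (two TRs
for alternating bSSFP; one module for FISS, where spoiling reduces the state
to Mz alone) acts affinely on the magnetization, M → AM + b, and solving
(I − A)M = b. A cold equilibrium start would still carry a ~1% transient
after 1000 excitations at TR 2.47 ms (effective relaxation time
T1* ≈ 0.84 s for these tissue parameters), visible against the closed-form
bSSFP oracle. With fixed-point initialization the simulator matches the
textbook on-resonance bSSFP steady state M0 sinα(1−E1)/(1−(E1−E2)cosα−E1E2)
to <1e−3 (the residual being the finite pulse duration and TE decay) and
is excitation-to-excitation stable to 1e−13.

**Steady-state maps** span off-resonance −800..800 Hz × 9 excitation-angle
values. The angle axis is the scanner-interface excitation angle — a linear
B1-amplitude sweep over ±20° (5° steps) around the calibrated operating
point — so the nominal 50° water rotation occurs at the center row and the
axis probes B1-inhomogeneity robustness. (Per-row renominal recalibration is
not used: beyond ≈55°/61° nominal, BORR/LIBRE cannot reach the target
rotation at all, so that reading cannot produce full maps.) On these maps
the fat-resonance column stays below 10% of the map maximum for all four
fat-suppressed protocols (FISS, BORR, LIBRE, LIBOR) at every angle row,
while the rectangular-pulse bSSFP map suppresses fat only partially.

## Synthetic phantom

`wexsim.phantom` generates the digital stand-in for the physical validation
phantom: 11 non-overlapping disc vials with fat fractions 0, 0.1, …, 1.0 on
a 96×96 canvas, a B0 offset map (default 0), and a background mask with a
guard margin. A pixel with fat fraction FF gets noiseless signal
FF·|Mxy_fat(b0 − 220 Hz)| + (1−FF)·|Mxy_water(b0)|, each compartment's
steady state simulated with its own relaxation times: water/blood T1/T2 =
1390/300 ms (the study's values) and fat T1/T2 = 290/80 ms (typical lipid
values at 1.5 T — an assumption, the study reports none). Complex Gaussian
noise (per-channel SD `noise_sd`, default 0.01 in units of M0, chosen to put
water SNR near 30) is added i.i.d. per pixel and the magnitude taken, so
vial statistics are Rician; the SNR denominator is the *empirical* SD of the
background region of the same image, as in the scanner analysis. CNR is the
difference of two ROI SNRs (water−fat by default).

What the generator does *not* emulate — and hence what passing tests do not
show about real acquisitions: multi-peak fat spectra (single peak at
−220 Hz only), B0/B1 field inhomogeneity beyond a user-supplied B0 map,
radial k-space sampling and its streaking/aliasing noise structure, coil
sensitivities, and motion. Absolute SNR/CNR values depend on scanner gain
and are not comparable to measured ones; only orderings, suppression ratios
and noise-scaling behavior are meaningful.

## Parameters that matter

| Parameter | Default | Units | Notes |
|---|---|---|---|
| τ (subpulse duration) | 1.3 | ms | all binomial pulses; RECT uses 0.3 ms |
| f_RF | 500 / 540 / 270 | Hz | BORR / LIBRE / LIBOR |
| Δφ₂ | 180 / derived / 290 | deg | LIBRE derived as 2πf_RFτ (see sign note) |
| LIBOR gap | 0.1 | ms | see gap section; 0 for BORR/LIBRE |
| α (nominal) | 50 | deg | water rotation target |
| TR | 2.47 / 4.9 | ms | rect / water-excitation protocols; TE = TR/2 |
| T1, T2 (water/blood) | 1390, 300 | ms | 1.5 T blood |
| T1, T2 (fat) | 290, 80 | ms | assumed lipid values |
| n_excitations | 1000 | — | steady-state train length |
| NR, spoil increment | 4, 117 | —, deg | FISS module structure |
| suppression threshold | 10 | % of max |Mxy| | band definition |
| grids | −800..800×10 Hz; 0..360×10°; ±20×5° | | inclusive endpoints |

## Numerical choices

Calibration tolerance 1e−6 rad; bracket scan step 0.05 in amplitude-factor
units, cap 8 (beyond which a clear error reports the saturation angle).
Degenerate suppression inputs: all-zero map → full-grid band; flat map at
its maximum → zero band. ODE oracle: fixed-step RK4, dt ≤ 1 µs. The phantom
image is computed per unique B0 value, so constant-B0 phantoms cost two
steady-state evaluations per protocol. All stochastic steps take explicit
integer seeds; pipeline outputs embed the package version and a config hash.

## Known limitations

* The published LIBRE/BORR power factors (and the relative SAR values
  derived from them) are not reproduced, for the reasons analyzed above; the
  package reports its own self-consistent calibrations.
* Relaxation during RF segments is neglected; no slice selection, shaped
  subpulses, or gradient/eddy-current modeling.
* FISS intra-module timing is an interpretation (the module description in
  the source material is ambiguous about pulse placement); perfect spoiling
  makes the simulated maps insensitive to most of that ambiguity.
* The steady-state suppression *bandwidths* at the 10% threshold differ in
  detail from the loosely quoted ~100–150 Hz range (we find 20–80 Hz for the
  water-excitation protocols and ~520 Hz for FISS at their operating
  points); the threshold convention of that quoted range is not specified.
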