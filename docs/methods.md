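# Methods

## Viscoelastic ligament model

Each ACL bundle is treated as a one-dimensional dense-connective-tissue
unit in which collagen fibers straighten sequentially: a fiber "recruited"
at strain ε_s carries elastic stress K(ε − ε_s) and viscous stress η ε̇,
and the recruitment strain follows a two-parameter Weibull density with
shape α = 4.5 and scale β = 0.3 (location fixed at 0 — the three-parameter
family degenerates to two parameters here). The nominal axial stress is
the recruitment-weighted integral over [0, ε]; slack tissue (ε ≤ 0)
carries exactly zero stress, and because the model is defined for tension
only, a negative total during rapid unloading (large negative ε̇) is
clamped at zero rather than interpreted as compression.

Units: with K and η ε̇ in MPa and cross-sectional area in mm², force comes
out directly in newtons. The viscosity is printed in mixed notation in
reference material ("MPa/S"); dimensional analysis requires MPa·s (it
multiplies a 1/s rate to give stress), which is what the implementation
uses — the value is configurable on the bundle spec.

Numerics. The scalar route (`nominal_axial_stress`) uses scipy adaptive
quadrature with absolute tolerance 1e-9 MPa and falls back to a
10⁴-interval composite Simpson rule, raising with the achieved error
estimate if both fail. The vectorised route used on time series
(`stress_series`) evaluates the closed forms obtained by exchanging the
order of integration:

    σ_e(ε) = K [ε − (β/α) γ(1/α, (ε/β)^α)]      (lower incomplete gamma)
    σ_v(ε, ε̇) = η ε̇ F(ε)                        (Weibull CDF)

Both routes are cross-checked against each other and against a 10⁶-node
trapezoid oracle in the tests. Strain rate is estimated by central
differences (one-sided at the ends) after the 10 Hz kinematic low-pass;
the differentiation scheme is not dictated by the model and is exact for
linear strain histories.

Bundle parameters default to the anteromedial (L_r = 30 mm, A = 20.7 mm²,
F_max = 1500 N) and posterolateral (L_r = 23.36 mm, A = 19.3 mm²,
F_max = 1600 N) bundles. A single measured elongation channel fixes the
anteromedial strain; the posterolateral bundle is assumed to share the
same strain history (its elongation scaling with its own resting length).
Forces above F_max and strains above the passive cap (15 %) or the
junction cap (2.5–3 %, configurable; 3 % default) are reported by the
validation layer and never clamped — the caps are modelling guardrails,
not constitutive features. The knee-flexion → elongation map is exposed
as a configurable polynomial (`ElongationMapping`) with no physiologic
default asserted, since no closed-form map is established; trials carrying
a measured elongation column bypass it entirely.

The fiber-orientation assumption — that the mean collagen axis is aligned
with the load, formally a Dirac orientation density — is a fixed modelling
assumption with no runtime parameter: it is what reduces the problem to
the scalar recruitment integral above.

## EMG-driven activation

Preprocessing: 10–400 Hz band-pass, full-wave rectification, 6 Hz low-pass,
all zero-phase. "Fourth-order zero-phase" is implemented as a
forward–backward pass of a second-order section (effective fourth order),
the standard reading; a forward–backward fourth-order variant is a flag.
MVC normalization divides the task envelope by the MVC envelope peak; a
moving-RMS reference is available by option because the phrasing of such
protocols is often ambiguous. Excitations above 1 are flagged and
preserved at normalization, then clipped (with a warning) only at the
recursion input, which is defined on [0, 1].

The recursion u(t) = α e(t−d) − β₁u(t−1) − β₂u(t−2) runs on the envelope's
sample grid with d rounded to whole samples (10 ms default). The roots
C₁, C₂ (β₁ = C₁+C₂, β₂ = C₁C₂) are rarely published; the defaults
C₁ = C₂ = −0.5 are a stable mid-range choice, and the gain is always
derived as α = 1+β₁+β₂ so constant full excitation converges to u = 1
exactly. The activation nonlinearity a = (e^{Au} − 1)/(e^A − 1) uses
`expm1` and the analytic identity limit at A = 0.

## Landing metrics

Phase detection thresholds the *raw* VGRF at 10 N in absolute newtons
(filtering first would ring at the contact discontinuity); the phase ends
at the knee-flexion argmax at or after contact, taking the first crossing
on bouncy traces. Kinematics are filtered at 10 Hz, kinetics at 20 Hz
(zero-phase Butterworth, effective fourth order); curves are
time-normalised to 101 points by linear interpolation with exact
endpoints.

Sign conventions: plantarflexion and inversion positive. AICA is the
filtered ankle angle at the contact sample; AROM is the excursion from
AICA to the most dorsiflexed angle within the phase (sagittal only,
consistent with restricting energy dissipation to the sagittal plane).
Angular velocity comes from the filtered angles by central differences
with degrees converted to radians before multiplying by the mass-normalised
moment; dissipation integrates only the negative part of power and is
reported as a positive magnitude, so TED is the exact sum of the three
joint dissipations. The inversion-moment channel's unit is carried as
metadata (`inversion_moment_unit`, default the "N/kg" printed in reference
tables even though Nm/kg is dimensionally expected) and never silently
corrected.

## Risk statistics

Correlations are Pearson r with the least-squares line; p is the two-sided
t-test with n − 2 degrees of freedom, unadjusted for multiplicity. The
unit of analysis is within-subject trial means (n = 60); pooled-trials
(n = 300) is a flag. Risk standardization is min–max over the subject-mean
cohort — the cohort maximum is read as the maximum plausible injury risk,
the minimum as the minimum. The ACL/LAS crossing solves the equality of
the two standardized-risk regression lines on the predictor (straight-line
fits, matching the linear-regression framing; smoothed-curve intersections
would be an alternative reading). The balanced range is the interval
around the crossing where the fitted risks differ by ≤ τ; its width is
2τ/|Δslope| in closed form. τ = 0.25 is the default: at the default
calibration it yields ≈ 10°-wide AICA and ≈ 20°-wide AROM bands.

## Synthetic cohort generator

The generator *is* the study condition: 60 subjects × 5 trials.
Subject-level vectors of the ten summary variables are multivariate normal
(normality is the documented property of the reference cohort) with the
calibrated means/SDs. Only the AICA and AROM correlation rows and the
PAF–PAIA pair are specified anywhere; the other pairs are filled by the
product-of-paths heuristic through the two anchors,
r(i,j) ≈ ½[r(i,AICA)r(j,AICA) + r(i,AROM)r(j,AROM)], the AICA–AROM entry
by the mean product over shared variables (≈ 0.19), and the matrix is
projected to the nearest correlation matrix by alternating projections
(Dykstra-corrected) *holding every specified entry fixed*, so the
calibration targets survive projection exactly (verified to 1e-6 in
tests). Within-subject trial noise is independent Gaussian at 0.2 of the
between-subject SD per variable — the trial-to-trial variance is a free
parameter with no published value; 0.2 keeps trial scatter visibly smaller
than between-subject spread, and because trials are averaged within
subject before analysis it attenuates correlations by only
1/(1 + 0.2²/5) ≈ 0.8 %. Body mass is drawn independently
(81.93 ± 12.81 kg, floored at 45 kg) and matters only for converting
mass-normalised targets to absolute newtons in the waveforms.

Trial waveforms are smooth closed-form templates on a 1 kHz grid (0.1 s
quiet stance, 0.5 s landing phase, 0.15 s tail): a smoothstep body-weight
shoulder plus a raised-cosine impact bump for VGRF (peak 80 ms after
contact, 160 ms wide — wide enough that the 20 Hz filter costs < 0.4 % of
the peak); a held plantarflexion plateau transitioning by smoothstep to
the dorsiflexion plateau for the ankle; monotone smoothstep knee/hip
flexion with the knee argmax marking the phase end; raised-cosine bumps
for the inversion angle and all moments. The ACL elongation is a
raised-cosine strain bump whose amplitude is solved by Brent's method
against the extraction pipeline's own peak-force routine, so the embedded
PAF is recovered essentially exactly. Noiseless round-trip recovery of
every embedded scalar is ≤ 0.7 % (tested at 1 %).

What the templates deliberately do not emulate: trial-level TED cannot be
embedded independently because power shares the angle trajectories with
the peak-moment targets — TED emerges from the templates (sub-J/kg) while
the calibrated TED lives in the summary-level tables, which is what all
correlation analyses consume; with the printed material constants the
strain amplitude needed to reach ~1200 N of ACL force exceeds the 15 %
passive cap (the elastic branch alone saturates far below it, making the
model viscous-dominated at landing rates), which the validation layer
flags on every generated trial; and real landings have multi-modal GRF,
co-varying segment dynamics, and soft-tissue artifact that bump/ramp
templates do not represent. Passing round-trip tests therefore
demonstrates pipeline correctness — that extraction inverts generation —
not physiological fidelity of the waveforms.

Synthetic EMG is band-limited (20–150 Hz) unit-RMS noise modulated by
raised-cosine burst envelopes; it exercises the preprocessing/activation
chain (envelope recovery correlates > 0.95 with the generating envelope)
but has no physiological motor-unit structure.

## Replicate-averaged reproduction

Because one 60-subject cohort gives noisy estimates (Fisher-z SE
≈ 0.13 at n = 60), the headline statistics are reproduced as
replicate averages: 200 independent cohorts, each analysed exactly as a
real one (subject means → correlations → standardization → line fits →
crossing/bands), with all seeds spawned from one `SeedSequence`. At the
default calibration the replicate means land within ~0.01 of the
calibrated correlations (the residual bias being the trial-noise
attenuation above) and the risk crossings fall near the cohort AICA/AROM
means, with per-replicate spreads of ≈ 2–4°. Problem sizes throughout
(200 replicates, 100-trial round-trip sweeps, 10⁶-node oracles) were
chosen so each check completes in seconds on one CPU.

## Known limitations

- Male-cohort calibration only; no female reference values are built in.
- The ligament model is short-term viscoelastic: no creep, relaxation, or
  stretch-shortening history beyond the instantaneous rate term.
- The knee-flexion → elongation map is configuration, not physiology.
- LAS risk is indexed by inversion angle alone; the inversion-moment
  channel is carried but not part of the standardized risk.
- Unspecified correlation pairs are heuristic fills; only the anchor rows
  and the PAF–PAIA pair are calibrated quantities.
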