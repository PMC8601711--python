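# Methods

This note documents the models behind `batrack`, their assumptions, the
parameters that matter, and the choices made where the design was open.

## World frame and camera model

The world frame is anchored at the left camera: *x* lateral along the
baseline, *y* range (the viewing direction), *z* height. Units are
millimetres everywhere except the metrics outputs, which report metres.
Cameras are standard pinholes with per-axis focal lengths, a principal
point and optional two-term radial distortion (k₁, k₂); distortion is
applied after perspective division and inverted by fixed-point iteration.
The default rig mirrors the field set-up: 640×480 sensors, 33° lenses
(f ≈ 1080 px), equal height, 4 m baseline. The exact mounting convergence
of the original rig is ambiguous (the stated inner-FOV crossing distance is
not consistent with simple parallel axes), so the pan angle is a free
configuration parameter; the default is parallel axes, and recovery tests
use an 8° toe-in where a wide joint view volume is convenient.

## Calibration

The bulb target is planar, so each filmed pose yields a plane-to-image
homography (DLT with Hartley normalisation). Zhang's closed-form
constraints on the image of the absolute conic initialise each camera's
intrinsics (zero skew enforced); per-pose target poses follow from the
homographies, the left-to-right pose is initialised as the rotation-mean of
the per-pose relative transforms, and everything is refined jointly by
Levenberg–Marquardt on the reprojection error over both cameras (intrinsics
× 2, relative pose, and one 6-dof target pose per position). Poses whose
plane normals all share a rotation axis make the Zhang system
rank-deficient; this is detected by the conditioning of the constraint
matrix and reported as a degenerate pose set rather than silently producing
garbage. Bulb identification works from blob pixels alone: the two bars of
the cross are found as lines (deterministic two-point hypothesis search),
their intersection gives the centre, the six-bulb arm is recognised by its
alternating small/large gap pattern, and the remaining ±x ambiguity is
resolved by in-image handedness (pixel *v* runs downward, so the
cross-product sign is flipped relative to the target frame). Poses with
fewer than 25 of 30 bulbs, ambiguous pair arms, or wrong per-arm counts are
rejected with a reason.

The target's as-built dimensions are not published; the default is 1 m
arms with even 125 mm spacing and a 60 mm in-pair gap, all configurable.

## Triangulation, pairing, linking

Triangulation is the midpoint of the shortest segment between the two
back-projected rays, with the mean two-camera reprojection error as the
residual; near-parallel rays raise an error rather than returning an
unstable depth. Cross-camera pairing scores every left×right detection
pair per frame by that residual and solves a global one-to-one assignment
(Hungarian algorithm); pairs above 2 px (configurable) are dropped. This
residual threshold operationalises "comparing x and y coordinates from
both cameras".

Linking is greedy across frames with a global minimum-cost assignment per
frame: an extension is legal iff frame gap ≤ 15, step ≤ 1000 mm and
implied speed ≤ 15 m s⁻¹; cost is the 3D gap distance with an infinitesimal
penalty on larger frame gaps (the tie-break). Tracks shorter than six
localisations are discarded, and every emitted trajectory is asserted
against all the linking invariants. A brute-force reference linker exists
for test scenes: it requires every localisation to have at most one legal
neighbour (true for well-separated bats) and refuses ambiguous scenes, so
it is an independent oracle rather than a re-implementation.

QC follows three rules: trajectories sharing more than three localisations
with another are removed (exactly three is allowed); a trajectory fails
speed consistency iff subsequent instantaneous speeds differ by more than
3 m s⁻¹; and smoothing removes an interior localisation only when both of
its segments are inconsistent with the bridging segment, the bridge is
legal, *and* the bridge agrees with the surrounding speeds — if more than
10 % of points would need removal the whole trajectory is rejected instead,
since removing more risks biasing the retained data.

The frame time defaults to 0.032 s. The cameras record 32 frames s⁻¹, for
which the exact period is 0.03125 s; both are supported (`dt` is a
parameter everywhere) and 0.032 s is the documented default.

## Flight metrics

Instantaneous speed: ‖P_{i+1} − P_i‖ / (gap × dt). Mean speed: arithmetic
mean of instantaneous speeds. Total length: sum of segment lengths
(segments spanning frame gaps contribute their straight-line length). Net
displacement: first-to-last distance. Tortuosity value: (total/net)/10, so
a straight path scores exactly 0.1 and the value is nominally in (0, 1];
zero net displacement makes it undefined and the trajectory is excluded
from tortuosity analyses with a logged reason. Values ≥ 1 are retained in
the metrics output but excluded (with a logged count) from the beta model,
whose domain is (0, 1). Distance from the deterrent is mean *y* plus a
15 m offset (speakers stood behind the cameras); both mean *y* and the
offset figure are reported so either convention can be reproduced.

## Sound field

SPL(d) = L₁ₘ − 20 log₁₀ d − α (d − 1), with α the ISO 9613-1 pure-tone
absorption coefficient (classical + oxygen and nitrogen relaxation terms).
Absorption accumulates from the 1 m reference outward so the reference
level is exact. At the deployed conditions (50 kHz, 14 °C, 90 % RH,
101.325 kPa) α ≈ 1.59 dB m⁻¹, giving 52.2 dB at 15 m and 2.1 dB at 41 m;
the quoted 30 m figure of 21 dB is ~1.3 dB below this model's 22.3 dB and
cannot be reconciled from the stated inputs, so only the robust values
(1 m, 15 m, the <3 dB bound) are treated as checks. Sources are isotropic
points; with two sources the nearest-source level is used (no incoherent
summation) — with side-by-side speakers this is within ~3 dB of any
summation and keeps the field monotone along rays.

## Synthetic data

**Flights** are 3D correlated random walks: per frame, a Gamma step length
(mean `mean_speed`·dt, SD `speed_sd`·dt), a wrapped-normal turning angle
with concentration κ (turn SD = κ^(−1/2)), and a Gaussian vertical
increment. Regime defaults use the observed means — commuting
4.86 ± 0.92 m s⁻¹, foraging 4.54 ± 0.99 m s⁻¹. No turning-rate data are
published, so the concentrations (400 commuting, 25 foraging) are package
assumptions chosen once so that simulated tortuosity falls in the observed
0.11–0.12 band; they are stated parameters, not fitted quantities. Walks
are truncated at the scene boundary with a logged warning.

**Deterrent response** is the minimal mechanism consistent with the three
observed effects (faster, straighter, further): above an SPL threshold the
bat switches to commuting kinematics with a per-frame probability, with
its heading pulled toward the away-from-source direction by a bias weight.
The threshold default (18 dB) sits inside the 2–35 dB range the sound
field actually takes over the observed 20–40 m span, so responses occur in
the scene; switch probability 0.5 per frame and bias 0.5 are defaults of
the same kind as the turn concentrations.

**Rendering** draws one isotropic Gaussian blob per visible projected bat
per camera per frame on Gaussian background noise, plus Poisson-rate
clutter blobs (fainter, smaller — insect stand-ins), quantised to uint16.
Same seed, same stacks, bit for bit.

**Counts** follow the field design exactly: 3 sites × 3 nights × 12
five-minute blocks alternating control/deterrent starting with control.
Counts are negative binomial about
baseline × ratioᵗʳᵉᵃᵗᵉᵈ × exp(u_site + u_night + u_block); defaults scale
the printed totals (5440 passes, 79 % *P. pygmaeus*, …) to per-block
control rates and use the printed percent reductions as rate ratios
(e.g. 0.7313 for *P. pygmaeus* passes, 0.3175 for *Nyctalus/Eptesicus*).
Random-effect SDs (0.35/0.30/0.20 on the log scale) and NB size 8 are
chosen as typical ecological overdispersion; they are the fixed study
conditions of every recovery test, not tuning knobs.

**Call parameters** are Gaussian with the treatment shifting start
frequency by −5.68 kHz and bandwidth by −5.79 kHz; the implied +0.11 kHz
end-frequency shift keeps bandwidth ≡ start − end exact in every record.
The number-of-bats effect (+2 kHz per extra bat) acts on start frequency.
Control means are typical of *P. pygmaeus* (the per-arm means are not
published in full). Block pairs nest in nights in sites with several
pairs per night, mirroring the pooled call sample (150 passes per arm,
three calls per pass).

What the generator does **not** emulate: species mixtures within a
trajectory scene, echolocation audio, insect flight behaviour (clutter is
spatially uniform), thermal drift, rolling shutter, or camera
desynchronisation. Passing recovery tests therefore demonstrate the
correctness of the measurement chain and estimators under the stated
statistical structure — not robustness to every field artefact.

## Statistical models

Counts: GLMM with fixed effects treatment + block order and nested random
intercepts (block in night in site). The family is Poisson unless the
conditional Pearson dispersion ratio of the Poisson fit exceeds 1.5, then
NB2. Note the block-level intercept has one observation per block per
series, so it acts as an observation-level (Poisson-lognormal) dispersion
term; the conditional check therefore selects NB only for overdispersion
beyond what that absorbs. Species-event series with fewer than 20 events
per night for the majority of nights are refused, mirroring the original
exclusion.

Trajectory responses: speed and distance as identity-link LMMs; height
Box–Cox transformed (λ by profile ML on the marginal response, then fixed
and reported; the response is shifted to positive support first since
heights below the camera line are negative); length log-transformed;
tortuosity as a beta-family mixed model with cloglog link — "beta binomial"
on a continuous proportion is interpreted as beta regression, since a
binomial needs integer trials that tortuosity does not have. Fixed effects
are treatment, block order, distance and treatment×distance (the distance
model uses treatment and block order only).

Call parameters: Gaussian LMM with fixed effects treatment, block order
and number of bats, and fully nested random intercepts
site/night/pair/block/sequence; the "nested design" wording is ambiguous,
and full nesting is the implemented reading. LRT p-values carry a
Bonferroni factor m = 6 (six responses measured on the same calls); raw
and adjusted values are both reported.

Gaussian LMMs with three-level nesting delegate to statsmodels `MixedLM`
(ML, so LRTs are valid). The five-level call model routinely drives
variance components to the zero boundary, where `MixedLM`'s Hessian
inversion fails; it and the non-Gaussian families use the package's own
Laplace-approximation fitter (`batrack.glmm`): spherical reparameterisation
u = σv so σ = 0 is an interior-feasible point, damped Fisher-scoring Newton
for the joint (β, v) mode, Nelder-Mead over (σ…, auxiliary) for the
marginal, and O(n) Hessian assembly via group-sum cross-tabulations. This
is the same approximation lme4 applies to GLMMs (nAGQ = 1); the test suite
cross-checks fixed effects and log-likelihood against `glmer` on a small
fixture. Fixed-effect SEs come from the inverse observed information at
the mode, conditional on the variance parameters.

Inference: LRT between nested ML fits (χ² = 2Δℓ, df = parameter
difference); AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n the number of
response rows and k counting fixed effects, variance components, family
auxiliaries and (for LMMs) the residual variance; model selection keeps the
richer model only when its AICc is more than 2 lower. Percent reductions
are reported both ways — raw totals, 100(1 − T/C), and model-based,
100(1 − exp(β_treatment)) — since how the printed figures were computed is
not stated.

## Numerical choices and problem sizes

Detection centroids are intensity-weighted over connected components;
`min_blob_area` defaults to 2 px to reject single-pixel noise. The
empirical threshold selection scores each candidate as
(QC-passing trajectories) − 0.1 × (detections not used by any such
trajectory); the 0.1 weight operationalises the unquantified "minimum
amount of noise", and ties go to the higher (more conservative) threshold.
The rolling-median background window defaults to 21 frames: it must exceed
about twice a blob's per-pixel dwell time, and bats flying near the
optical axis move only ~1–2 px per frame. Frame indices are 0-based
everywhere.

Test and demonstration problem sizes are chosen to exercise every code
path at desk scale: rendered scenes of 2–4 bats over 32–64 frames at full
640×480 resolution, 24-pose calibrations, 100 replicate count fits for
effect-size recovery, 500 null simulations for LRT calibration, and the
field's own n (150 passes per arm) for the call models, averaged over five
replicates to separate estimator bias from single-draw noise.

## Known limitations

- Pairing is appearance-free; two bats crossing in both views can swap
  identities (mitigated, as in the original workflow, by the QC rules).
- The beta tortuosity model conditions on tortuosity < 1; heavily
  convoluted paths (ratio > 10) are excluded, and a dataset consisting
  entirely of straight paths (zero variance) is a reported degenerate case.
- The Laplace approximation is least accurate for very small counts with
  large random-effect variances — the same regime where glmer's nAGQ = 1
  shares the bias.
- The sound-field model is isotropic; the real transducers have a beam
  pattern, so on-axis levels in the field likely exceeded the model at
  moderate ranges.
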