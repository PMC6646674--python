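# Methods

This note documents the models, parameter choices and numerical conventions
behind `canopytraits`, and what the synthetic-scene tests do and do not
demonstrate about real field data.

## Gap-fraction model and inversion

The canopy is modelled as a Poisson turbid medium. For a view zenith angle
θp the gap fraction is Po(θp) = exp(−G(θp, θl)·GAI/cos θp), where G is the
foliage projection function. Writing G = K·cos θp with the extinction
coefficient K of an ellipsoidal leaf angle distribution,

    K(θp, χ) = sqrt(χ² + tan²θp) / (χ + 1.774·(χ + 1.182)^(−0.733)),

the model reduces to Po = exp(−K·GAI). The distribution-shape parameter χ
maps to the average leaf angle through ALA = 9.65·(3 + χ)^(−1.65) radians
(monotone decreasing; χ = 1 is the spherical canopy with ALA ≈ 56.1°); the
inverse is solved by bracketed root finding to < 0.01° round-trip error.

The 1.774/1.182/−0.733 coefficients are Campbell's closed-form
approximation to the exact ellipsoidal normalisation. We verified it against
direct numerical integration of the ellipsoidal leaf-normal density with
the standard direct-beam projection kernel: the two agree to < 0.002 in G
across χ ∈ [0.2, 5]. A consequence worth recording: at the "hinge" angle
57.5°, G is close to 0.5 for all inclinations but its true envelope over
χ ∈ [0.2, 5] is [0.494, 0.532] — the popular ±0.03 insensitivity claim is
slightly violated at the extreme planophile end (χ = 0.2, G = 0.532). One
test asserts the ±0.03 band anyway and is expected to fail at that
endpoint; a companion test pins the true envelope.

**Inversion.** Exhaustive search over a precomputed look-up table:
GAI 0–8 in steps of 0.05, ALA 10–80° in steps of 1°, at the platform's two
camera angles {0°, 45°}. Grid steps are finer than the sensor noise floor
while keeping the full table (161 × 71 × 2) instantly searchable. The cost
is the unweighted RMSE over available angles (configurable weights are
accepted); ties break toward smaller GAI, then smaller ALA (parsimony). A
fully open observation (Po = 1) returns GAI 0 with ALA pinned to the grid
minimum and flagged non-identifiable, as is any single-angle inversion.
With green-only gap fractions (1 − GCF) the inverted quantity is a green
plant area index (GPAI); the code does not distinguish the two beyond the
trait label.

## Green cover fraction

White balance applies per-channel gains mean(panel)/panel_c from a grey
reference panel, clipping to [0, 1]. Pixel classification uses a linear
SVM (scikit-learn `LinearSVC`, standardised features, fixed random state)
over (R, G, B, excess green 2G−R−B, hue). The feature set and classifier
family are our choice — reference field training sets for such platforms
are proprietary, so the classifier here is trained and validated purely on
the synthetic mosaics. An excess-green threshold (default 0.2 on [0, 1]
linear RGB) is provided as a parameter-free fallback. GCF is an exact
pixel count ratio, hence exactly additive over image tiles; an optional
border-margin crop (default 0 px) supports intra-plot border removal.

## Spectral processing

Reflectance is the canopy/panel digital-number ratio times the panel's
characterised reflectance. The usable window is 450–820 nm (sensing-chain
SNR ≥ 20 outside loses validity); when repeat scans are available the
mean/std ≥ 20 criterion is applied per wavelength on top of the fixed
window — estimating SNR from session repeats is a declared choice, as is
averaging three acquisitions after MAD-based outlier rejection (> 3 scaled
MADs; with zero MAD only values equal to the median are kept). Band
sampling is a Gaussian-weighted mean with σ = FWHM/(2√(2 ln 2)), weights
renormalised over the ±2σ support; a band whose support is masked raises
instead of silently extrapolating.

Index conventions: NDVI uses R670 in the denominator (R800 + R670); MCARI2
uses the original published closed form with the square root in the
denominator, and a `literal_denominator` flag exposes the variant without
it that circulates in some transcriptions. Plot-level indices are computed
on the average of the normalised reflectances by default (not the average
of per-scan indices); both paths are exposed. Nadir and 45° spectra are
reported separately, nadir being the default plot value.

## LiDAR height

Ground/vegetation separation is an Otsu threshold on the z histogram —
parameter-free and robust for the bimodal soil/canopy distributions a
cereal plot produces. Otsu will happily split a unimodal bare-soil pile,
so clusters whose means are closer than 3× the lower cluster's spread are
merged back into ground. Ground level is the mode of the ground cluster's
z histogram (1 cm bins, lowest bin on ties; literal "mode of the
non-vegetation points"). Height is the linear-interpolation 99.5 % quantile
of vegetation elevations minus ground (negatives clamped), reported in cm.
Range-style inputs (distance below the scanner, valid 0.70–3.00 m) are
converted to elevation on read using the gantry height; out-of-range
returns are dropped. PLY files are read through `trimesh`, CSV through
pandas.

## Trait dynamics

The default trajectory model is the daily linear interpolant; logistic
a/(1+exp(−k(t−t₀))) and double-logistic (rise-and-fall) fits are opt-in
via `scipy.optimize.curve_fit` with deterministic, data-driven starts
(half-amplitude crossing for the midpoint). AUC is the trapezoidal
integral with window edges interpolated — exactly additive over adjacent
windows and linear in the values; the natural window for senescence
indicators is flowering → maturity from the phenology calendar.
Divergence onset interpolates both series to a daily grid over their
common support and returns the first day |a−b| exceeds the threshold and
stays above it for the persistence span (default 5 days), filtering
single-day spikes. Nabs = GY·P·10/5.7 kg N/ha for GY in t/ha and P in %;
the ×10 makes the protein-to-nitrogen formula dimensionally consistent,
and a `literal` flag drops it. Treatment summaries wrap one-way
Tukey HSD at α = 0.05 with a compact letter display built in-package.

## Water accounting

WHC = Σ thickness_cm·10·(θ_fc − θ_wp) mm over the horizons; typical
platform profiles fall in 102–275 mm and values outside raise a range
warning. The daily bucket clamps storage to [0, WHC], routes overflow to
drainage, and records the ET actually extracted, so
Δstorage = rain + irrigation − ET − drainage holds to machine precision
every day. This bucket plus the piecewise-linear stress factor (1 above an
available fraction of 0.4 — a declared placeholder breakpoint — falling
linearly to 0) is a deliberately simple stand-in for a full daily
carbon/water/nitrogen crop model: it reproduces the water accounting, not
crop physiology, and ET is an input series rather than being computed.
Irrigation thresholds: 100 cbar at 30 cm; 80 cbar at 60 cm before Z39 and
100 after; well-watered management overrides to 80 cbar throughout;
120 cbar flags actual water stress; readings at the 200 cbar probe cap are
censored and flagged. Interception efficiency uses the maximum of the
outside pluviometers as reference by default (the mean is selectable).
Degree-days accumulate (Tmax+Tmin)/2 above base 0 °C from the start of
protection. TDR calibration is ordinary least squares of gravimetric
content ((fresh−dry)/dry mass) on probe readings, requiring ≥ 3 pairs.

## Acquisition geometry

Pure arithmetic with reporting-precision rounding: mm/pixel =
field/pixels; LiDAR longitudinal = speed/frequency, transversal =
distance·tan(step); fibre FOV = 2·d·NA (paraxial; the exact-trig variant
2·d·tan(asin NA) differs by ~2 % at NA 0.2 and is available). Full
precision is retained internally.

## Synthetic scenes

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`. Mosaics place an exact green-pixel budget at
random positions with Gaussian colour texture (σ = 0.04) around fixed
green/soil means. Gap fractions are forward-model values with
multiplicative Gaussian noise, clipped to (0, 1]. Spectra mix two built-in
smooth endmembers (foliage: red absorption, red-edge sigmoid, NIR plateau
≈ 0.55; soil: a rising line) under a broad lamp envelope on the
instrument's 380–1100 nm / 256-pixel grid. Clouds combine a N(0, 5 mm)
ground plane with a top-weighted Beta(5, 1) canopy profile, the ground
fraction set by the nadir gap fraction of a spherical canopy. Seasonal
curves rise logistically to a treatment plateau and decay logistically
from a treatment-dependent senescence onset; stressed treatments senesce
earlier and nitrogen-poor ones plateau ~20 % lower.

What passing tests show: each processing stage recovers its generator's
truth within stated tolerances, invariants hold, and the chain is
bit-reproducible. What they do not show: robustness to real-world
nuisances absent from the generators — mixed pixels and shadows, canopy
clumping that violates the Poisson assumption, spectral BRDF effects,
LiDAR multi-returns and wind motion, spatial field trends. Validation
against those requires field reference data.

## Problem sizes and determinism

Default test and acceptance runs use 64–128 px mosaics, 4 000–50 000-point
clouds, 50-seed Monte-Carlo noise studies, 400-point grid round-trips and
multi-plot end-to-end trials of 2–4 plots — sizes chosen so each check
isolates one property while the full suite stays interactive. All
randomness descends from explicit seeds; reruns are bit-identical.
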