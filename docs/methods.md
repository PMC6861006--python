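# Methods

This note documents the models, conventions and numerical choices behind
`vesipool`, in the spirit of a methods section a maintainer can audit.

## FRAP recovery model

Bouton fluorescence recovery after photobleaching is modelled as

    R(t) = P · [ f · (1 − 2^(−t/h_f)) + (1 − f) · (1 − 2^(−t/h_s)) ]

with plateau (mobile fraction) `P ∈ [0, 1.05]` (a small overshoot
tolerance absorbs noise in near-fully-mobile data), fast-component share
`f ∈ [0, 1]` and half-lives `0 < h_f < h_s` in seconds. Half-lives are the
native parameterization because that is how recovery kinetics are reported
in this field; `h = τ·ln 2` converts to rate time constants
(`vesipool.kinetics.half_life_to_tau`). The same biexponential is the
solution of a linear two-compartment exchange between a bouton cluster
containing two kinetically distinct sub-pools and an effectively infinite
unbleached axonal super-pool; the mapping is noted in
`vesipool/kinetics.py` and the ODE system is not integrated separately.

## Acquisition schedule

The standard protocol images a baseline every 30 s over 3 min, bleaches,
and samples recovery every 30 s for 3 min and then every 5 min out to
73 min (4380 s) post-bleach, which places samples exactly at the 68-min
(4080 s) comparison point and at 73 min. The frame acquired at the bleach
time is taken to be the *immediately post-bleach* frame: the bleach pulse
fires just before it, so that frame shows the full bleach depth and the
normalization below can pin it to zero. The baseline therefore contributes
6 pre-bleach frames (0–150 s) plus the bleach frame at 180 s. The fast
protocol (5-s sampling, default 30 s baseline and 300 s of recovery)
resolves the fast component; its spans are package defaults, configurable
per experiment.

## Trace normalization and QC

For each bouton trace with whole-cell reference and background ROI:

1. subtract the background trace from bouton and cell series;
2. divide the bouton by the cell reference rescaled to its own pre-bleach
   mean. This ratio cancels any multiplicative per-frame acquisition
   photobleaching shared by bouton and cell *exactly* — on noiseless
   synthetic data the corrected trace equals the bleach-free trace to
   better than 1e-9, which the tests assert;
3. full-scale normalize: `v(t) = (F(t) − F_post0) / (F̄_pre − F_post0)`,
   so the pre-bleach mean is 1 and the immediately-post-bleach value 0.

`photobleach_fraction` is the relative loss of the background-subtracted
cell reference between the first and last 3 frames of the run; recordings
are discarded when it *exceeds* 0.60 (strictly greater — a fraction of
exactly 0.60 passes). A nonpositive corrected cell reference or a trace
with no bleach step (pre-bleach mean ≤ post-bleach value) raises a typed
error rather than returning garbage.

## Biexponential fitting

Fits minimize squared residuals over post-bleach points only (the t = 0
post-bleach point is included; pre-bleach samples are not), with bounds
`P ∈ [0, 1.2]`, `f ∈ [0, 1]`, `h ∈ [1, 1e5] s`. The default **pooled**
mode fits every trace's points jointly, which gives well-defined residual
degrees of freedom; **averaged** mode fits the mean trace for fidelity to
the classic average-then-fit workflow (it requires a common schedule).
Because the two-timescale model has local minima, fitting multi-starts
from 8 log-spaced half-life pairs (tie-break: lowest SS, then lowest
h_f); `P` starts at the mean of the latest fifth of the data and `f` at
0.5. Half-life order is enforced by relabelling (`h_f ↔ h_s`,
`f → 1 − f`) after convergence. Degenerate solutions are flagged rather
than hidden: `f > 0.999` / `f < 0.001` mark an unidentifiable slow/fast
component, and `h_s < 1.05·h_f` marks the half-life collapse that makes
`f` unidentifiable (both parameterizations of single-exponential data are
accepted by the tests). Parameter uncertainties come from the Gauss-Newton
covariance `(JᵀJ)⁻¹·SS/dof`.

## Extra sum-of-squares F test

One model is fitted to the pooled points of all groups and one per group;
`F = ((SS_sh − SS_sep)/(df_sh − df_sep)) / (SS_sep/df_sep)` with
`df_sh = N − 4`, `df_sep = N − 4k`. Each per-group fit is additionally
seeded from the shared optimum, which guarantees the nesting inequality
`SS_sep ≤ SS_sh` up to round-off. Two numerical guards: if the shared fit
is already perfect at the scale of the data (SS below 1e-12 of Σv²), or if
the extra SS is below 1e-12 of SS_sh (e.g. duplicated groups), the test
reports F = 0, p = 1 exactly. The verdict threshold is α = 0.05,
configurable; no multiple-testing correction is applied across mutants.
Degrees-of-freedom conventions differ between averaged-trace and pooled
fitting; both modes are exposed and the pooled one is the default.

Calibration at study conditions (plateaus 0.73 vs 0.53, `f = 0.4`,
half-lives 60/1200 s, i.i.d. Gaussian noise sd 0.05 in normalized units,
20 traces per group, standard schedule) is asserted by the acceptance
tests: median plateau error ≤ 0.03, median half-life errors ≤ 15%, null
rejection rate within the binomial 95% band around 0.05 over 500
replicates, power > 90% over 100 replicates. These Monte-Carlo studies add
noise in normalized-recovery space (`sim.simulate_normalized_traces`):
that is what "noise sd 0.05" means for a unitless trace, and it keeps
residuals independent, which the F test assumes. Noise injected on *raw*
traces additionally propagates the bleach-frame noise sample into every
normalized point of a trace (a per-trace random offset); the raw path is
exercised by the noiseless-identity and image-path tests instead.

Note one deliberate reading: the F ratio is invariant under a common
*multiplicative* rescaling of all trace values (residuals scale, the ratio
cancels), and the tests assert that. An additive offset is not absorbed by
this model family (R(0) = 0 is structural), so offset invariance is
neither claimed nor tested.

## Synthetic FRAP generator

Trace level: each bouton follows `B·(1 − d + d·R(t))` after the bleach
(`d` = bleach depth, default 0.5 — half the initial bouton fluorescence is
removed), multiplied by `r^k` per acquired frame `k`
(`acquisition_bleach_rate r`, default 0.998/frame ≈ 5% cell-reference loss
over a standard 27-frame run), plus Gaussian noise of sd
`noise_sd·baseline`. A shared whole-cell reference carries the same `r^k`
and a constant background trace is emitted alongside. Image level: boutons
are pixel-integrated 2-D Gaussian spots (exact per-pixel erf masses, so
ROI sums reproduce the generating trace to < 1%, limited only by mask
truncation of the tails), the cell reference is a broad Gaussian blob
placed away from the boutons, and optional global drift and
Gaussian-or-Poisson camera noise are applied. All generators are pure
functions of their config including the seed.

What the generator does *not* emulate: optics-accurate PSFs, reversible
fluorophore dark states, bouton-to-bouton baseline variability, spatially
correlated noise, and z-drift. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not robustness to every
real-microscope artifact.

## Image processing

Registration targets the first frame using phase cross-correlation with
10× upsampled sub-pixel refinement; estimated drift is undone by bilinear
interpolation. All-zero frames trigger a degenerate-registration warning
and pass through unshifted. ROI masks are pixel-inclusive if the pixel
center falls inside; coordinates are 0-based (row, col), origin top-left.
Bouton morphometry follows the edge-based recipe: Sobel gradient →
threshold (Otsu by default) → closing (disk 2) → hole fill → erosion
(disk 1, compensating the edge band that straddles the true boundary) →
connected components ≥ 4 px. Integrated intensities are
background-subtracted (mean outside all components by default) and
optionally normalized to a caller-supplied reference-group mean; when no
reference is given the normalized value is NaN, never guessed. Puncta
density: mean filter (radius 2 px) → median background subtraction →
Otsu → mean of the background-subtracted image within the mask; an empty
mask is flagged with density 0.

## Transport quantification

Kymographs resample the axon polyline at 1-px arc-length steps and reduce
over a 3-px-wide normal segment, by maximum by default (preserves dim
puncta next to saturated boutons; mean available). Track tracing detects
per-row sub-pixel peaks (parabolic refinement) and links them greedily
across rows within the displacement reachable at `max_speed` (default
3 µm/s), bridging ≤ 2 missing rows; near-stationary ridges (boutons) are
excluded. Crossing-track disambiguation is out of scope — validation uses
non-crossing geometries. Speeds are segmental means of |Δx|/Δt (pauses
count as zero); a signed least-squares velocity is also exposed.
Cumulative traffic integrates density along a 1-px line (bilinear),
subtracts background, divides the per-frame series by the mean of its 10
lowest values and sums — a constant sequence sums exactly to the frame
count, and the statistic is invariant under global intensity rescaling.
The movie generator includes a static diffuse axon ridge (`axon_level`)
because the normalization divides by baseline axon fluorescence; a
zero-signal line raises a degenerate-normalization error.

## Miniature-current analysis

Detection is sliding scaled-template matching: at each lag the
biexponential template (unit peak; defaults rise 0.5 ms / decay 5 ms for
mEPSCs, 1/10 ms for mIPSCs, configurable — published templates came from
representative recordings and are not printed anywhere) is fitted by
optimal scale and offset, and the criterion is scale / SE of fit. Windowed
sums use FFT correlation; an SE floor of 1e-9 and a scale floor of 1e-6 of
the trace amplitude guard the noise-free limit, where round-off would
otherwise produce huge criteria at negligible scales. Detections are
criterion peaks above the threshold (default 4.0) separated by the
refractory interval (rise time + 2 ms) with a prominence floor of half the
threshold, which suppresses the shallow secondary maxima the criterion
develops along the decay of one large event. Amplitudes are the fitted
signed scales.

Cell QC from the seal-test step: leak = pre-step holding current, access
resistance from the peak transient, membrane resistance from the
steady-state response, τ from a mono-exponential fit of the transient
decay, and `C_m = τ/R_a`. That formula underestimates the true capacitance
by the factor `R_m/(R_a + R_m)` — negligible in the intended regime
`R_m ≫ R_a` and asserted to 10% against an RC-circuit oracle. The
exclusion rule is |leak| > 200 pA or `R_m` < 100 MΩ — the physically
coherent reading of thresholds that are conventionally quoted with
inconsistent signs. Group statistics dispatch unpaired t, Mann-Whitney,
one-way ANOVA or Kruskal-Wallis.

## Pipeline

Runs are YAML configs (seed, outdir, ordered stages); every run writes
JSON provenance (hash of stages+seed, package version). Identical
config and seed reproduce outputs byte-for-byte, which is tested. The
report stage emits recovery curves with fitted models and a group table
using the field's n/N convention (n = synapses or cells, N = independent
cultures). Stage failures abort naming the failed stage and keep completed
outputs. The `vesipool` CLI wraps the same functions; electrophysiology
input is CSV (`time_s, current_pA`), imaging input TIFF with a JSON
sidecar, ROIs ImageJ `.roi`/`.zip`.

## Problem sizes

Monte-Carlo sizes were chosen to make the calibration checks statistically
decisive while keeping the suite quick on one CPU: 100 two-group
replicates for power/recovery, 500 for type-I error (binomial 95% band
[0.031, 0.069]), 200 traces for the bleach-depth summary, 200 replicates
for Poisson-rate checks, 5 speeds spanning 0.5–2.5 µm/s for transport.

## Known limitations

* The averaged-vs-pooled degrees-of-freedom convention used by historical
  analyses is not recoverable; both are provided, neither claimed original.
* Track tracing is validated on non-crossing puncta only.
* No 3-D registration, flat-field correction, or evoked-response analysis.
* ABF (Axon Binary Format) reading is not included; convert recordings to
  CSV first.
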