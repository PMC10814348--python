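# Methods

## The forward model

Dynamic hyperpolarized [1-¹³C]pyruvate signals are modeled as a
three-pool linear system driven by a vascular input u(t):

    dP/dt = −(1/T1_P + k_PL + k_PB)·P + u(t)
    dL/dt = k_PL·P − L/T1_L
    dB/dt = k_PB·P − B/T1_B

At each sample time t_i = delay + i·Δt the recorded signal is
S_X(i) = M_X(t_i)·sin(α_X) and the longitudinal magnetization loses a
factor cos(α_X), once per metabolite per 3-s frame.  Multi-slice
sub-frame timing is folded into these effective per-frame losses; the
analysis operates at the frame level.  Propagation between samples uses
the closed-form solution of the lower-triangular system on a fine
substep grid (default 60 substeps per frame) with piecewise-constant
input, so integration is exact up to the input discretization; the
`expm1`-based propagator entries remain accurate in the long-T1 and
small-step limits.  A matrix-exponential cross-check in the test suite
agrees with this propagator to ~1e−13.

The bolus is a gamma-variate, u(t) ∝ (t−t₀)^α e^{−(t−t₀)/β}, normalized
to a peak amplitude.  This is a synthetic stand-in for the arterial
input, which the analysis itself never requires (see below).  Defaults:
arrival t₀ = 4 s post-injection, shape α = 2.5, scale β = 3.5 s, i.e. a
rise spanning several frames and a peak ~8.75 s after arrival.

Default relaxation times are T1 = 30 s (pyruvate), 25 s (lactate), 25 s
(bicarbonate).  These are model assumptions, configurable everywhere;
in-vivo *apparent* pyruvate decay is faster because washout and
conversion add to T1 loss, and the delay-sweep reference conditions use
an apparent 12 s (below).

## Inputless kinetic fitting

The fit uses the measured pyruvate signal as the driving input, so no
arterial input function is estimated.  With flip-corrected pyruvate
magnetization P_i = S_P(i)/sin(α_P), each product pool X ∈ {L, B}
follows the discrete update

    M_X(i+1) = M_X(i)·cos(α_X)·e^{−Δt/T1_X} + k_PX·G_i ,
    G_i = ∫₀^Δt P(t_i+s)·e^{−(Δt−s)/T1_X} ds ,

where P(·) is piecewise-linear between the post-flip value
cos(α_P)·P_i and P_{i+1}.  G_i is the trapezoidal pyruvate integral
weighted by the product pool's own decay within the interval; as
T1_X → ∞ it reduces to the plain trapezoid Δt·(P_i+P_{i+1})/2.  The
weighting matters at 3-s sampling: the unweighted trapezoid biases
noiseless rate recovery by ~6–9 %, the weighted form by <0.3 %.

k_PL and k_PB are fitted jointly by bounded nonlinear least squares on
the predicted signals M_X·sin(α_X) (bounds [0, 1] s⁻¹, initialization
0.01 s⁻¹); with fixed T1s the problem is separable and an independent
per-metabolite mode (`joint=False`) gives identical estimates.  The
fractional error of each rate is the standard error of the estimate —
residual variance over the squared sensitivity ∂(prediction)/∂k — as a
fraction of the rate.  Whether such an error should be a standard error
or a residual-norm ratio is a convention choice; the standard-error
convention is used and exposed as `k_pl_error`, `k_pb_error`.  Maps are
filtered to voxels whose k_PL error is ≤25 % of k_PL (boundary
retained), and regional summaries include voxels whose ROI
partial-volume fraction strictly exceeds 30 %.

**Initial condition.**  By default the product pools are initialized
from the first observed flip-corrected signals (`init="data"`).  An
alternative `init="zero"` assumes no product magnetization at the first
sample — the implicit assumption of complete-inflow-capture protocols.
The two coincide when acquisition starts before tracer arrival.  They
diverge sharply on late starts: data-initialized fits absorb the missed
history into the initial condition and stay nearly delay-invariant,
whereas zero-initialized fits must explain the already-accumulated
product signal with extra conversion and therefore overestimate the
rates.  The delay sweep (below) uses `init="zero"` precisely because
that is the failure mode an acquisition delay induces in practice.

## Inflow capture and the delay sweep

The inflow percentage of a dynamic pyruvate trace is

    %Inflow = (Pyr_max − (Pyr_0 − Pyr_min)) / (Pyr_max − Pyr_min) × 100

with Pyr_0 the first and Pyr_min the last timepoint (taking the last
timepoint rather than the global minimum is deliberate; a
`robust_min` variant uses the median of the final two frames).  The
statistic is scale-invariant and reads 100 % exactly when the trace
starts and ends at baseline.  When the acquisition starts at zero
signal but the tail has not fully decayed (Pyr_0 < Pyr_min), values
slightly above 100 % occur; they indicate complete capture.

The delay sweep emulates late acquisition starts: ROI-mean metabolite
traces are interpolated with natural cubic splines, shifted in 0.1-s
increments, and resampled at the native 3-s resolution with the first
sample at the shifted origin and the acquisition end fixed — so a shift
of exactly k frames equals dropping the first k frames, and the sampled
window shortens as it would in vivo.  At each shift, %Inflow and the
zero-initialized kinetic fit (rates and fractional errors) are
recomputed, and rates are reported relative to the zero-shift fit at
the first ROI threshold; `rel_*_error` fields report error differences
from that reference.  After a resampled shift, the shifted trace's own
first frame serves as Pyr_0.

Reference conditions for the sweep: bolus arrival 3 s, α = 3,
β = 2.5 s, and apparent pyruvate decay 12 s, chosen so the trace
returns to baseline within the 60-s window (%Inflow ≈ 102 at zero
shift) and the rise spans several frames.  Under these conditions the
captured inflow decreases with delay (within a ≤1-percentage-point
sawtooth caused by the frame-quantized window end), relative k_PL and
k_PB are ≥1 whenever inflow is incomplete (reaching ~1.12–1.16 at ~35 %
inflow), and the fractional fit errors at ~35 % inflow exceed ~5× their
value at ~80 % inflow.

A negative finding worth recording: the steeper sensitivity of *k_PB*
relative to *k_PL* seen in patient data cannot be reproduced by this
generator's deterministic sweep.  With equal product T1s and flips the
synthetic lactate and bicarbonate traces are exact scalar multiples of
one another, so their relative inflation curves coincide identically; a
realistic shorter bicarbonate T1 makes k_PB slightly *less* inflated,
and noise at realistic SNR adds scatter rather than systematic
ordering.  The k_PB-specific fragility is an SNR property of real
bicarbonate signal near the noise floor; the package's tests therefore
assert its robust counterparts — the k_PB fractional error exceeds the
k_PL error at matched inflow, and relative RMSE of k_PB exceeds that of
k_PL under noise.

## Preprocessing chain

Order: prewhiten → combine → phase → denoise (fixed pipeline
convention).  The channel noise covariance is the sample covariance of
designated signal-free samples (pre-arrival frames, or an appended
flagged noise frame), regularized onto the positive-definite cone by
adding ε·trace/n (ε = 1e−9, escalating tenfold) to the diagonal when
needed.  Prewhitening multiplies channels by L⁻¹ where cov = L·Lᴴ.
Channel combination is a per-voxel matched filter: weights are the
conjugate of the time-summed complex pyruvate signal, unit-normalized
across channels and shared by all metabolites (time-summed rather than
peak-frame for noise averaging); all-zero-pyruvate voxels are zeroed
and flagged.  Phasing removes the per-voxel zero-order phase at the
pyruvate magnitude peak and keeps the real part; first-order
(frequency) phase is out of scope.

HOSVD denoising treats the data as a 5-mode tensor (metabolite, time,
slice, row, column), truncates each mode's singular basis, and
reconstructs.  At full ranks this is the identity (≤1e−10); truncation
error is monotone in rank.  The default scree criterion retains modes
covering 99.9 % of each mode's squared singular spectrum — deliberately
conservative, because the metabolite mode is dominated by pyruvate and
aggressive truncation there mixes metabolites into each other and
biases downstream kinetics (a 95 % criterion truncates the metabolite
mode to rank 1 and biased demo-pipeline k_PL by ~25 %).

AUC maps sum the dynamic data over time; SNR is defined as
AUC/(noise_sd·√n) since independent per-frame noise adds in quadrature
over the sum, and the validity mask keeps voxels strictly above the
SNR-5 threshold.

## Asymmetry statistic

The map is linearly interpolated 2× in-plane, z-normalized over the
analysis region (symmetric mask minus exclusions; a constant map is
flagged degenerate), and restricted to brain ∩ mirrored brain.  Lesion
and resection-cavity masks are excluded together with their midline
reflections, so only normal-appearing tissue is compared.  The midline
is the column-center plane of the brain-mask bounding box (an explicit
midline can be supplied); even-width masks reflect about the
half-integer center.

Each point's feature vector concatenates its 3×3 in-plane patch with
its coordinates scaled by a weight w (default 1.0, in voxel units of
the interpolated grid; comparisons across datasets must hold w fixed).
Right-hemisphere patches are column-flipped and coordinates are
expressed in the mirrored frame, so a perfect mirror pair has feature
distance zero.  s(p) is the minimum Euclidean feature distance to any
valid opposite-hemisphere point in the same slice (cross-slice search
is not performed; patches that touch excluded or out-of-mask voxels are
skipped).  S is the mean of s over both hemispheres, overall and per
slice.  S = 0 iff the included data are mirror-identical, and S is
invariant to affine rescaling of the input map and to reflection.

## Coverage

Prescriptions are oriented boxes (center, orthonormal rotation, extents
in mm).  Rasterization includes a voxel iff its center lies in the box,
half-open on the max faces, making Dice deterministic across platforms;
the default comparison grid is fine relative to the box (1–2 mm).  The
serial-consistency harness models two exams differing by a rigid head
rotation: an atlas-anchored prescription images the same anatomy-fixed
box in both exams (Dice 1 up to rasterization), while a fixed
scanner-axis prescription appears counter-rotated in the anatomy frame
and loses overlap.  Atlas registration itself is out of scope;
prescriptions enter as geometry.

## Acquisition utilities

The urea-referenced pyruvate center frequency is f_urea + 270 Hz; the
water-referenced one is f_water × 0.251491899 (empirical ¹H→¹³C
conversion ratio).  The excitation response is modeled as a Gaussian
passband exp(−4 ln2 · Δf²/FWHM²) parameterized by the pulse's 130-Hz
FWHM — a model of the pulse, not a measured profile, and pluggable.
Phase-encode voxel bandwidth is 1/(matrix_n·echo_spacing) (60.562 Hz
for 16 × 1032 µs); off-resonance shifts data by offset/bandwidth voxels
and is flagged beyond half a voxel.  QC release criteria follow the
printed inequality semantics exactly: polarization ≥15 %, concentration
220–280 mM inclusive, EPA ≤3.0 µM, pH 5.0–9.0 inclusive, temperature
25–37 °C inclusive, volume strictly >38 mL, bubble point passed.

## Synthetic data: what it does and does not emulate

The phantom is an ellipsoidal, mirror-symmetric brain with a
gray-matter shell, a lateralized spherical T2 lesion containing a tumor
core, and NAWM defined as interior minus gray matter and lesion; all
generators are bit-reproducible under a seed.  Coil profiles are smooth
Gaussian sensitivity lobes with slowly varying phase; channel noise is
circular complex Gaussian with a configurable Hermitian covariance
(demo default: neighbor-coupled ρ^|i−j| with ρ = 0.3).  The demo
pipeline noise level is set so NAWM-scale fractional rate errors land
near those reported for in-vivo white matter (k_PL ~ a few %, k_PB
~25 %).

Not emulated: vascular anatomy and perfusion heterogeneity, B₀
inhomogeneity and EPI distortion (image-domain simulation only),
k-space sampling, motion, and the in-vivo bolus-shape variability.
Passing tests therefore validate the *analysis* (estimators, statistics
and their implementations), not the fidelity of any particular
acquisition; conclusions about patient data that hinge on bolus shape
or bicarbonate SNR (see the delay-sweep note above) do not transfer
automatically.

## Numerical choices and degenerate inputs

- Propagator difference quotients use `expm1` with relative-scale
  degeneracy thresholds, accurate for T1 → ∞ and sub-millisecond steps.
- Fit convergence failures mark voxels invalid rather than raising;
  all-zero product traces yield k ≈ 0 with an uninformative error.
- Dice of two empty volumes, flat inflow traces, empty masks and empty
  point sets raise explicit `ValueError`s.
- The problem sizes used in tests and the acceptance script (16×16×8
  phantoms, 200-voxel Monte-Carlo, 0.1-s × 11-s sweeps) are chosen as
  the smallest at which the statistical assertions are stable.

## Known limitations

- T1 values are assumed, not fitted; rate estimates inherit any T1
  misspecification.
- The asymmetry midline assumes prior anatomical alignment; no midline
  estimation is performed.
- The excitation response is a Gaussian surrogate for the true
  spectral-spatial profile.
- The delay sweep's zero-initialized refit is one convention among
  several; `init="data"` is available and nearly delay-invariant.
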