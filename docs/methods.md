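# Methods

## Compression model

The compressor converts a uniformly sampled ECG from `fs_in` to an
effective output rate `K` (both in Hz) through a rational resampling
chain parameterized by an additional intermediate rate `B ≥ K`. The three
rates are reduced to exact integer factors: the conversion runs on the
design grid `L = lcm(fs_in, B, K)` with upsampling factor `up = L/fs_in`
and downsampling factor `down = L/K`, so `fs_in · up / down = K` holds as
exact rational arithmetic (rates that are not integers are handled through
their decimal representation as fractions; irrational approximations are
never used). The output rate is always `K`; `B` matters only through the
design grid, which changes the realized filter slightly — this is why
grid cells with the same `K` but different `B` score slightly differently
in the optimizer.

### Filter

The combined anti-imaging/anti-aliasing low-pass is a Kaiser-windowed
sinc, linear phase, odd length:

* passband gain `up` (restores amplitude after zero-stuffing; the discrete
  counterpart of the ideal response's gain `B`),
* stopband edge at `f_c = min(fs_in, B, K)/2` Hz (the binding Nyquist
  frequency — for decimation this is `K/2`),
* transition band of width `0.1 · f_c` placed immediately below `f_c`
  (passband edge `0.9 · f_c`), so no aliased energy leaks above the output
  Nyquist rate,
* default stopband attenuation 60 dB (configurable). Tap count follows the
  Kaiser design formula; at the published operating point
  (360 → 80 Hz via 390 Hz, grid 9360 Hz) this gives 8485 taps on the grid,
  i.e. an effective ~330-sample support at the input rate.

Taps are normalized so the DC response equals `up` to 1e-6 relative; the
`FilterSpec` constructor enforces symmetry and DC gain as invariants.

### Edge and length conventions

Output length is `ceil(n_in · up / down)`. The symmetric FIR's group
delay `(N−1)/2` grid samples is compensated exactly inside the conversion
(the output phase is aligned with the input; the identity spec is a true
passthrough). Edges are zero-padded, so the first and last ~half filter
length of output are transient; evaluation utilities that quote spectral
properties trim edges, while the QRS pipeline simply never places beats
that close to the record boundary.

The fast path (`rational_resample`, scipy `upfirdn` polyphase) is checked
against an intentionally literal reference (`resample_literal`:
zero-stuff, `np.convolve`, strided pick-off) that shares only the index
convention; the suite requires agreement to 1e-9 on random signals and
factors, and observed agreement is ~1e-14.

### Reconstruction and PRD

`reconstruct` inverts the factors on the same design grid and trims/pads
to the original sample count, giving the delay-aligned `x̂` used for
`PRD = ‖x − x̂‖₂ · 100 / ‖x̂‖₂`. The PRD denominator is the
*reconstructed* signal and no mean is removed — that is the printed form
of the metric this package reproduces; because other literature normalizes
by the original or de-meaned signal, `prd()` exposes
`denominator={"reconstructed","original"}` and `demean` switches, with the
printed dialect as default.

## QRS detector

Four stages on the analyzed (usually compressed) signal:

1. third-order Butterworth bandpass `f1=8`–`f2=20` Hz, applied
   forward-backward by default (zero phase keeps block centers on the R
   peaks; a causal single-pass mode exists for streaming parity),
2. element-wise squaring,
3. two centred moving means of the squared signal with shrinking windows
   at the edges: event window `w1 = 97 ms` and cycle window `w2 = 611 ms`,
   converted to the nearest odd sample count (minimum 3; 97 ms at 80 Hz is
   7 samples),
4. blocks of interest where `MA_event > MA_cycle + β·s·z̄`, with `z̄` the
   global mean of the squared signal, `β = 8` and scale `s = 0.01`; blocks
   narrower than the event window are rejected and each surviving block
   yields one R index at the argmax of `|filtered|`.

The β offset deserves a note: the published parameter is a bare `β = 8`
with no printed formula. Interpreted as a multiple of the mean squared
signal it suppresses every block (8× the global mean energy exceeds the
event average even at QRS centers); interpreted as a *percentage* — the
convention of the two-moving-average detector family this stage comes
from — it is an 8% offset and reproduces the expected behavior. The
percentage reading is the default and `beta_scale` is the explicit hook
for any other convention. This is the main fidelity risk for reproducing
corpus numbers exactly, together with the beat-matching tolerance below.

Thresholding is relative (cycle average + fraction of mean energy), so
detection is invariant to positive amplitude scaling — asserted in the
suite at scales 0.1 and 10.

Detected indices live at the analyzed rate; `DetectionResult.map_indices`
converts with `round(i · fs_target / fs)`, and the matching tolerance
absorbs the ≤ ½-sample quantization.

## Baseline predictor

The lossless-compression reference predicts each sample from its `m`
predecessors with fixed coefficients (default slope predictor `(2, −1)`,
which annihilates linear trends); prediction error is exact beyond an
`m`-sample warm-up where `x̂ = x`. For detection the error magnitude is
Savitzky–Golay smoothed (polyorder 3, window 15 samples — the only
feasible reading of the published `(W, q)` pair, since a window of 3
cannot carry a degree-15 polynomial) and squared into the same block
thresholding as the main detector. The published baseline is described as
*adaptive* without an update rule; a sign-sign LMS variant is provided as
a clearly labelled extrapolation, not a reproduction.

## Evaluation

Beat matching is one-to-one within ±75 ms (no tolerance is printed in the
source literature; 75 ms is the conventional beat-by-beat comparison
window, exposed as `tol_s`/`--tol`). The matcher walks both sorted
sequences pairing the first feasible reference/detection; for interval
tolerance on a line this attains maximum cardinality (crossing matches can
always be uncrossed), and the suite cross-checks it against an independent
dynamic-programming oracle on random instances. Pooling over records sums
TP/FP/FN before computing rates (the table-footer convention). BCR uses
equal 11-bit sample widths by default (the MIT-BIH ADC resolution), so
`BCR = fs_in/K`.

## Grid optimizer

`grid_search` enumerates every `(B, K)` cell of a rectangular grid
(default 360–500 × 50–360 Hz in 10 Hz steps — every published value is a
multiple of 10, the step itself is not printed), skipping infeasible cells
(`K > B`, or `K ≤ 2·f2` where the detector's bandpass no longer fits under
the compressed Nyquist rate), and ranks by pooled `g` descending. Ties
break toward higher `K` (cheaper at equal accuracy) then lower `B` — an
arbitrary but documented order. The search is the scalarized argmax of
`g`; rows dominated in (SE, +P) space are flagged as a diagnostic only.

## Synthetic generator

Each beat is five Gaussian bumps: P (−200 ms, 0.15 mV, σ 22 ms), Q and S
(∓half the QRS width, −0.15 of R, σ = width/10), R (1 mV, σ = width/5,
default width 80 ms) and T (+300 ms, 0.3 mV, σ 50 ms). The RR schedule is
`60/HR` plus Gaussian jitter truncated at ±3σ and floored at 300 ms; beats
keep a 0.45 s margin from the record edges. PVC-like beats (probability
`pvc_rate`) double the QRS width, drop the P wave, invert the T wave,
raise R by 20% and stretch the following interval by 1.5× (compensatory
pause). Tall-T mode sets the T amplitude to 1.5× R — the classic
false-positive trap for amplitude-threshold detectors. Ground-truth
`beat_indices` are the exact sample positions of the generated R maxima
(each nominal index is snapped to the local argmax of the clean signal
within ±3 samples, before any noise is added). Noise is white Gaussian
plus a single-tone baseline wander; one integer seed drives jitter, PVC
placement and noise, and for a fixed seed the white-noise perturbation
scales proportionally with the requested level, which makes
noise-degradation sweeps monotone by construction.

What the generator does *not* emulate: realistic beat-to-beat morphology
variability, atrial arrhythmias, electrode motion artefacts with
steplike discontinuities, muscle noise spectra, or multi-lead geometry.
Perfect synthetic scores therefore demonstrate the pipeline's mechanics
(rates, alignment, thresholds, block logic), not clinical performance;
corpus-level numbers require the real MIT-BIH/QT recordings, which cannot
be redistributed with the package.

## Problem sizes and defaults

The suite and the acceptance script use 2–5 minute synthetic records
(one to three per scenario) and a 3×3 grid around the published optimum —
sizes chosen so the whole verification cycle runs in seconds while every
record is still long compared to the 611 ms cycle window and the filter
support. Defaults throughout equal the published operating point: B = 390,
K = 80, bandpass 8–20 Hz, windows 97/611 ms, β = 8, stopband 60 dB,
tolerance 75 ms, 11-bit samples.

## Known limitations

* WFDB support covers single-segment headers, signal formats 16 and 212,
  and MIT annotation files — enough for MIT-BIH/QT and the package's own
  round-trips, not the full format zoo.
* Corpus-exact TP/FP/FN reproduction depends on two conventions the
  source literature does not print (β scaling and match tolerance); both
  are exposed as parameters.
* The `K ≥ 50 Hz` floor on `ResampleSpec.create` reflects the optimizer's
  lower grid bound rather than a hard sampling-theory limit (the printed
  Nyquist discussion is self-inconsistent); pass `k_floor=None` to explore
  below it.
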