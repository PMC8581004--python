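# Models, conventions and numerical choices

This note documents the science inside `echoarray`: what each stage
assumes, which parameters matter, where the design was genuinely open and
what was chosen, and what a green test does and does not establish.

## Coordinate and unit conventions

Right-handed global frame, meters, z-up. Azimuth is measured
counter-clockwise from +x in the x-y plane; elevation from the horizontal
plane (+z is elevation 90°). Amplitudes are dimensionless in [−1, 1]
(16-bit PCM full scale); "intensity" means amplitude squared (linear
power). Default speed of sound is 343 m/s (dry air at 20 °C); a layout's
medium can state a temperature (c = 331.3 + 0.606·T m/s, a standard linear
fit valid for −40…60 °C) or an explicit value.

## Capture capacity

A recording device buffers `n_c` 1-bit PDM streams at `f_s` bits/s per
channel into `mem` bytes of RAM, with the channel count padded to the next
multiple of 8 (byte packing). The maximal capture duration is
`D = 8·mem / (f_s·n_c)` — e.g. 180 MB at 4.5 MHz with 11 requested
channels (padded to 16) gives exactly 20 s. The division is done in exact
rational arithmetic so scaling identities hold bit-exactly. Capture runs
into a circular buffer; a trigger saves the most recent `D` seconds. If
the buffer holds less than requested, what exists is returned with a
warning rather than an error (in the field, a short recording beats none).

## PDM→PCM conditioning

Decoding maps bits to ±1, low-pass filters with a 6th-order Butterworth at
f_c = 100 kHz, quantizes to the 16-bit grid (round half away from zero,
saturating), and decimates by an integer factor (4.5 MHz → 450 kHz is 10).
Two deliberate choices:

* **Causal single-pass filtering** is the default. It matches the one-way
  magnitude response `|H(f)| = 1/√(1+(f/f_c)^12)` that a hardware
  decimation chain realizes (−21.2 dB at 150 kHz relative to 40 kHz);
  forward-backward filtering would square the magnitude (−42 dB) while
  zeroing phase. `zero_phase=True` is available when group delay matters
  more. The group delay of the causal filter is common to all channels and
  therefore cancels in every TDoA.
* **The sigma-delta test encoder is second order by default.** A
  first-order loop at this oversampling ratio (effective OSR 22.5 for the
  0–100 kHz band) has a theoretical in-band SNR ceiling near 35 dB for a
  full-scale sine — physically incapable of the ≥ 40 dB the chain is
  validated against — and real PDM microphones use higher-order
  modulators. The second-order loop uses clamped integrators and a 1.25×
  quantizer feedback reference so a true full-scale ±1 input stays inside
  the stable range; measured round-trip SNR is ≈ 54 dB. `order=1` keeps
  the classic textbook modulator for behavioral tests (zero input →
  strictly alternating bits).

## PRBS synchronization

All devices record a shared 1-bit pseudo-random signal whose
autocorrelation has a single sharp peak; cross-correlating two sync
tracks recovers their constant clock offset. (Clock *drift* is not
modeled — offsets are assumed constant over a recording, as for the
short triggered captures the system produces.)

* **Parameter selection.** With `f_min` the slowest device rate and
  `T_s = 1/f_min`: `P_min = 2·T_s` guarantees every hold spans at least
  two samples of the slowest device. For a minimal synchronizable
  fragment of `L` samples at `f_min`, the expected transition count is
  `K = 2·L·T_s/(P_min·(P_max/P_min+1))` (fragment duration over mean hold
  period). `P_max` is the largest integer multiple of `P_min` keeping `K`
  strictly above 10; with `P_min = 2·T_s` this reduces exactly to
  `K = L/(r+1)`, so the search needs no floating-point care. The strict
  inequality (rather than ≥) reproduces the canonical worked selection
  for a 450 kHz / 700 / 300 / 120 Hz device set: P_min ≈ 16.7 ms,
  P_max ≈ 167 ms, K ≈ 10.9.
* **Hold-time distribution** is i.i.d. uniform on [P_min, P_max]. Only
  the bounds and the expected count are prescribed anywhere; uniform is
  the maximum-entropy choice consistent with the mean-period algebra
  of K.
* **Offset estimation** mean-centers both tracks (states → ±1), resamples
  to the faster rate by zero-order hold (the signal is genuinely
  piecewise-constant; band-limited interpolation would ring), and takes
  the argmax of the full FFT cross-correlation. Accuracy is one sample
  period of the *slower* track. The quality ratio divides the main peak
  by the largest correlation outside an exclusion zone as wide as the
  longest observed hold (≈ P_max): the correlation main lobe of a
  random-telegraph signal is as wide as its holds, so a narrower
  exclusion would measure the lobe's own shoulder and bottom out near
  1.6 even for perfect tracks. With K ≥ 10, quality ≥ 2 in ≥ 98% of
  seeded trials; estimates below threshold are flagged low-confidence and
  alignment refuses them unless forced.
* **Alignment** shifts every device onto the clock of the
  highest-sample-rate device (ties broken by device id) and trims to the
  common overlap.

## Matched-filter detection

Each channel is correlated with a known call template; the trace is
normalized by the template norm and the local signal energy, so a perfect
match scores 1 at the sample where the template *starts*. Candidate call
times are peaks of the strongest channel's trace, separated by at least
`min_gap` (default 30 ms) and above a floor (6× the trace median, an
absolute 0.2, and 30% of the global maximum — the latter two keep silence
and pure noise from producing candidates). Per channel, the arrival is
the trace argmax within ±`window` (default 10 ms, bounding the physical
spread of one call's arrivals across the array; window < min_gap so two
calls cannot share a window), and the amplitude is the maximum of the
analytic-signal (Hilbert) envelope in that window — robust to carrier
phase, unlike the raw |sample|.

The per-channel quality is the peak-to-sidelobe ratio inside a
`min_gap`-sized segment (so neighboring calls are not counted as
sidelobes), with an exclusion of half the template length around the
peak. Clean chirps score ≈ 9 (the local-energy normalization caps noise
sidelobes near 1/√L regardless of SNR); overlapping echoes or distorted
arrivals approach 1. Channels below `quality_threshold` (default 2) are
excluded from localization. GCC weighting is plain cross-correlation by
default; PHAT is a flag (whitening helps in reverberant scenes but
discards amplitude structure).

## Probabilistic TDoA localization

For a detection with accepted channels, the reference channel is the
highest-quality one; measured delay differences are
`Δ_i = t_i − t_ref`. For each 3D grid point `p` the model predicts
`Δ̂_i(p) = (|p−m_i| − |p−m_ref|)/c`, and

    loglik(p) = − mean_i (Δ_i − Δ̂_i(p))² / (2·σ_eff²)

normalized over the grid. The MAP cell is the estimate; the uncertainty
cloud is every cell with likelihood ≥ `credibility_fraction` (default
0.5) of the maximum, with deterministic lexicographic tie-breaking.
Fewer than 4 accepted channels raises an underdetermined error
(`allow_underdetermined=True` exposes the ambiguity surface itself, e.g.
the two-mic hyperboloid).

Two conventions here are this package's own and deserve emphasis:

* **Grid-quantization inflation.** Evaluating only at cell centers
  leaves up to half a cell of unmodeled path length, i.e. a timing error
  of `σ_q = cell/(2c)` (73 µs for 5 cm cells — an order of magnitude
  above a 2-sample timing σ at 450 kHz). The likelihood uses
  `σ_eff² = σ_t² + σ_q²`; without it any realistic grid yields
  meaninglessly overconfident single-cell posteriors.
  `grid_quantization=False` restores the bare model for fine grids.
* **Mean, not sum, over channels.** A summed misfit concentrates the
  likelihood-fraction cloud as 1/√n_mics, so denser arrays would display
  *smaller* uncertainty regions for the same per-channel error —
  collapsing to one cell at 64 mics. The per-channel mean keeps the
  cloud's spatial extent a property of the geometry and timing error,
  not the channel count, and makes the 0.5-fraction cloud conservative:
  measured coverage of the true cell is ≈ 99/100 under matched noise.
  The MAP is unaffected (monotone transform).

Defaults: σ_t = 2 samples at 450 kHz; grid resolution 5 cm at flight-room
scale, 0.5 m at rooftop scale.

## Angle of arrival and cone fusion

A 10-mic board spanning ~10 cm sees essentially plane wavefronts beyond a
meter or two, so its delays constrain direction only. About the board
centroid the predicted relative delay for unit direction `u` is
`τ̂_i(u) = −(x_i·u)/c`; measured and predicted delays are both centered
(removing the unknown emission time) and scored with the same Gaussian
misfit on a regular az×el grid over the front hemisphere (default 2°×2°;
a coplanar board cannot distinguish mirror directions through its own
plane, so the back hemisphere is excluded by convention). Normalization
weights cells by solid angle (cos el).

Fusion evaluates each board's hemisphere along the direction from that
board to each 3D grid point (nearest-cell lookup — the error is bounded
by the angular cell size; at range R a cell of s degrees blurs positions
by ≈ R·s·π/180, so choose the angular step to match the position grid:
1° at 30 m for 0.5 m cells), multiplies across boards and normalizes. A
single board yields a posterior elongated along the ray; it is returned
flagged `range_ambiguous`, never silently resolved.

## Beam images and statistics

A detection's calibrated per-mic window-max amplitudes on a regular
planar grid form one image per call, pixel = amplitude² (linear power;
dB is display-only). Missing or rejected mics (up to 10% of the grid)
are filled with the mean of their valid 4-neighbors and flagged.
Interpolation is bicubic on a fine grid stepping at 1/factor of the mic
spacing, so original nodes land exactly on fine samples and keep their
values; the output is ((n−1)·factor+1) per axis and factor 1 is the
identity.

* **Level of focus** is the spread ratio `LF = s_w/s_u`: the
  intensity-weighted RMS distance of mic positions from the
  intensity-weighted centroid, over the same RMS with uniform weights
  (the maximally distributed reference). 0 = all energy on one mic,
  1 = uniform; values > 1 are possible for strongly multimodal
  footprints and are reported as-is. The numeric definition is this
  package's construction — chosen to be dimensionless, invariant to
  global intensity scaling and grid translation, and consistent with a
  0.5 working threshold for "focused" calls (`focus_filter` default).
* **Beam centroid** is the intensity-weighted mean position;
  `centroid_distance` is its Euclidean distance to a target (e.g. a prey
  item) in the grid plane. No 1/r spreading compensation is applied by
  default (the aim of the beam, not the absolute level, is the object of
  study); an optional correction hook exists.
* **Overlay**: a homography estimated from the four grid corners as seen
  in a video frame (direct linear transform via scikit-image; corners
  must be cyclic with no three collinear) warps the colormapped,
  normalized image into the camera view; alpha-blending leaves the frame
  untouched outside the warped quadrilateral. A sequence overlay holds
  each call's image until the next call.

## The scene simulator: what it emulates, what it does not

The generator renders exactly the world the analysis chain assumes:
linear-FM chirps (default 80→30 kHz, 3 ms, 10% raised-cosine tapers —
the downward sweep of a typical vespertilionid echolocation call) emitted
along a piecewise-linear trajectory with aim directions; a baffled
circular-piston directivity `|2·J1(ka·sinθ)/(ka·sinθ)|` (default radius
4 mm, evaluated at the chirp center frequency); spherical spreading
(1 m reference); band-limited fractional delays (64-tap windowed sinc,
group-delay error ≤ 1/20 sample in band); per-device clock offsets with
the shared PRBS sampled into each device's sync channel; white Gaussian
noise per channel; and optionally one planar specular reflector via the
image-source method (mirrored source, reflected aim, coefficient ≤ 1 —
the water-surface scenario).

Not modeled, deliberately: atmospheric absorption by default (short
ranges; a dB/m hook exists for ~75 m bird scenes), Doppler (ms calls at
m/s speeds give sub-sample shifts at these ranges), higher-order
reflections, frequency-dependent microphone responses, and any deviation
of a real animal's beam from the piston stand-in. Consequently a green
end-to-end test establishes that the chain is *self-consistent* —
correct recovery of the generator's own physics — not that the piston
model matches any particular animal's measured beam. Ground-truth
arrival times are closed-form (`emission + r/c`), so detector and
localizer accuracy is measured against exact values, and all rendering
is reproducible from a single seed.

## Known limitations

* Constant clock offsets only; long unsynchronized recordings with
  drifting oscillators would need rate estimation.
* The candidate anchor is the single strongest channel; two animals
  calling within one `min_gap` on different parts of a large array merge
  into one candidate set. Multi-source data association is out of scope
  (consecutive calls are connected purely by time order).
* The uncertainty cloud is a likelihood-fraction region under an
  assumed-Gaussian, assumed-independent timing-error model, conservative
  by construction; it is not a calibrated credible interval.
* Beam statistics assume the planar grid geometry; sparse or non-planar
  layouts raise errors rather than approximating.
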