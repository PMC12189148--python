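# Methods

## Model overview and assumptions

`soniclimate` models pre-attentive sound appraisal as a fixed signal-
processing chain: a tonotopic energy representation, a multi-timescale
foreground/background separation, a linear mapping of per-band audibility
onto the pleasantness × eventfulness circumplex, and long-term histogram
aggregation.  The core assumption is that appraisal is driven by *how far
a component rises above a slower-changing background* (audibility in dB),
not by total loudness, and that the time scale on which a component
develops — sub-second vocalizations, 5–30 s passages, minute-to-hour
machinery, constant background — determines its qualitative effect.

## Time–frequency front end

The cochleogram is an ERB-spaced, gammatone-shaped band-grouped STFT
rather than a transmission-line cochlea simulation: any tonotopic energy
representation with the right invariants serves the later stages, which
only consume band levels in dB.

* Channels: 64, equally spaced on the ERB-number scale from 50 Hz to
  min(23 kHz, 0.45·fs).  A 20 Hz lower edge is impractical at 20 ms
  frames; 50 Hz is the deliberate default, configurable.
* Frames: 50 /s (Hann window of four hops, 75 % overlap).  The longer
  window trades ~80 ms of temporal smearing for the spectral resolution
  needed to keep low-frequency channels tonotopic.
* Per-bin power normalization: each FFT bin's squared channel gains sum
  to one, so channel energies are a partition of total signal power.
  Consequences: the sum over channels equals the signal's mean square
  (Parseval), a tone at any channel's center frequency peaks in that
  channel, and broadband dB(A) sums need no overlap correction.
* Levels are dB re digital full scale, floored at −100 dB (silence maps
  exactly to the floor).  A `calibration_offset` (default 97 dB, placing
  a full-scale sine near 94 dB SPL) converts to approximate dB SPL only
  when dB(A) levels are computed; audibilities are differences and need
  no calibration.
* In broadband dB(A) sums, channels at the floor are silence sentinels
  contributing zero energy; an all-floor frame reports exactly
  `floor + calibration_offset` instead of an n-channel floor sum.
* A-weighting uses the IEC 61672 pole-zero magnitude response,
  re-referenced so the gain at 1 kHz is exactly 0 dB.

## Layer decomposition

"Components that change considerably within τ" is operationalized as a
causal running low percentile: the slow envelope at time constant τ is
the q-th percentile (default q = 0.10) of the trailing τ-long window,
per channel, clamped per cell to never exceed its input.  The percentile
is the k-th order statistic with k = ⌊q·(m−1)⌋ (numpy's `"lower"`
method); this exact definition is frozen so that an independent
brute-force window scan reproduces the implementation bit for bit.

* The cascade runs fast → slow; each slower envelope consumes the
  previous clamped envelope.  Clamping simultaneously guarantees
  non-negative foreground audibilities, envelope ordering
  (S_fast ≥ S_slow) and exact additive reconstruction.
* Warm-up: until τ of history exists the window is the available
  history; those frames are flagged provisional.  Recordings shorter
  than the slowest τ are allowed.
* A low percentile (rather than a minimum) rejects isolated dropouts
  and makes the envelope's response to a level step predictable: it
  tracks a sustained step no earlier than (1−q)·τ after onset.  An
  event of duration d therefore routes its energy to the layer between
  τ_fast and τ_slow cleanly when d ≳ 5·τ_fast and d ≲ 0.9·τ_slow; the
  natural taxonomy (0.2 s calls, 5–30 s passages, multi-minute
  machinery) sits comfortably inside these bands for τ = {1 s, 1 min,
  1 h}.
* Complexity: for long windows a Fenwick-tree order-statistic counter
  over per-channel coordinate-compressed values gives O(log n) per
  frame (an hour window at 50 frames/s spans 180 000 frames; an
  O(window)-per-frame scan would be prohibitive).  Short windows use a
  vectorized partition.  Both paths are bit-identical.
* Idempotence: re-running the tracker on its own output is exact for
  the signal class the decomposition targets — upward events over a
  background, occupying less than the fraction q of any window.  For
  long *downward* excursions the clamp follows the drop immediately,
  which lengthens the low period and a re-run can lower the envelope
  further; this is accepted tracker behavior, not a defect.
* The decomposition operates in the dB domain, consistent with
  audibility being defined in dB.

## Appraisal

Each configuration row carries a layer, a frequency band, a value range,
a unit and a quadrant.  Row values are pooled per second: the per-frame
maximum across the band's channels, then the 90th percentile over the
frames of the row's `scope`-second look-back window restricted to
*active* frames (band maximum > 0; 0 dB if none).  The activity
restriction lets a single brief call influence the full 5 s scope of the
sub-second rows, which is the point of the scope parameter; a plain
percentile over a mostly silent window would erase brief events.  Hour-
background rows use the A-weighted broadband level of the layer instead.

Weights scale linearly within the value range and clip to [0, 1].  The
embedded default rows: hour background 30–70 dB(A), full band → boring;
hour foreground 0–20 dB split at 2300 Hz → boring (low) / center (high);
minute foreground 0–15 dB, full band → chaotic; second foreground
0–20 dB split at 2300 Hz, 5 s scope.

Two ambiguities in the source parameter table were resolved as follows:

* Second-foreground band assignment: the tabulated row alignment reads
  low band → calm / high band → lively, but the descriptive text and the
  worked dawn-chorus example assign high-frequency bird-like sounds to
  calm and the human vocal band to lively.  The default follows the
  descriptive reading; `default_config(band_assignment="table")`
  restores the tabulated one.
* dB(A) scope: the accompanying text attributes dB(A) to the hour
  foreground, while the table marks the hour *background* as 30–70
  dB(A) and the hour foreground as 0–20 dB.  The table is followed:
  the background is an absolute level, all foregrounds are
  audibilities.

Combination rule: quadrant unit vectors are the circumplex diagonals
(calm (+1,−1)/√2, lively (+1,+1)/√2, chaotic (−1,+1)/√2, boring
(−1,−1)/√2, center (0,0)); the appraisal point is Σ wᵢuᵢ / max(1, Σ wᵢ),
radially clipped to the unit disk.  This makes a single saturated row
reach the rim, a single weak row proportionally short, opposing rows
cancel, and "center" rows damp extremity (their zero vector still
enters the denominator).  The normalization and the pooling statistic
are this package's design choices; only the weighted-vector-sum-in-a-
disk structure and the row parameters are given.

One emergent property worth knowing: a steep level onset (e.g. an
abruptly rising car passage) produces a strong transient in the
sub-second foreground for the first ≈(1−q)·τ₁ of the rise, so the first
seconds of a passage can briefly pull toward lively/calm before the
minute layer dominates.  The method is reporting, correctly, that a
fast-developing component exists; gently rising passages do not show it.

## Sonic climate

Per-second points are binned on a 21 × 21 grid over [−1, 1]² (odd bin
count keeps the origin interior to the central bin); bins are half-open
with the last edge closed, fractions sum to 1.  Quadrant fractions
assign the central row and column (bins straddling zero) to "center".
Climate comparison uses total variation distance ½Σ|h₁−h₂|.  Display
contours are drawn at the bin-fraction thresholds containing 50/90/99 %
cumulative mass — presentation only, configurable.

## Audibility analysis

Local SNR is the per-second maximum over time–frequency cells of
(target − background) level; 0 dB means the most audible target
component equals the background energy at its cell.  Exceedance curves
use strict inequality (a tie does not exceed), thresholds −10…+30 dB in
1 dB steps by default, and are evaluated per second to match the
appraisal cadence.  Targets and backgrounds come either from two
recordings (pre/post-mitigation style) or from a LayerSet, where a
foreground layer is already an audibility against its own slower
background.

## Synthetic scenes

The generator emulates the source taxonomy schematically: band-limited
Gaussian noise under parametric envelopes (Hann pulse trains, sin²-edged
passages and quasi-stationary events, constant backgrounds, ramps),
scheduled with per-event bands, peak levels and seeded randomness, in
the audio domain or directly in the cochleogram domain (hour-scale
events would be wasteful to synthesize as audio).  Every event carries
its expected layer and quadrant, so routing and end-to-end appraisal are
scored against ground truth.

What it does not emulate: harmonic structure, reverberation, source
motion (Doppler, level trajectories of real pass-bys), overlapping dense
mixtures, or stress-distorted vocalization cues.  Passing tests
therefore demonstrate the mechanics of scale separation and appraisal
geometry on controlled material, not field validity on real recordings.

Test problem sizes: scenes of 120–260 s at 20 frames/s with scaled time
constants τ = {1, 10, 100} s and matching event durations (0.24 s
pulses, 6–8 s passages, 75 s quasi-stationary events).  The
decomposition is parametric in τ, so routing behavior transfers to the
full-scale constants; the full-day frame cadence (86 400 appraisals) is
verified analytically alongside the scaled runs.

## Known limitations

* The front end is a spectral approximation; no phase, fine structure,
  binaural cues or continuity-preserving resynthesis.
* Appraisal weights are the example parameter set, not fitted to human
  judgments; no personalization (noise sensitivity, attention state).
* No source classification inside layers: a jackhammer and a wind gust
  with the same time scale and band appraise identically.
* dB SPL calibration is nominal unless a measured offset is supplied.
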