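# Methods

## The measurement problem

A tetraspanin–pHluorin reporter is dark inside acidic multivesicular bodies
and fluoresces at extracellular pH, so each MVB–plasma-membrane fusion event
appears in a TIRF movie as an abrupt, localized brightening. The analysis
must (i) find these brightenings against camera noise and a bright resting
membrane, (ii) reject artefacts (drifting vesicles, focus ripple, re-used
sites), (iii) characterize each event's size, brightness and decay
kinetics, and (iv) ask whether release is spatially clustered ("EV
hotspots") and temporally synchronized. `evhotspot` implements this chain
deterministically, with every threshold exposed in `RunConfig` and echoed
into all outputs.

## Detection model

Frame differencing isolates *new* fluorescence: `D_k = I_{k+1} − I_k`
(gap 1), so an event with onset frame `t0` produces one positive blob in
difference frame `t0 − 1`. Only positive differences are thresholded —
departures and bleaching are negative-going and can never become
candidates. Blobs are 8-connected components with area in
`[min_area, max_area]` (defaults 4 and 200 px); their intensity-weighted
centroid, area and mean difference intensity are retained. Because an
interactively tuned threshold is not reproducible, the default threshold is
a robust per-stack statistic of the positive difference values,
`median + k·1.4826·MAD` with `k = 5`; thresholding is per stack, not per
frame, so one value governs the whole acquisition. Candidates recurring
within 2 px in consecutive difference frames are merged and keep the
earlier onset, so a slow riser is counted once.

Known resolution limit: two events that share an onset frame *and* lie
within roughly one blob diameter (≈1 µm at the default optics) fuse into a
single candidate. This truncates the measured synchronized fractions —
exactly the events most likely to be synchronized (same hotspot, same
frame) are the ones at risk of fusing — and is the main reason the
synchrony benchmark recovers the planted *direction* robustly but not the
planted magnitude.

## Event profiles and quality control

Each candidate's trace is the mean intensity in a disc ROI (radius 4 px) at
the detection centroid over all frames. The baseline is the median of up to
10 pre-onset frames and the noise scale σ their scaled MAD. A pre-onset
window shorter than 3 frames is flagged low-confidence; because a 1–3
sample MAD is an unusable noise estimate, σ is floored by a robust
whole-trace estimate, `1.4826·MAD(ΔI)/√2` over the trace's first
differences, which is insensitive to the single step and smooth decay the
event itself contributes.

The peak is searched within 3 frames of onset (the rise is instantaneous at
the frame rate; a wider search lets plateau noise drag the peak away from
onset). The by-eye exclusion criteria of the interactive workflow are
operationalized as three ordered rules:

1. **minimal change** — `Δpeak < k_snr·σ` (default `k_snr = 3`);
2. **lateral movement** — a follow-the-spot tracker (window radius equal to
   the ROI radius, re-centred each frame on the previous position, weights
   `max(I − baseline − 2σ, 0)`) follows the signal during its *contiguous*
   visible lifetime from onset; if the tracked centroid moves more than
   `d_max = 0.5 µm` from the detection centroid the event is excluded.
   Re-centring lets genuine drift accumulate without letting bright
   neighbours outside the moving window capture the track, and ending the
   track at the first invisible frame stops a later event at the same site
   from masquerading as movement;
3. **irregular profile** — on the 3-frame moving average of the post-onset
   trace: an undershoot below `baseline − 3σ`, a second significant
   excursion above baseline (reaching at least half the main peak after the
   trace has come back down), or a second local maximum with prominence
   `≥ max(2σ, Δpeak/2)`. The prominence floor is tied to the event's own
   peak because over a ~100-frame trace pure noise ripples routinely exceed
   a few σ in prominence, which would veto essentially every long-lived
   event.

Rules run in a fixed order and the first failure is reported, so flags are
reproducible.

## Kinetic classification

An event that is back within `2σ` of baseline one frame after its peak is a
**flash**. Otherwise `A·exp(−(t − t_peak)/τ) + baseline` is fitted to the
post-peak trace by least squares (three starting values of τ, best
residual kept, baseline fixed). The event is a **fade** when the fit
explains the decay (`r² ≥ 0.8`) and the end of the trace (last 5 frames)
sits below `baseline + 0.7·Δpeak`; it is a **stay** when the end level holds
at or above that mark. Events matching neither rule side with the
better-supported model (fade if `r² ≥ 0.8`, else stay). A fitted
`τ < frame interval` is reported as a flash — a decay faster than the
sampling interval is operationally "gone within a single frame". Events
whose post-peak trace is shorter than 3 frames are *undecidable*: counted in
event totals, excluded from class proportions. The 0.7 end-level fraction
(`stay_frac`) parameterizes the genuine ambiguity of whether a "stay" must
hold the full peak level or merely stay well above baseline.

Width is the FWHM of the background-subtracted radial intensity profile at
the peak frame (annulus means in 0.5-px rings, half-maximum located by
linear interpolation), which equals `2√(2 ln 2)·σ ≈ 2.355σ` for a Gaussian
spot. Mean fluorescence is the mean of the detection blob's pixels in the
onset frame, matching particle-analysis output rather than the ROI trace.

## Hotspot and synchrony statistics

Localization ignores time: an event is localized iff another event of the
same cell lies strictly within 5 µm. Synchrony requires an identical onset
frame (a ± window is available for sensitivity analysis, default 0). The
primary outputs are per-event percentages — among localized events, the
percentage synchronized, and the same among diffuse events. Because the
natural denominator of "percentage of synchronized events" is ambiguous, a
per-pair convention (share of <5 µm pairs that are same-frame, and of
≥5 µm pairs) is emitted alongside; the per-event figures are primary. Only
QC-passing events enter the spatial statistics. Distances come from an
explicit `sqrt(dx² + dy²)` broadcast that is bit-identical to a per-pair
loop.

## The synthetic-data generator

`simulate_movie` renders one cell per field as a disc (radius 12.5 µm by
default — the largest disc that fits a 256-px field at 0.1067 µm/px while
keeping 30 events below the overlap-density guard). Defaults mirror the
acquisition they emulate: 120 frames at 2.5 s/frame (0.40 fps), 16-bit
single channel, 0.1067 µm/px (16-µm camera pixels behind a 150× objective).
Each event is an isotropic Gaussian spot (peak amplitude 40–80 units,
σ 0.15–0.30 µm) with a class-specific envelope: flash exists for exactly
one frame; fade decays as `exp(−(t−t0)/τ)` with τ ∈ 5–20 s; stay holds its
amplitude to the last frame. The basal class mix (stay 0.16 / fade 0.16 /
flash 0.68) follows the flash-dominated resting behaviour of the cell
system being modelled. Background is constant (level 100) with optional
per-frame geometric bleaching, and noise is additive Gaussian (σ = 5, so
default amplitudes correspond to SNR 8–16). Events are born at frame ≥ 1 so
differencing can in principle find all of them. A `hotspot_fraction` of
events is placed in discs of `hotspot_radius` (hotspot count
`⌈n_hotspot_events/4⌉`, round-robin occupancy, so clusters hold ~3–4 events
each); within a hotspot, each event adopts the hotspot's shared onset frame
with probability `sync_fraction`. Configs whose expected density exceeds
one event per `4·hotspot_radius²` µm² are rejected as overlap-dominated.

What the generator does *not* emulate: a realistic PSF (no Airy rings), EM
gain noise statistics, cell motion or shape, membrane inhomogeneity,
focal-adhesion background, or bleaching of the events themselves. Passing
recovery tests therefore demonstrate correctness of the analysis chain
under the stated noise model, not performance on arbitrary real data.

`simulate_nfat_image` renders disjoint cells as concentric discs (cytoplasm
mean 100, nucleus mean `100·ratio`, additive noise) with matching label
masks; it exists to validate the N/C ratio computation, whose real inputs
are user-supplied masks (segmentation is out of scope, since the original
measurement used interactive segmentation).

## Benchmark conditions and problem sizes

The validation benchmarks (`evhotspot.validation`, exercised both by
`tests/test_acceptance.py` and `scripts/acceptance.py`) use: 20 default
movies for detection (600 events, 3-px/1-frame matching); 20 movies at
SNR 8 with an equal class mix, split into τ ∈ {5, 10, 20} s batches, for
classification; 50 σ = 0.2 µm stay events across 10 short movies for width;
and 20-seed sets for hotspot and synchrony recovery. The spatial benchmarks
use a wider field (512 px at 0.2134 µm/px, cell radius 45 µm, 10–20 events,
spot σ 0.3–0.5 µm to keep blobs above the area filter at the coarser
sampling): at the default geometry a 5-µm neighbourhood covers a large
share of the cell footprint, so nearly every event is "localized" by chance
and the planted hotspot fraction would be unidentifiable in principle, not
merely hard to estimate. These sizes keep each benchmark to roughly one to
two minutes on a single CPU while leaving the recovery statistics
well-resolved.

## Numerical and degenerate-input conventions

Coordinates are 0-based, pixel-centre; physical positions are
`centroid·pixel_size`. 8-bit conversion uses the global stack min/max with
round-half-up and flags constant stacks instead of dividing by zero. A
difference stack of a `T`-frame movie has exactly `T − 1` frames; `gap ≥ T`
is an error. Zero classified events yield missing (null) proportions;
spatial fractions with empty denominators are reported missing rather than
zero. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces every output
byte for byte (the run log carries no timestamps, and the provenance hash
covers analysis parameters but not file paths).

## Known limitations

- Same-frame events closer than about one blob diameter merge into one
  candidate (see above); synchronized fractions are accordingly
  conservative.
- The fallback for events matching neither the fade nor the stay rule means
  a borderline flash (noisy return to baseline, poor exponential fit) can
  be labelled stay; at SNR 8 this affects a few percent of flashes.
- Width assumes an approximately radially symmetric spot; strongly
  elongated events would need 2-D fitting, which is out of scope.
- The NFAT cytoplasmic mean uses the full cell-minus-nucleus region; no
  perinuclear exclusion ring is applied.
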