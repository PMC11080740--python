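# evhotspot

Single-cell TIRF analysis of tetraspanin–pHluorin extracellular-vesicle (EV)
release events, as an automated, reproducible pipeline.

pH-sensitive reporters such as CD81-pHluorin are quenched inside the acidic
lumen of multivesicular bodies and light up the moment an MVB fuses with the
plasma membrane, so EV release appears in TIRF movies as sudden, localized,
diffraction-limited brightenings. Quantifying those events is usually done
interactively in ImageJ: difference stacks, a hand-tuned threshold, particle
analysis, and by-eye curation and classification. `evhotspot` reimplements
that workflow as a tested Python library with every judgement call turned
into an explicit, recorded parameter, and adds a synthetic-movie generator
with planted ground truth so the whole chain can be validated end to end.

## What the pipeline computes

For a movie `I(t)` (one cell per field, default 120 frames at 0.40 fps,
0.1067 µm/px):

1. **Detection** — difference stack `D_k = I_{k+1} − I_k` (gap 1); pixels
   with `D_k > θ` (positive increases only) are grouped into 8-connected
   blobs with an area filter (4–200 px). The threshold default is robust
   and per-stack: `θ = median + 5·1.4826·MAD` of the positive differences.
2. **Profiles & QC** — per candidate, the mean intensity in a fixed ROI
   over all frames; events are excluded for *minimal change*
   (`Δpeak < 3σ`), *lateral movement* (tracked centroid displaced more than
   0.5 µm), or an *irregular profile* (a second significant excursion or an
   undershoot).
3. **Classification** — by decay kinetics:
   *flash* returns to baseline within one frame of the peak; *fade* follows
   `A·exp(−(t−t_peak)/τ) + baseline` (least squares, r² ≥ 0.8); *stay* holds
   near peak level to the end of the acquisition.
4. **Measurements** — event width as the FWHM of the background-subtracted
   radial profile at peak (`FWHM = 2√(2 ln 2)·σ` for a Gaussian spot) and
   mean fluorescence of the detection blob at onset.
5. **Hotspot statistics** — an event is *localized* if another event in the
   same cell lies within 5 µm; *synchronized* if another event shares its
   onset frame. The per-movie summary reports the localized fraction and
   the synchronized fraction among localized vs diffuse events.

Companion assays: the NFAT translocation readout (per-cell nuclear /
cytoplasmic mean-intensity ratio), bead-panel marker normalization
(blank-adjusted, scaled to the mean CD63/CD81/CD9 signal), and relative
cell-growth differences versus a control.

## Worked example

```sh
evhotspot simulate --seed 4 --out sim
# wrote sim/movie.tif with 30 planted events
evhotspot run --movie sim/movie.tif --out results
# 30 candidates, 30 events pass QC (30 classified) -> results
```

`results/summary.json` then holds, for this movie:

```
n_candidates = 30
n_events = 30
events_per_5min = 30.0
class_proportions = {'fade': 0.1, 'flash': 0.833, 'stay': 0.067}
width_um = {'mean': 0.571, 'median': 0.584, 'sd': 0.110, 'n': 30}
```

i.e. all 30 planted events were recovered and pass QC, the recovered class
proportions reflect the generator's basal flash-dominated mix, and the mean
event width (~0.57 µm) sits where the planted spot sizes (σ = 0.15–0.30 µm,
FWHM 0.35–0.71 µm) put it. `results/spatial.json` reports the localized
fraction and synchrony split for the same cell, and `results/events.csv`
lists every event with its onset, position (µm), width, brightness, class
and QC flag. Every output embeds the hash and full parameter set that
produced it, and rerunning with the same seed and config reproduces every
file byte for byte.

The same analyses are available as a library (`simulate_movie`,
`find_candidates`, `classify_event`, `summarize_spatial`,
`nfat_nc_ratio`, `normalize_macsplex`, ...); see the module docstrings.

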