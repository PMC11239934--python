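# radmig

Quantification pipeline for slice time-lapse imaging of radial neuronal
migration in the embryonic neocortex.

Newborn excitatory neurons migrate from the ventricular zone toward the
pial surface and switch from a multipolar (MP) to a bipolar (BP)
morphology at the subplate (SP) layer. Experiments probing this
transition produce a small family of image-based readouts: the time
course of a luminescent signaling reporter in slice movies, per-cell
radial migration velocities from tracked time-lapse data, MP:BP
compositions at fixed timepoints, laminar "BIN" distributions of
electroporated neurons in fixed sections, and zone-wise protease
(in situ zymography) signal around the SP band. `radmig` implements all
of these as a tested, reusable library, together with a ground-truthed
synthetic-data generator so every stage can be validated without any
imaging data.

## The core quantification

The reporter readout works on a movie of frames `I_t(r, c)`:

1. partition each frame into a `14 × 16` grid and average intensity per
   square, giving per-square time series `x_g[n]`;
2. drop frames starting before 4.5 h (high background right after the
   start of acquisition);
3. discrete-Fourier-transform each series,
   `X_g[k] = Σ_n x_g[n]·exp(−2πikn/N)`, `k = 0…⌊N/2⌋`;
4. sum spectral power over the low band `k ∈ [2, 30]` (the signal
   readout `B_g`) and over the high band `k ∈ [30, 75]` (`H_g`);
5. correct for cosmic-ray camera spikes — temporal impulses with a flat
   spectrum — by estimating their per-bin level from the high band,
   where slow biological signal is absent, and subtracting:
   `B*_g = max(0, B_g − n_low·H_g/n_high)`;
6. keep the four grid rows above and the four below the grid row
   containing the annotated SP-band centre, and report one corrected
   value per retained square (violin plot across squares/conditions).

Band indices are DFT bin numbers along the frame axis (at a cadence of
minutes per frame, physical-hertz bands of this size cannot exist).
Statistics throughout are mean ± SEM and unpaired two-tailed t-tests
with `*p < 0.05`, `**p < 0.01`, `***p < 0.001`.

Migration velocity is the endpoint displacement of a tracked cell along
the pial axis over elapsed time (µm/h, positive toward the pia).
Morphology is classified from the skeletonized cell mask: ≥ 3 primary
neurites → MP; 1–2 neurites whose longest points into a ±45° pia-ward
cone → BP. BIN analysis divides the pial–ventricular span into equal
bins (BIN 1 pial-most) and counts labelled cells per bin.

## Worked example

`examples/02_quantify_reporter.py` simulates a slice movie in which
cells burst the reporter only inside the SP-adjacent band, then runs the
full quantification:

```
grid squares: 224 (8 SP-selected rows x 16 columns)
median corrected band power, SP selection :    93913.0
median corrected band power, elsewhere    :       40.1
SP / elsewhere ratio                      :     2342.9
after 494 injected cosmic rays the SP median moves 5.3%
```

The corrected low-band power concentrates in the grid rows flanking the
SP centre, where cells transiently activate the reporter; injected
cosmic rays (3 per frame, 50× the background noise) barely move the
corrected readout because their flat-spectrum contribution is estimated
from the high band and removed. `examples/03_track_velocity.py` shows
the tracking arm:

```
control : 10.16 +/- 0.33 um/h (n = 10 cells)
slow    :  5.09 +/- 0.30 um/h (n = 10 cells)
unpaired two-tailed t-test: t = 11.40, df = 18, p = 1.15e-09 (***)
```

The remaining examples cover simulation (`01`), morphology and BIN
distributions (`04`), and zone-wise zymography scoring (`05`). A thin
CLI mirrors the stages (`radmig simulate|quantify|track|classify|bins|
zones|report`); see `radmig --help`.

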