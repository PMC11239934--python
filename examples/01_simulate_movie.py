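"""Generate a ground-truthed synthetic slice movie and write it to disk.

Builds the default two-channel fixture — a labelled-cell channel with
radially migrating, morphology-switching cells and a luminescence channel
with subplate-confined reporter bursts — plus its ground-truth sidecar.
"""

from pathlib import Path

import radmig as rm

out = Path("scratch_example_output")
out.mkdir(exist_ok=True)

params = rm.SimParams(seed=1)
label, truth = rm.generate_migration_movie(params)
lum = rm.generate_luminescence_movie(params, truth)

rm.write_stack(label, out / "label.tif")
rm.write_stack(lum, out / "luminescence.tif")
truth.to_json(out / "truth.json")
rm.write_annotation(rm.default_annotation(params), out / "annotation.json")

n_burst = sum(w is not None for w in truth.burst_windows)
print(f"movie: {label.n_frames} frames of {label.shape[1]}x{label.shape[2]} px "
      f"({params.pixel_size_um} um/px, {params.frame_interval_h} h/frame)")
print(f"cells: {truth.n_cells}, of which {n_burst} burst inside the "
      f"subplate band rows {params.burst_band_rows}")
print(f"true radial velocity: {truth.velocities_um_per_h.mean():.1f} um/h "
      f"(condition mean {params.velocity_um_per_h[0]})")
# Each bursting cell emits for up to burst_duration_h once it enters the
# band; the ground truth records every trajectory, class and burst window.
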