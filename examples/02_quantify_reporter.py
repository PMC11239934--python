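"""Grid-Fourier quantification of the luminescence reporter.

Runs the full published procedure on a synthetic slice movie: 14 x 16
grid averaging, exclusion of the first 4.5 h, temporal DFT, band sums
over bins 2-30 (signal) and 30-75 (cosmic-ray floor estimate), broadband
spike correction, and selection of the four grid rows above and below
the subplate centre.
"""

import numpy as np

import radmig as rm

params = rm.SimParams(seed=1)
_, truth = rm.generate_migration_movie(params)
lum = rm.generate_luminescence_movie(params, truth)
annotation = rm.default_annotation(params)
config = rm.RunConfig()

gbp = rm.quantify_reporter(lum, annotation, config, condition="ctrl")
table = gbp.to_frame()

sp = table[table["in_sp_selection"]]["B_star"]
non = table[~table["in_sp_selection"]]["B_star"]
print(f"grid squares: {len(table)} ({gbp.sp_rows.sum()} SP-selected rows "
      f"x {gbp.B.shape[1]} columns)")
print(f"median corrected band power, SP selection : {sp.median():10.1f}")
print(f"median corrected band power, elsewhere    : {non.median():10.1f}")
print(f"SP / elsewhere ratio                      : "
      f"{sp.median() / non.median():10.1f}")
# The corrected low-band power is high only in the grid rows flanking the
# subplate, where migrating cells transiently activate the reporter.

# Cosmic rays barely move the corrected readout:
spiked, spikes = rm.inject_cosmic_rays(lum, rate=3.0, amplitude=250.0, seed=2)
g2 = rm.quantify_reporter(spiked, annotation, config)
m0, m1 = np.median(gbp.B_star[gbp.sp_rows]), np.median(g2.B_star[g2.sp_rows])
print(f"after {len(spikes)} injected cosmic rays the SP median moves "
      f"{100 * abs(m1 - m0) / m0:.1f}%")
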