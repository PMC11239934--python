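"""Classify cell morphology and quantify the laminar bin distribution.

Renders noiseless cell masks with known classes, classifies them with
the skeleton-based multipolar/bipolar criterion, summarises the MP:BP
composition at 0 h and 10 h, and bins a synthetic section's cells into
five equal-height laminar bins (BIN 1 at the pial surface).
"""

import numpy as np

import radmig as rm
from radmig.morphology import classify_polarity

annotation = rm.LayerAnnotation(pial_row=0, ventricular_row=63,
                                sp_center_row=30)


def classify(gallery):
    records = []
    for i, cell in enumerate(gallery):
        cls, n, lead = classify_polarity(cell["mask"], annotation)
        records.append(rm.CellRecord(i, (0, 0), morphology=cls,
                                     n_primary_neurites=n,
                                     leading_process=lead))
    return records


# MP-dominated population at the start, BP-dominated 10 h later
t0 = classify(rm.generate_cell_masks(50, seed=21,
                                     classes=["MP"] * 40 + ["BP"] * 10))
t1 = classify(rm.generate_cell_masks(50, seed=22,
                                     classes=["MP"] * 10 + ["BP"] * 40))
table = rm.mp_bp_composition(t0, t1)
print(table[["timepoint", "t_h", "n_mp", "n_bp", "frac_mp", "frac_bp"]]
      .to_string(index=False))
# The programmed 80% -> 20% multipolar decline is recovered exactly on
# noiseless masks.

# Laminar bins: a migration-arrested population sits in the deep bins
section_ann = rm.LayerAnnotation(pial_row=5, ventricular_row=205,
                                 sp_center_row=110)
pos, _, _ = rm.generate_section(400, np.array([0.05, 0.1, 0.15, 0.3, 0.4]),
                                section_ann, seed=3)
dist = rm.assign_bins(pos, section_ann, n_bins=5)
for b, (c, f) in enumerate(zip(dist.counts, dist.fractions), start=1):
    print(f"BIN {b} ({'pial-most' if b == 1 else 'deep' if b == 5 else '':9s})"
        f": {c:4d} cells ({100 * f:4.1f}%)")
print(f"BIN 1+2 fraction: {dist.fractions[:2].sum():.3f}")
# The BIN 1+2 fraction is the headline readout for rescued vs impaired
# migration phenotypes.
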