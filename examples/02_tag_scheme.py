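"""Lay 150 samples out on the 18 x 18 tag grid, as in the study design.

324 forward x reverse combinations are available; only 150 are used so that
tag jumps can land in deliberately unused cells where they become countable.
"""

import collections

import amplitag as at
from amplitag.primers import S615F_CER, S947R_CER

constraints = at.DesignConstraints()
fw = at.design_barcodes(S615F_CER, constraints, 18, seed=1)
rv = at.design_barcodes(S947R_CER, constraints, 18, seed=2, orientation="reverse")

grid = at.build_grid(fw, rv)
samples = [f"S{i + 1:03d}" for i in range(150)]
scheme = at.select_combinations(grid, samples, seed=5,
                                fw_primer=str(S615F_CER), rv_primer=str(S947R_CER))

rows = collections.Counter(fi for fi, _ in scheme.assignments.values())
cols = collections.Counter(ri for _, ri in scheme.assignments.values())
print(f"grid: {grid.shape[0]} x {grid.shape[1]} = {grid.n_cells} combinations")
print(f"assigned: {len(scheme.assignments)}   unused: {len(scheme.unused)}")
print(f"forward-tag usage per row: {sorted(rows.values())}")
print(f"reverse-tag usage per col: {sorted(cols.values())}")
print(f"mistag exposure (unused cells that can catch a single jump): "
      f"{at.mistag_exposure(scheme):.3f}")

# the scheme round-trips through its TSV serialization bit-exactly
assert at.TagScheme.from_tsv(scheme.to_tsv()).to_tsv() == scheme.to_tsv()
print("TSV round trip: exact")
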