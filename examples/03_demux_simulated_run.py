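"""Simulate a dual-tagged paired-end run and demultiplex it exactly.

Twelve samples on the 18 x 18 grid, 1,000 reads each, with a 2% tag-jump
rate and 5% truncated reads.  The demultiplexer merges each pair, applies
the >=300 bp length and >=100 bp overlap filters, then matches tags with
zero tolerance: errored tags go to 'unassigned', valid-but-unused tag pairs
to 'mistag'.
"""

import amplitag as at
from amplitag.primers import S615F_CER, S947R_CER

constraints = at.DesignConstraints()
fw = at.design_barcodes(S615F_CER, constraints, 18, seed=1)
rv = at.design_barcodes(S947R_CER, constraints, 18, seed=2, orientation="reverse")
grid = at.build_grid(fw, rv)
scheme = at.select_combinations(grid, [f"AEG{i + 1:02d}" for i in range(12)], seed=3,
                                fw_primer=str(S615F_CER), rv_primer=str(S947R_CER))

run = at.simulate_run(scheme, rho_mistag=0.02, short_frac=0.05,
                      reads_per_sample=1000, seed=11)
merged = [m for rid, r1, r2 in run.pairs
          if (m := at.merge_pair(r1, r2, read_id=rid)) is not None]
result = at.demux_reads(merged, scheme)

print(f"input read pairs: {len(run.pairs)}")
print(f"bins: {result.bins}")
truth = {r["read_id"]: r["sample"] for r in run.manifest.reads}
correct = sum(truth[rid] == s for s, reads in result.assigned.items() for rid, _ in reads)
print(f"assigned reads whose sample matches the simulation truth: "
      f"{correct}/{result.bins['assigned']}")
planted = sum(r["cell_status"] == "unused" for r in run.manifest.reads)
print(f"planted jumps into unused cells: {planted} -> observed mistag bin: "
      f"{result.bins['mistag']} (short reads are filtered before matching)")

retained = at.drop_low_yield(result.sample_counts(), min_reads=900)
print(f"samples kept by the yield filter at 900 reads: {len(retained)}/12")
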