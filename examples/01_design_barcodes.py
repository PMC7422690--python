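"""Design dual-index barcode sets for the Cercozoa-specific primers.

Builds a synthetic reference alignment around the forward primer site,
screens all 65,536 candidate 8-mers through the composition, homopolymer,
hairpin, duplex, flank and pairwise-distance filters, and prints the two
validated 18-barcode sets.
"""

import amplitag as at
from amplitag.primers import S615F_CER, S947R_CER

constraints = at.DesignConstraints()  # 8-mers, pairwise Hamming distance >= 3

# flank screen input: consensus of the template immediately 5' of the primer
records = at.make_reference_alignment(primer=str(S615F_CER), seed=7)
consensus = at.consensus([seq for _, seq in records])
flank = at.extract_flank(consensus, str(S615F_CER), constraints.flank_window)

fw = at.design_barcodes(S615F_CER, constraints, target_size=18, seed=1,
                        flank_consensus=flank)
rv = at.design_barcodes(S947R_CER, constraints, target_size=18, seed=2,
                        orientation="reverse")

for bset in (fw, rv):
    report = at.validate_set(bset)
    print(f"{bset.orientation} primer {bset.attached_primer}: "
          f"{len(bset)} barcodes, min pairwise distance "
          f"{bset.min_pairwise_distance()}, validation "
          f"{'pass' if report.passed else 'FAIL'}")
    print("  " + " ".join(bset.barcodes[:6]) + " ...")

# cross-dimer screen over every tagged-oligo pair (fw x fw, rv x rv, fw x rv)
failing = at.cross_combination_screen(fw, rv)
print(f"cross-combination screen: {len(failing)} pairs above duplex thresholds")
print("(the printed reverse primer is self-complementary over 10 bases under")
print(" worst-case degenerate pairing, so rv x rv pairs report regardless of tag)")
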