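"""Cercozoa/Endomyxa-specific 18S V4 primers (all written 5'->3').

The semi-nested amplification uses a first round with a forward-primer mixture
(S615F_Cerco + S615F_Phyt) and reverse S963R_Phyt, then a second, barcoded
round with S615F_Cer / S947R_Cer.  Barcodes are appended to the 5' ends of the
second-round primers.
"""

from .oligo import Oligo

S615F_CERCO = Oligo("GTTAAAAAGCTCGTAGTTG", "S615F_Cerco")
S615F_PHYT = Oligo("GTTAAAARGCTCGTAGTCG", "S615F_Phyt")
S963R_PHYT = Oligo("CAACTTTCGTTCTTGATYAAA", "S963R_Phyt")
S615F_CER = Oligo("GTTAAAARGCTCGTAGTYG", "S615F_Cer")
S947R_CER = Oligo("AAGARGAYATCCTTGGTG", "S947R_Cer")

PRIMERS = {p.name: p for p in (S615F_CERCO, S615F_PHYT, S963R_PHYT, S615F_CER, S947R_CER)}
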