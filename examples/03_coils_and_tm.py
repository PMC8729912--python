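"""Coiled-coil and transmembrane segment prediction on constructed sequences.

An ideal heptad repeat (leucines at positions a/d, charged residues
elsewhere) is recognized as a coiled coil; a 23-residue poly-leucine
stretch between acidic flanks is recognized as a membrane span.
"""

from prgscan import default_coils_model, default_tm_model
from prgscan.coils import predict_coiled_coils
from prgscan.seqio import ProteinRecord
from prgscan.tm import predict_tm_segments

heptad = "LEELKEK" * 5
cc_protein = ProteinRecord(id="cc", sequence="GSTND" * 4 + heptad + "GSTND" * 4)
for seg in predict_coiled_coils(default_coils_model(), cc_protein):
    print(f"CC segment {seg.start}-{seg.end}, max probability {seg.max_probability:.3f}")

tm_protein = ProteinRecord(id="tm", sequence="DEDEDEDEDE" + "L" * 23 + "EDEDEDEDED")
for seg in predict_tm_segments(default_tm_model(), tm_protein):
    print(f"TM segment {seg.start}-{seg.end}, peak hydropathy {seg.peak_hydropathy:.1f}")
# The CC probability compares the heptad-window score against coiled-coil vs
# globular score distributions; the TM call is the union of 19-residue
# windows whose mean Kyte-Doolittle hydropathy reaches 1.6.
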