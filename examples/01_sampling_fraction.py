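"""How little of an RNA-seq library does one lane actually sequence?

A standard 10 nM, 400 uL library holds about 2.4e12 cDNA molecules; a
single flow-cell lane reads ~30 million of them.
"""

import techvar as tv

protocol = tv.ProtocolSpec(concentration_nm=10, volume_ul=400)
molecules = tv.estimate_library_molecules(protocol)
fraction = tv.sampling_fraction(30_000_000, molecules)

print(f"molecules in library : {molecules:.4g}")
print(f"reads in one lane    : 3e+07")
print(f"sampling fraction    : {fraction:.3g} ({fraction * 100:.4f}%)")
print()
print("A lane sequences roughly one molecule in eighty thousand, so pure")
print("sampling noise alone can make two lanes of the SAME library disagree.")
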