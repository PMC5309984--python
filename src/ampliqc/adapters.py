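"""Sequencing-adapter constants shared by the simulator and detector.

Standard TruSeq-style read-through adapter sequences: a read whose
insert is shorter than the read length runs off the template into
these, which is exactly how primer-dimer reads are recognised.
"""

ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

DEFAULT_ADAPTERS = (ADAPTER_R1, ADAPTER_R2)
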