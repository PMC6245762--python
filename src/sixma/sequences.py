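"""Reference model substrates used in the single-site experiments.

``MODEL_DNA_208`` is the 208-bp nucleosome-positioning element derived from
the Lytechinus variegatus (sea urchin) 5S rDNA, the classic strong-positioning
substrate for in vitro assembly.  It carries exactly one GATC motif, whose
adenine becomes 6mA after Dam methylase treatment — a single-site test bed for
methylation-sensitive digestion and placement-model experiments.

``MD_DUPLEX_33`` is the 33-bp B-DNA duplex used for the structural-parameter
statistics, with the methylatable ApT dinucleotide at ``MD_DUPLEX_SITE``
(0-based index of the adenine).
"""

MODEL_DNA_208 = (
    "ACTTCCAGGGATTTATAAGCCGATGACGTCATAACATCCCTGACCCTTTAAATAGCTTAA"
    "CTTTCATCAAGCAAGAGCCTACGACCATACCATGCTGAATATACCGGTTCTCGTCCGATC"
    "ACCGAAGTCAAGCAGCATAGGGCTCGGTTAGTACTTGGATGGGAGACCGCCTGGGAATAC"
    "CGAATTCCCCGAGGAATTCCAACGAATA"
)

MD_DUPLEX_33 = "GCTCACCCGCGCCCATGGTGGGAGCCGGAGACG"
MD_DUPLEX_SITE = 14  # the A of the central ApT

assert len(MODEL_DNA_208) == 208
assert len(MD_DUPLEX_33) == 33
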