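>5xcNRE_sense
CTAGGAAGGACAAAGAGGGGACAAAGAGGCGGAGGTGAAGGACAAAGAGGGGACAAAGAG
GCGGAGGTGAAGGACAAAGAGGGGACAAAGAGGCGGAGCTGAAGGACAAAGAGGGGACAA
AGAGGCGGAGGTGAAGGACAAAGAGGGGACAAAGAGGCGGAGGTCTCGAGA
>5xcNRE_antisense
GATCTCTCGAGACCTCCGCCTCTTTGTCCCCTCTTTGTCCTTCACCTCCGCCTCTTTGTC
CCCTCTTTGTCCTTCACCTCCGCCTCTTTGTCCCCTCTTTGTCCTTCACCTCCGCCTCTT
TGTCCCCTCTTTGTCCTTCACCTCCGCCTCTTTGTCCCCTCTTTGTCCTTC
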