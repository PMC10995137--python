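>MutA_sense
gaGTCGACaagaggggacaaagaggcggaggt
>MutA_antisense
acctccgcctctttgtcccctcttGTCGACtc
>MutB_sense
cttgcgaaggacaaagTTgggacaaagaggcggag
>MutB_antisense
ctccgcctctttgtcccAActttgtccttcgcaag
>MutC_sense
aggggacaaagaTTcggaggtggggctgg
>MutC_antisense
ccagccccacctccgAAtctttgtcccctc
>MutS_sense
gaaggacaaagaggggaTTaagaggcggaggt
>MutS_antisense
acctccgcctcttAAtcccctctttgtccttc
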