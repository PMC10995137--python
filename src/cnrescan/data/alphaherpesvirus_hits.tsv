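virus	accession	start	end	strand	sequence	mismatches
HSV1	JN420341.1	4652	4683	-	GAGGAAGAGGCAGAGGAGGAAGAGGCGGAGGC	10
HSV1	JN420341.1	8437	8469	+	GAAGGAGAAGGAGGAGAGAGGGGGGGGGAGAG	10
HSV1	JN420341.1	8727	8759	+	AGGGGATCAAAGGGGGACAAAGAGGCGGGGGC	9
HSV1	JN420341.1	33929	33960	-	CACGTACAAATCGGGGGCCATGAGGCCGCTGT	11
HSV1	JN420341.1	121375	121406	+	GAGGAAGAGGCAGAGGAGGAAGAGGCGGAGGC	10
HSV1	JN420341.1	132264	132295	+	GGCGGAGGAGGGGGGGACGCGGGGGCGGAGGA	11
GaHV1	NC_006623.1	26529	26560	+	GAACAGCGGCGAGACGAAAAAGAAGCGGAGGA	11
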