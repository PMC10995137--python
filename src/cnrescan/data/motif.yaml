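# Reference tripartite cNRE motif of the quail SMyHC III promoter.
# Hexad intervals are 1-based inclusive on the 32-nt consensus.
consensus: GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT
hexads:
  A: [3, 8]    # AGGACA (VDRE half-site)
  B: [12, 17]  # AGGGGA (RARE half-site)
  C: [24, 29]  # GGCGGA (atrial activator)
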