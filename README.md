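# cnrescan

Toolkit for analyzing the **cNRE** (complex Nuclear Receptor Element), a
32-bp tripartite *cis*-regulatory element from the quail *SMyHC III* (Slow
Myosin Heavy Chain III) promoter that biases cardiac reporter expression
toward the atrium. The element is a consensus of three purine-rich hexad
half-sites on a 32-nt backbone:

```
position:  1.........11........21........31
consensus: GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT
hexads:      [A 3-8 ]  [B12-17]     [C24-29]
             AGGACA    AGGGGA       GGCGGA
```

Hexad A is a VDRE half-site, Hexad B a RARE half-site, and Hexad C an
atrial activator. The package is aimed at researchers studying hexamer
half-site regulatory elements who need to (re)run the element's
computational analyses on their own sequences or on fully synthetic data
with known ground truth.

## What it does

- **Genome scanning** (`cnrescan.genome_scan`) — exhaustive both-strand
  Hamming scan for element-like occurrences, with the *hexad retention
  rule*: a hit is kept when it covers consensus positions 3–29 with at most
  one mismatch inside each hexad (spacer mismatches unrestricted). Hits
  with ≥ 4 total mismatches over the 32-bp stretch are classified
  divergent. Includes flank extraction (5–6 kb windows) and gene-locus
  co-localization (5′-flanking / 3′-flanking / intragenic).
- **Viral screening** (`cnrescan.viral_screen`) — best query-global /
  subject-local ("glocal") alignment of the element against each viral
  genome (both orientations, affine gaps), with an empirical permutation
  null: the same 1000 random 32-mers are scored against every genome, a hit
  is significant when its score exceeds the null's 95th percentile, and the
  permutation p-value is `(1 + #{null ≥ obs}) / (n + 1)`. The full screen
  ranks by score, keeps the top 2000, reduces to the best virus per family,
  then retains survivors with p ≤ 0.05.
- **Motif and mutagenesis** (`cnrescan.motif`) — the reference element, the
  named promoter mutations (Mut A/B/C/S) with old-base verification, tandem
  multimer constructs, and primer-placement checks against the printed
  mutagenesis primers.
- **Binding-energy hexad calling** (`cnrescan.energy_profile`) — pools
  per-hexad ΔΔG profiles across receptors, thresholds at the 10th
  percentile, calls candidate hexad starts, and scores per-nucleotide hexad
  participation.
- **Binding-curve fitting** (`cnrescan.binding_fit`) — Levenberg–Marquardt
  fit of the Hill isotherm `r(c) = r_free + (r_bound − r_free)·cⁿ/(Kdⁿ + cⁿ)`
  to fluorescence-anisotropy titrations (Kd in nM, Hill coefficient n).
- **Cohort statistics** (`cnrescan.cohort_stats`) — per-category 2×2
  chi-square contrasts of chamber-expression counts
  (atrium / ventricle / both) between reporter constructs.
- **Synthetic data** (`cnrescan.synthetic_data`) — seeded generators for
  genomes with planted element copies at controlled per-hexad mismatch
  levels, telomeric-repeat and hexad-violator decoys, viral genomes with
  planted degenerate copies, ΔΔG profiles with planted low-energy hexads,
  and noisy Hill titrations — all with exact truth tables.

## Worked example

Plant two element copies (one exact, one on the minus strand with 1+0+1
hexad and 2 spacer mismatches) plus a hexad-violator decoy in a 50-kb
random genome, then scan:

```python
from cnrescan.motif import cnre_reference
from cnrescan.genome_scan import scan_sequence, hits_to_frame
from cnrescan.synthetic_data import PlantSpec, CopySpec, DecoySpec, gen_genome

motif = cnre_reference()
spec = PlantSpec(
    length=50_000,
    copies=(CopySpec(position=12_001),
            CopySpec(strand="-", hexad_mismatches=(1, 0, 1), spacer_mismatches=2)),
    decoys=(DecoySpec("hexad_violator"),),
    seed=11,
)
genome, copies, decoys = gen_genome(spec, motif)
hits = [h for h in scan_sequence(genome, motif, 11) if h.is_full_length]
print(hits_to_frame(hits).to_string(index=False))
```

```
              target_id  start   end strand                         sequence  total_mismatches  hexA_mm  hexB_mm  hexC_mm  pass locus_label
synthetic_genome_seed11  12001 12032      + GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT                 0        0        0        0  True        None
synthetic_genome_seed11  26849 26880      - GAAGGACGAAGAGGGGACAATGGGGGGGAGGT                 4        1        0        1  True        None
synthetic_genome_seed11  40534 40565      + GAAGACCAAAGAGGGGACAAAGAGGCGGAGGT                 2        2        0        0 False        None
```

Both planted copies are recovered at their exact coordinates and pass the
hexad rule (the minus-strand copy despite 4 total mismatches, because no
hexad carries more than one); the decoy at 40,534 is found (2 mismatches)
but fails the rule, with both of its substitutions in Hexad A. The same
pipeline is available from the shell:

```sh
cnrescan scan --genome genome.fasta --loci loci.bed --max-mm 11
cnrescan viral-screen --viruses viruses.fasta --taxonomy families.tsv --seed 1
cnrescan fit-binding --curve titration.csv
```

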