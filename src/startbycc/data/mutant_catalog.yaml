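# START mutant catalog: documented phenotypes used by the screen.
# provenance: experiment (default) | model prediction |
#   validated prediction | contradiction (reported separately)
- genotype: wildtype
  expected_viable: true
  expected_size:
  - 1.0
  - 1.0
  size_class: ~WT
- genotype: cln3Δ
  expected_viable: true
  expected_size:
  - 1.8
  - 2.7
  size_class: very-large
- genotype: bck2Δ
  expected_viable: true
  expected_size:
  - 1.2
  - 1.45
  size_class: large
- genotype: whi5Δ
  expected_viable: true
  size_class: small
- genotype: swi4Δ
  expected_viable: true
  expected_size:
  - 1.3
  - 1.5
  size_class: large
- genotype: mbp1Δ
  expected_viable: true
  expected_size:
  - 1.2
  - 1.3
  size_class: large
- genotype: swi6Δ
  expected_viable: true
  expected_size:
  - 2.0
  - 2.5
  size_class: very-large
- genotype: msn5Δ
  expected_viable: true
  size_class: large
- genotype: bck2Δ cln3Δ
  expected_viable: false
  notes: G1 arrest; no activator of SBF/MBF
- genotype: bck2Δ cln3Δ whi5Δ
  expected_viable: true
  expected_size:
  - 1.2
  - 1.6
  size_class: large
  notes: rescue by loss of the inhibitor
- genotype: cln3Δ swi6Δ
  expected_viable: true
  expected_size:
  - 2.0
  - 2.6
  size_class: very-large
- genotype: CLN3-1 swi6Δ
  expected_viable: true
  expected_size:
  - 2.0
  - 2.6
  size_class: very-large
  notes: Swi6 epistatic to Cln3
- genotype: bck2Δ swi6Δ
  expected_viable: false
- genotype: SWI6-SA4 bck2Δ
  expected_viable: true
  size_class: large
  notes: bck2Δ swi6Δ carrying the SA4 allele; rescued, ~bck2Δ size
- genotype: swi4Δ swi6Δ
  expected_viable: false
- genotype: SWI6-SA4 swi4Δ
  expected_viable: true
  size_class: large
  notes: swi4Δ swi6Δ carrying the SA4 allele; rescued, size ~ swi4Δ
- genotype: swi4Δ swi6Δ whi5Δ
  expected_viable: false
  notes: no SBF/MBF left for Whi5 to inhibit
- genotype: mbp1Δ swi4Δ
  expected_viable: false
- genotype: cln3Δ swi4Δ
  expected_viable: false
- genotype: cln3Δ swi4Δ whi5Δ
  expected_viable: true
  size_class: large
  provenance: validated prediction
- genotype: GAL-BCK2 cln3Δ swi4Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: bck2Δ mbp1Δ
  expected_viable: true
  size_class: large
  provenance: validated prediction
- genotype: cln3Δ mbp1Δ
  expected_viable: true
  size_class: very-large
  provenance: validated prediction
- genotype: cln3Δ mbp1Δ swi6Δ
  expected_viable: true
  size_class: very-large
  provenance: validated prediction
- genotype: cln3Δ mbp1Δ whi5Δ
  expected_viable: true
  size_class: large
  provenance: validated prediction
  notes: smaller than cln3Δ mbp1Δ
- genotype: GAL-CLB5 swi4Δ swi6Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: GAL-CLN2 swi4Δ swi6Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: GAL-CLN3 swi4Δ swi6Δ
  expected_viable: false
  provenance: model prediction
  notes: Cln3 alone cannot replace Clb5 for DNA synthesis
- genotype: GAL-CLB5 bck2Δ swi6Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: GAL-CLN2 bck2Δ swi6Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: WHI5-12A
  expected_viable: true
  expected_size:
  - 0.9
  - 1.1
  size_class: ~WT
- genotype: SWI6-SA4
  expected_viable: true
  expected_size:
  - 0.9
  - 1.1
  size_class: ~WT
- genotype: SWI6-SA4 WHI5-12A
  expected_viable: true
  expected_size:
  - 1.25
  - 1.6
  size_class: large
  notes: ~40% size increase only in the double
- genotype: GAL-WHI5-12A SWI6-SA4
  expected_viable: false
  notes: excess non-phosphorylable Whi5 also inhibits MBF
- genotype: GAL-WHI5
  expected_viable: true
  size_class: large
- genotype: GAL-WHI5 mbp1Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: GAL-WHI5-12A mbp1Δ
  expected_viable: true
  size_class: large
  provenance: model prediction
- genotype: mc-BCK2 cln3Δ mbp1Δ
  expected_viable: true
  size_class: large
  provenance: validated prediction
- genotype: GAL-BCK2
  expected_viable: true
  size_class: small
  provenance: model prediction
- genotype: cln1Δ cln2Δ
  expected_viable: true
  size_class: large
- genotype: sic1Δ
  expected_viable: true
  size_class: ~WT
- genotype: cdh1Δ
  expected_viable: true
  size_class: ~WT
  notes: viable, fast mitotic cycles
- genotype: GAL-WHI5 swi6Δ
  expected_viable: true
  size_class: very-large
  provenance: contradiction
  notes: 'model: ~swi6Δ size; experiment: much larger'
- genotype: msn5Δ swi4Δ
  expected_viable: true
  size_class: large
  provenance: contradiction
  notes: 'model: viable ~swi4Δ; experiment: inviable'
- genotype: msn5Δ swi6Δ
  expected_viable: true
  size_class: very-large
  provenance: contradiction
  notes: 'model: viable ~swi6Δ; experiment: inviable'
- genotype: cdh1Δ cln1Δ cln2Δ
  expected_viable: false
  provenance: contradiction
  notes: 'model: inviable; experiment: viable'
- genotype: GAL-CLN2 cdh1Δ cln1Δ cln2Δ
  expected_viable: true
  size_class: small
  provenance: contradiction
  notes: 'model: viable but very small; experiment: normal'
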