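# Integration-test ground truth: stand-in alternative-paralog fractions
# consistent with the qualitative gonad findings (switching of RpL22-like
# and RpL37b in testis and RpS5b in ovary; parity of RpS19b and RpS5b in
# testis; minority enrichment of RpS15Ab/RpS10a/RpS28a in testis and of
# the RpL24/RpL7/RpLP0 alternatives in ovary). Values are modelling
# stand-ins, not measurements.
default_alt_fraction: 0.05
rna_base: 50.0
ribosome_abundance:
  testis: 1.0
  ovary: 1.0
  head: 1.0
  embryo: 1.0
alt_fraction:
  testis:
    RpL22: 0.8
    RpL37: 0.8
    RpS19: 0.5
    RpS5: 0.5
    RpS15A: 0.1
    RpS10: 0.1
    RpS28: 0.1
  ovary:
    RpS5: 0.8
    RpL24: 0.25
    RpL7: 0.25
    RpLP0: 0.25
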