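# Shipped normative constants: demographic adjustment equations and
# tolerance-limit / equivalent-score thresholds for the FAB and its
# three sub-scales.  Edit nothing here: the loader verifies the
# checksum over the canonical JSON serialization of the payload.
checksum: 50e2f454dd7bf6dde0022da70532f7c0e64e36294c1d25cbbebee492bd5b5e26
equations:
  FAB:
    age:
      center: 269630.547368
      coefficient: 4.0e-06
      family: cube
    education:
      center: 2.366383
      coefficient: -1.565729
      family: log
  FAB1:
    age:
      center: 269630.547368
      coefficient: 1.0e-06
      family: cube
    education:
      center: 2.366383
      coefficient: -0.607345
      family: log
  FAB2:
    age:
      center: 269630.547368
      coefficient: 2.0e-06
      family: cube
    education:
      center: 0.105356
      coefficient: 2.527494
      family: reciprocal
  FAB3:
    age:
      center: 3958.627368
      coefficient: 0.000103
      family: square
    education:
      center: 2.366383
      coefficient: -0.640471
      family: log
norm_tables:
  FAB:
    iTL: 13.16
    median: 16.24
    n: 475
    oTL: 12.02
    precision: 2
    scheme: published
    t1: 13.71
    t2: 15.1
  FAB1:
    iTL: 3.81
    median: 5.49
    n: 475
    oTL: 3.49
    precision: 2
    scheme: published
    t1: 4.35
    t2: 4.76
  FAB2:
    iTL: 3.76
    median: 5.69
    n: 475
    oTL: 2.74
    precision: 2
    scheme: published
    t1: 4.45
    t2: 5.41
  FAB3:
    iTL: 3.12
    median: 5.65
    n: 475
    oTL: 2.8
    precision: 2
    scheme: published
    t1: 3.57
    t2: 5.09
provenance: Italian adult normative study of the FAB and its sub-scales (N=475 healthy
  participants; norms edition 2021)
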