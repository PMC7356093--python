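# Dissimilatory sulfur metabolism gene panel for Beggiatoa leptomitoformis.
# locus_a: strain D-402T (assembly CP012373.2); locus_b: strain D-401
# (assembly CP018889.2).
genes:
  - {gene: soxY,  locus_a: AL038_09565, locus_b: BLE401_14705}
  - {gene: soxZ,  locus_a: AL038_09560, locus_b: BLE401_14710}
  - {gene: soxAX, locus_a: AL038_11110, locus_b: BLE401_13150}
  - {gene: soxB,  locus_a: AL038_05225, locus_b: BLE401_00760}
  - {gene: soxF,  locus_a: AL038_02505, locus_b: BLE401_03540}
  - {gene: sqr,   locus_a: AL038_16835, locus_b: BLE401_07405}
  - {gene: dsrE,  locus_a: AL038_07480, locus_b: BLE401_16835}
  - {gene: dsrF,  locus_a: AL038_07475, locus_b: BLE401_16840}
  - {gene: dsrH,  locus_a: AL038_07470, locus_b: BLE401_16845}
  - {gene: dsrC,  locus_a: AL038_07465, locus_b: BLE401_16850}
  - {gene: soeA,  locus_a: AL038_09735, locus_b: BLE401_14535}
  - {gene: soeB,  locus_a: AL038_09730, locus_b: BLE401_14540}
  - {gene: soeC,  locus_a: AL038_09725, locus_b: BLE401_14545}
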