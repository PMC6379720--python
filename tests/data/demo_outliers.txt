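# >3-sigma above-line outlier pairs for examples/demo_config.yaml
ACA-GCA
ATT-AGC
CAT-TCT
CGA-CGA
CGG-GCC
CTC-CCG
CTT-GAC
GCG-CTG
GTA-ATA
GTG-AAG
GTT-TCC
TAC-ATG
TAC-TTA
TTT-ATG
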