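# Default expert thresholds for liver biochemistry readouts, expressed as
# fold-of-control elevation factors. Edit per study protocol.
ALP: 1.5
AST: 2.0
ALT: 2.0
GTP: 2.0
TC: 1.5
TG: 1.5
TBIL: 1.5
DBIL: 1.5
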