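# FPC risk genes (editable; one symbol per line)
ATM
POLQ
BUB1B
CPA1
FANCC
FANCG
BRCA1
BRCA2
PALB2
CDKN2A
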