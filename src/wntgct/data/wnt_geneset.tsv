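gene	role
CTNNB1	activator
FZD1	activator
FZD7	activator
LRP5	activator
LRP6	activator
WNT5B	activator
CCND2	activator
TCF7L2	activator
APC	repressor
BTRC	repressor
CHD8	repressor
FAT1	repressor
FAT2	repressor
FAT3	repressor
FAT4	repressor
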