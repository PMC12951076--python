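# Fallback mapping for Sybyl atom types that are outside the 23-label
# ligand vocabulary. Types not listed here fall back by element
# (see atomtypes.py).
# sybyl_type<TAB>mapped_label
C.cat	C.2
O.spc	O.3
O.t3p	O.3
N.2	N.2
Se	S.3
Si	C.3
As	P.3
B	C.3
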