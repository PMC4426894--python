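# 3-state secondary-structure substitution matrix: +2 match / -1 mismatch.
# 8-state DSSP labels are collapsed before lookup (H,G,I -> H; E,B -> E; rest -> -).
    H  E  -
H   2 -1 -1
E  -1  2 -1
-  -1 -1  2
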