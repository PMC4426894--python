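# Moiety atom partitions for supported dinucleotide cofactors, keyed on the
# PDB Chemical Component Dictionary heavy-atom names. Each ribose is grouped
# with its adjacent base; the pyrophosphate bridge forms the phosphate moiety.
# Editable: drop in an alternative partition to change moiety assignment.
NAD:
  phosphate: [PA, O1A, O2A, O3, PN, O1N, O2N]
  adenosine: [O5B, C5B, C4B, O4B, C3B, O3B, C2B, O2B, C1B,
              N9A, C8A, N7A, C5A, C6A, N6A, N1A, C2A, N3A, C4A]
  nicotinamide: [O5D, C5D, C4D, O4D, C3D, O3D, C2D, O2D, C1D,
                 N1N, C2N, C3N, C7N, O7N, N7N, C4N, C5N, C6N]
FAD:
  phosphate: [PA, O1A, O2A, O3P, P, O1P, O2P]
  adenosine: [O5B, C5B, C4B, O4B, C3B, O3B, C2B, O2B, C1B,
              N9A, C8A, N7A, C5A, C6A, N6A, N1A, C2A, N3A, C4A]
  flavin: [N1, C2, O2, N3, C4, O4, C4X, N5, C5X, C6, C7, C7M, C8, C8M,
           C9, C9A, N10, C10,
           "C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'", "O5'"]
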