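# Small C/N/O/F fragment library used for the low-fitness initial
# population (molecules capped at 9 heavy atoms, QM9-style composition).
cap [*]C
cap [*]CC
cap [*]CCC
cap [*]C(C)C
cap [*]N
cap [*]NC
cap [*]O
cap [*]OC
cap [*]F
cap [*]C#N
cap [*]C=O
cap [*]C(C)=O
cap [*]C(N)=O
cap [*]C1CC1
cap [*]c1ccco1
cap [*]C1CO1
linker [*]C[*]
linker [*]CC[*]
linker [*]C(C)[*]
linker [*]O[*]
linker [*]OC[*]
linker [*]N([*])C
linker [*]NC[*]
linker [*]C(=O)[*]
linker [*]C(=O)O[*]
linker [*]C=C[*]
linker [*]C1CC([*])C1
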