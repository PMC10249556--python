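# Drug-like fragment library for synthetic corpus generation.
# role cap    = one attachment point [*]
# role linker = two attachment points [*]
# Hand-curated small substituents, rings and connectors typical of
# lead-like chemistry; recombined at random to emulate a broad
# make-on-demand compound collection.
cap [*]c1ccccc1
cap [*]c1ccc(F)cc1
cap [*]c1ccc(Cl)cc1
cap [*]c1ccc(C)cc1
cap [*]c1ccc(OC)cc1
cap [*]c1ccc(C#N)cc1
cap [*]c1ccncc1
cap [*]c1cccnc1
cap [*]c1ccnc(C)c1
cap [*]c1ccco1
cap [*]c1cccs1
cap [*]c1cnn(C)c1
cap [*]c1nccs1
cap [*]C1CCCCC1
cap [*]C1CCOCC1
cap [*]N1CCOCC1
cap [*]N1CCCC1
cap [*]N1CCN(C)CC1
cap [*]C1CC1
cap [*]C1CCC1
cap [*]C(C)C
cap [*]C(C)(C)C
cap [*]C(F)(F)F
cap [*]C
cap [*]CC
cap [*]OC
cap [*]O
cap [*]N
cap [*]N(C)C
cap [*]C#N
cap [*]C(N)=O
cap [*]C(C)=O
cap [*]S(C)(=O)=O
cap [*]F
linker [*]C(=O)N[*]
linker [*]C(=O)N([*])C
linker [*]NC(=O)C[*]
linker [*]C(=O)[*]
linker [*]OC(=O)[*]
linker [*]S(=O)(=O)N[*]
linker [*]C[*]
linker [*]CC[*]
linker [*]CCC[*]
linker [*]OCC[*]
linker [*]O[*]
linker [*]N([*])C
linker [*]C=C[*]
linker [*]c1ccc([*])cc1
linker [*]c1ccc([*])nc1
linker [*]c1cc([*])ccc1C
linker [*]C1CCN([*])CC1
linker [*]N1CCN([*])CC1
linker [*]C1CCC([*])CC1
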