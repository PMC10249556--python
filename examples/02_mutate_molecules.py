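"""Propose masked-language-model mutations for a handful of molecules.

Each parent gets one mutation plan (replacement, insertion or deletion,
chosen uniformly); masks are filled with the model's top-5 predictions,
giving up to five offspring per parent. Offspring are then scored with
the two-metric harmonic fitness (drug-likeness x synthesizability).
"""

import numpy as np

import mlmga as M

corpus = M.generate_corpus(M.CorpusSpec(n_molecules=500, min_sa_norm=0.30, seed=1))
vocab = M.build_vocabulary(corpus, target_size=256)
model = M.NGramPredictor(vocab, seed=0)  # exact, fast counting backend
model.pretrain([M.encode(vocab, s) for s in corpus], epochs=1)

scorer = M.PopulationScorer(("qed", "sa"))
rng = np.random.default_rng(7)
for smiles in corpus[:4]:
    parent = scorer.score(M.canonicalize(smiles))
    print(f"parent    {parent.canonical_smiles}  fitness={parent.fitness:.3f}")
    offspring = M.generate_offspring(
        model, M.encode(vocab, smiles), rate=0.3, k=5, mode="topk", rng=rng
    )
    for child_smiles in offspring:
        try:
            child = scorer.score(child_smiles)
        except M.InvalidSmilesError:
            print(f"  invalid {child_smiles}")
            continue
        delta = child.fitness - parent.fitness
        print(f"  child   {child.canonical_smiles}  fitness={child.fitness:.3f} ({delta:+.3f})")
    print()
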