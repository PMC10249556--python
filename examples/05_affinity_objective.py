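"""Three-metric optimization with a pluggable binding-affinity scorer.

Any callable mapping a list of SMILES to one predicted -log10 affinity
per molecule can serve as the third fitness component (the prediction is
divided by 10 and clipped to [0, 1]). Here the deterministic mock scorer
stands in for an external model, so the run is fully reproducible.
"""

import mlmga as M

corpus = M.generate_corpus(M.CorpusSpec(n_molecules=1000, min_sa_norm=0.30, seed=9))
vocab = M.build_vocabulary(corpus, target_size=256)
model = M.NGramPredictor(vocab, seed=0)
model.pretrain([M.encode(vocab, s) for s in corpus], epochs=1)

schedule = M.RunSchedule(
    mu=80, generations=5, mutation_rate=0.3, n_repeats=2, seed=10,
    metric_set=("qed", "sa", "affinity"),
)
result = M.run(schedule, model, M.make_gdb9_like(200, seed=11),
               affinity_scorer=M.MockAffinityScorer())

print(result.aggregated()[["generation", "mean_fitness", "max_fitness"]].to_string(index=False))
best = max(result.final_populations[0], key=lambda i: i.fitness)
m = best.metrics
print(
    f"\nbest molecule: {best.canonical_smiles}\n"
    f"  qed={m.qed:.3f} sa_norm={m.sa_norm:.3f} affinity={m.affinity:.3f} "
    f"-> fitness={best.fitness:.3f} (harmonic mean of the three)"
)
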