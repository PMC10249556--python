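"""Build a subword vocabulary from a synthetic corpus and pre-train the
masked language model.

Generates a 1,000-molecule drug-like corpus, learns a 256-token subword
vocabulary by pair merging, pre-trains the small transformer for three
epochs of masked-token prediction, and shows top-5 mask completions for
one molecule.
"""

import numpy as np

import mlmga as M

corpus = M.generate_corpus(M.CorpusSpec(n_molecules=1000, min_sa_norm=0.30, seed=0))
vocab = M.build_vocabulary(corpus, target_size=256)
print(f"corpus: {len(corpus)} molecules, vocabulary: {len(vocab)} tokens")
print("longest merged tokens:", sorted(vocab.tokens, key=len)[-5:])

sequences = [M.encode(vocab, s) for s in corpus]
model = M.TransformerPredictor(vocab, M.TransformerConfig(), seed=0)
report = model.pretrain(sequences, epochs=3, masking_rate=0.15)
print(
    f"masked cross-entropy: {report.mean_masked_loss_start:.3f} -> "
    f"{report.mean_masked_loss_end:.3f} after {report.epochs} epochs "
    f"(lower = better token reconstruction)"
)

# mask the second token of a corpus molecule and inspect the ranking
smiles = corpus[0]
seq = M.encode(vocab, smiles)
masked = M.TokenSequence((seq.ids[0], vocab.mask_id) + seq.ids[2:])
ranked = model.predict_topk(masked, k=5)[0]
print(f"\n{smiles!r} with token 2 masked; top-5 completions:")
for token_id, prob in ranked:
    print(f"  {vocab.tokens[token_id]!r:10s} p={prob:.3f}")
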