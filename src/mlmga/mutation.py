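"""Masked-mutation operators.

A parent molecule is mutated by masking part of its token sequence and
letting a masked-token predictor fill the blanks.  Three mutation types
are supported:

* **replacement** — sampled token positions become masks (length kept);
* **insertion** — a mask is inserted before one sampled token, the
  remaining sampled positions become replacements (length +1);
* **deletion** — one site becomes a mask and the token following it is
  deleted, the remaining sampled positions become replacements
  (length −1).

The number of masks is a binomial draw over the token count at the
mutation rate, with a floor of one mask per molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .predictor import MaskedPredictor
from .tokenizer import TokenSequence, decode

__all__ = [
    "MUTATION_TYPES",
    "MutationPlan",
    "draw_mask_count",
    "plan_mutation",
    "apply_plan",
    "generate_offspring",
]

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("replacement", "insertion", "deletion")
MutationType = Literal["replacement", "insertion", "deletion"]


@dataclass(frozen=True)
class MutationPlan:
    """A parent sequence plus where and how it will be masked.

    ``designated`` is the site that receives the insertion/deletion
    treatment; the remaining ``mask_positions`` are replacements.  For
    pure replacement it is ``None``.
    """

    parent: TokenSequence
    mtype: MutationType
    mask_positions: tuple[int, ...]
    rate: float
    designated: int | None = None

    def __post_init__(self) -> None:
        if self.mtype not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mtype!r}")
        pos = tuple(sorted(self.mask_positions))
        if len(pos) < 1:
            raise ValueError("a plan needs at least one mask position")
        if len(set(pos)) != len(pos):
            raise ValueError("mask positions must be distinct")
        if pos[0] < 0 or pos[-1] >= len(self.parent):
            raise ValueError("mask positions out of parent bounds")
        object.__setattr__(self, "mask_positions", pos)


def draw_mask_count(n_tokens: int, rate: float, rng: np.random.Generator) -> int:
    """Binomial(n_tokens, rate) draw with a floor of 1 and cap of n_tokens."""
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    return min(max(1, int(rng.binomial(n_tokens, rate))), n_tokens)


def plan_mutation(
    parent: TokenSequence,
    mtype: MutationType,
    rate: float,
    rng: np.random.Generator,
) -> MutationPlan:
    """Draw a mask count and sample mask locations for one parent.

    Replacement and insertion sample positions uniformly without
    replacement; the insertion site is the first sorted position.  For
    deletion the deletion site is drawn first among positions that have a
    following token, and the remaining replacement positions avoid the
    token slated for deletion, so the deleted token is never itself a
    mask and the length arithmetic is exact.  A deletion on a one-token
    parent has nothing to delete and degrades to replacement.
    """
    n = len(parent)
    count = draw_mask_count(n, rate, rng)
    if mtype in ("replacement", "insertion"):
        positions = tuple(int(i) for i in rng.choice(n, size=count, replace=False))
        designated = min(positions) if mtype == "insertion" else None
        return MutationPlan(parent, mtype, positions, rate, designated)
    # deletion
    if n == 1:
        logger.debug("deletion on a 1-token parent degrades to replacement")
        return MutationPlan(parent, "replacement", (0,), rate, None)
    designated = int(rng.integers(n - 1))
    count = min(count, n - 1)  # the deleted token cannot also be masked
    pool = [i for i in range(n) if i not in (designated, designated + 1)]
    extra = (
        tuple(int(i) for i in rng.choice(len(pool), size=count - 1, replace=False))
        if count > 1
        else ()
    )
    positions = (designated,) + tuple(pool[i] for i in extra)
    return MutationPlan(parent, "deletion", positions, rate, designated)


def apply_plan(plan: MutationPlan, mask_id: int) -> TokenSequence:
    """Materialize the plan as a token sequence containing mask tokens."""
    ids = list(plan.parent.ids)
    if plan.mtype == "replacement":
        for p in plan.mask_positions:
            ids[p] = mask_id
        return TokenSequence(tuple(ids))
    if plan.mtype == "insertion":
        d = plan.designated if plan.designated is not None else plan.mask_positions[0]
        for p in plan.mask_positions:
            if p != d:
                ids[p] = mask_id
        ids.insert(d, mask_id)
        return TokenSequence(tuple(ids))
    # deletion
    d = plan.designated if plan.designated is not None else plan.mask_positions[0]
    if d >= len(ids) - 1:
        logger.debug("deletion site has no following token; using replacement")
        for p in plan.mask_positions:
            ids[p] = mask_id
        return TokenSequence(tuple(ids))
    for p in plan.mask_positions:
        ids[p] = mask_id
    del ids[d + 1]
    return TokenSequence(tuple(ids))


def generate_offspring(
    predictor: MaskedPredictor,
    parent: TokenSequence,
    rate: float,
    k: int = 5,
    mode: Literal["topk", "sample"] = "topk",
    rng: np.random.Generator | None = None,
    mtype: MutationType | None = None,
    temperature: float = 1.0,
) -> list[str]:
    """Propose up to ``k`` offspring SMILES from one parent.

    A mutation type is chosen uniformly at random (unless forced), one
    plan is drawn and applied, and the masks are filled either with the
    predictor's rank-1..rank-``k`` candidates (``topk`` mode: offspring
    *i* takes the rank-*i* token at every masked position) or with ``k``
    independent Gumbel-softmax samples (``sample`` mode).  Decoded
    duplicates are removed; parents too long for the predictor yield no
    offspring.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    vocab = predictor.vocab
    if mtype is None:
        mtype = MUTATION_TYPES[int(rng.integers(len(MUTATION_TYPES)))]
    plan = plan_mutation(parent, mtype, rate, rng)
    masked = apply_plan(plan, vocab.mask_id)
    if len(masked) > predictor.max_seq_len:
        logger.debug("parent of %d tokens exceeds model window; skipped", len(masked))
        return []
    if vocab.unk_id in parent.ids:
        return []

    fills: list[list[int]] = []
    if mode == "topk":
        ranked = predictor.predict_topk(masked, k)
        for i in range(k):
            fills.append([ranked[pos][i][0] for pos in range(len(ranked))])
    elif mode == "sample":
        for _ in range(k):
            fills.append(predictor.predict_sample(masked, temperature, rng))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mask_positions = [i for i, t in enumerate(masked.ids) if t == vocab.mask_id]
    seen: set[str] = set()
    offspring: list[str] = []
    for fill in fills:
        ids = list(masked.ids)
        for pos, tok in zip(mask_positions, fill):
            ids[pos] = tok
        if vocab.unk_id in ids:
            continue
        smiles = decode(vocab, ids)
        if smiles and smiles not in seen:
            seen.add(smiles)
            offspring.append(smiles)
    return offspring
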