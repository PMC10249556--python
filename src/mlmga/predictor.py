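"""Masked-token prediction backends.

A masked predictor fills [MASK] positions in a token sequence and is the
mutation engine of the genetic algorithm: given a partially masked
molecule it ranks vocabulary tokens at each masked position.  Two
interchangeable backends are provided:

* :class:`NGramPredictor` — a positional (left-token, right-token)
  frequency model with unigram backoff.  Training is exact counting, so
  every prediction can be verified against a brute-force oracle; it is
  also fast enough for large test batteries.
* :class:`~mlmga.transformer.TransformerPredictor` — a small
  bidirectional transformer encoder trained by masked-token
  cross-entropy (see :mod:`mlmga.transformer`).

Both support ``pretrain`` (multi-epoch training on a corpus), ``adapt``
(exactly one epoch on a population — the operation that turns the fixed
strategy into the adaptive one), deterministic top-k ranking and
Gumbel-perturbed categorical sampling.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tokenizer import TokenSequence, TokenVocabulary

__all__ = ["TrainReport", "MaskedPredictor", "NGramPredictor", "load_predictor"]


@dataclass(frozen=True)
class TrainReport:
    """Summary of one training call (pretrain or adapt)."""

    epochs: int
    mean_masked_loss_start: float
    mean_masked_loss_end: float
    n_sequences: int

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("TrainReport requires n_sequences >= 1")
        for v in (self.mean_masked_loss_start, self.mean_masked_loss_end):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"loss must be finite and nonnegative, got {v}")


class MaskedPredictor(ABC):
    """Contract shared by all mask-prediction backends.

    Subclasses implement :meth:`_masked_log_probs`, returning one
    log-probability row over the vocabulary per masked position;
    ranking and sampling are derived here so their tie-breaking and
    Gumbel mechanics are identical across backends.
    """

    vocab: TokenVocabulary
    backend_name: str = "abstract"

    #: Sequences longer than this are skipped during training and mutation.
    max_seq_len: int = 128

    @abstractmethod
    def _masked_log_probs(self, seq: TokenSequence) -> np.ndarray:
        """(n_masks, |vocab|) natural-log probabilities, one row per mask."""

    @abstractmethod
    def pretrain(
        self,
        corpus: Iterable[TokenSequence],
        epochs: int = 1,
        masking_rate: float = 0.15,
    ) -> TrainReport:
        """Train on a corpus for ``epochs`` epochs of masked prediction."""

    @abstractmethod
    def adapt(self, population: Sequence[TokenSequence]) -> TrainReport:
        """One epoch of masked-prediction training on ``population``."""

    @abstractmethod
    def state_dict(self) -> dict:
        """Copyable snapshot of the trainable state."""

    @abstractmethod
    def load_state_dict(self, state: dict) -> None:
        """Restore a snapshot taken with :meth:`state_dict`."""

    @abstractmethod
    def save(self, directory) -> None:
        """Persist vocabulary, weights and a JSON sidecar to a directory."""

    # -- derived operations -------------------------------------------------

    def mask_positions(self, seq: TokenSequence) -> list[int]:
        mask_id = self.vocab.mask_id
        return [i for i, t in enumerate(seq.ids) if t == mask_id]

    def _check_masked_input(self, seq: TokenSequence) -> list[int]:
        positions = self.mask_positions(seq)
        if not positions:
            raise ValueError("input sequence contains no mask token")
        return positions

    def predict_topk(
        self, seq: TokenSequence, k: int
    ) -> list[list[tuple[int, float]]]:
        """Rank the top ``k`` candidate tokens at every masked position.

        Returns one ranked list per mask (in sequence order) of
        ``(token_id, probability)`` pairs, probabilities non-increasing,
        ties broken by ascending token ID.  Special tokens never appear.
        """
        self._check_masked_input(seq)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > self.vocab.n_predictable:
            raise ValueError(
                f"k={k} exceeds the {self.vocab.n_predictable} predictable tokens"
            )
        logp = self._masked_log_probs(seq)
        probs = np.exp(logp)
        probs[:, list(self.vocab.special_ids)] = -1.0  # rank specials last, below p=0
        out: list[list[tuple[int, float]]] = []
        for row in probs:
            # argsort on (-p, id): stable sort over id-ordered array
            order = np.argsort(-row, kind="stable")[:k]
            out.append([(int(t), float(max(row[t], 0.0))) for t in order])
        return out

    def predict_sample(
        self,
        seq: TokenSequence,
        temperature: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> list[int]:
        """Sample one token per masked position via Gumbel perturbation.

        Draws ``argmax(log p / T + G)`` with i.i.d. standard Gumbel noise
        ``G`` — the hard Gumbel-softmax sample from the model's categorical
        distribution at temperature ``T``.  As ``T → 0`` this reduces to
        the rank-1 candidate of :meth:`predict_topk`.
        """
        self._check_masked_input(seq)
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        rng = np.random.default_rng() if rng is None else rng
        logp = self._masked_log_probs(seq).copy()
        logp[:, list(self.vocab.special_ids)] = -np.inf
        gumbel = rng.gumbel(size=logp.shape)
        return [int(t) for t in np.argmax(logp / temperature + gumbel, axis=1)]

    def trainable_sequences(
        self, sequences: Iterable[TokenSequence]
    ) -> list[TokenSequence]:
        """Drop sequences exceeding ``max_seq_len`` or containing unk."""
        unk = self.vocab.unk_id
        return [
            s
            for s in sequences
            if len(s) <= self.max_seq_len and unk not in s.ids
        ]


class NGramPredictor(MaskedPredictor):
    """Positional bigram-context frequency model.

    For a mask at position *i* the context is the ordered pair
    ``(token[i-1], token[i+1])`` with virtual begin/end sentinels at the
    sequence boundaries; a masked or unseen neighbour falls back to
    unigram frequencies.  Distributions use add-one smoothing over the
    predictable vocabulary so cross-entropies stay finite.

    Training ("one epoch") adds each sequence's (left, centre, right)
    triples to the count tables — the model's exact analogue of one pass
    of masked-prediction training, independent of any masking rate.
    """

    backend_name = "ngram"

    BOS = -1
    EOS = -2

    def __init__(self, vocab: TokenVocabulary, seed: int = 0):
        self.vocab = vocab
        self.rng_seed = int(seed)
        self.context_counts: dict[tuple[int, int], Counter[int]] = {}
        self.unigram_counts: Counter[int] = Counter()

    # -- distributions ------------------------------------------------------

    def _distribution(self, left: int, right: int) -> np.ndarray:
        """Smoothed probability vector over the full vocabulary."""
        V = len(self.vocab)
        counts = np.zeros(V)
        table = self.context_counts.get((left, right))
        if table is None:
            table = self.unigram_counts
        for tid, c in table.items():
            counts[tid] = c
        predictable = np.ones(V, bool)
        predictable[list(self.vocab.special_ids)] = False
        probs = np.zeros(V)
        probs[predictable] = (counts[predictable] + 1.0) / (
            counts[predictable].sum() + predictable.sum()
        )
        return probs

    def _context(self, ids: Sequence[int], i: int) -> tuple[int, int]:
        left = ids[i - 1] if i > 0 else self.BOS
        right = ids[i + 1] if i < len(ids) - 1 else self.EOS
        return int(left), int(right)

    def _masked_log_probs(self, seq: TokenSequence) -> np.ndarray:
        positions = self.mask_positions(seq)
        rows = np.empty((len(positions), len(self.vocab)))
        mask_id = self.vocab.mask_id
        for r, i in enumerate(positions):
            left, right = self._context(seq.ids, i)
            # a masked neighbour is no context at all
            if left == mask_id:
                left = self.BOS - 10  # unseen key -> unigram backoff
            if right == mask_id:
                right = self.BOS - 10
            with np.errstate(divide="ignore"):
                rows[r] = np.log(self._distribution(left, right))
        return rows

    # -- training -----------------------------------------------------------

    def _mean_cross_entropy(self, sequences: Sequence[TokenSequence]) -> float:
        """Mean −log p(token | left, right) over every position."""
        total, n = 0.0, 0
        for seq in sequences:
            ids = seq.ids
            for i, tid in enumerate(ids):
                left, right = self._context(ids, i)
                p = self._distribution(left, right)[tid]
                total += -np.log(p) if p > 0 else np.inf
                n += 1
        return total / max(n, 1)

    def _count_epoch(self, sequences: Sequence[TokenSequence]) -> None:
        for seq in sequences:
            ids = seq.ids
            for i, tid in enumerate(ids):
                key = self._context(ids, i)
                self.context_counts.setdefault(key, Counter())[tid] += 1
                self.unigram_counts[tid] += 1

    def pretrain(self, corpus, epochs: int = 1, masking_rate: float = 0.15) -> TrainReport:
        if not 0 < masking_rate < 1:
            raise ValueError("masking_rate must be in (0, 1)")
        sequences = self.trainable_sequences(list(corpus))
        if not sequences:
            raise ValueError("cannot train on an empty corpus")
        start = self._mean_cross_entropy(sequences)
        for _ in range(epochs):
            self._count_epoch(sequences)
        end = self._mean_cross_entropy(sequences) if epochs > 0 else start
        return TrainReport(epochs, start, end, len(sequences))

    def adapt(self, population: Sequence[TokenSequence]) -> TrainReport:
        return self.pretrain(population, epochs=1)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "context_counts": {
                k: dict(v) for k, v in self.context_counts.items()
            },
            "unigram_counts": dict(self.unigram_counts),
        }

    def load_state_dict(self, state: dict) -> None:
        self.context_counts = {
            tuple(k): Counter(v) for k, v in state["context_counts"].items()
        }
        self.unigram_counts = Counter(state["unigram_counts"])

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vocab.save(directory / "vocab.txt")
        serializable = {
            "context_counts": [
                [list(k), dict(v)] for k, v in self.context_counts.items()
            ],
            "unigram_counts": dict(self.unigram_counts),
        }
        (directory / "weights.json").write_text(json.dumps(serializable))
        sidecar = {
            "backend": self.backend_name,
            "rng_seed": self.rng_seed,
            "max_seq_len": self.max_seq_len,
        }
        (directory / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "NGramPredictor":
        directory = Path(directory)
        vocab = TokenVocabulary.load(directory / "vocab.txt")
        sidecar = json.loads((directory / "config.json").read_text())
        model = cls(vocab, seed=sidecar.get("rng_seed", 0))
        raw = json.loads((directory / "weights.json").read_text())
        model.context_counts = {
            tuple(k): Counter({int(t): c for t, c in v.items()})
            for k, v in raw["context_counts"]
        }
        model.unigram_counts = Counter(
            {int(t): c for t, c in raw["unigram_counts"].items()}
        )
        return model


def load_predictor(directory) -> MaskedPredictor:
    """Load any saved predictor by inspecting its JSON sidecar."""
    directory = Path(directory)
    sidecar = json.loads((directory / "config.json").read_text())
    backend = sidecar["backend"]
    if backend == "ngram":
        return NGramPredictor.load(directory)
    if backend == "transformer":
        from .transformer import TransformerPredictor

        return TransformerPredictor.load(directory)
    raise ValueError(f"unknown predictor backend {backend!r}")
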