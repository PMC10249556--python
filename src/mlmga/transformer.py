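"""A compact bidirectional transformer encoder for masked-token prediction.

This is a BERT-style masked language model implemented directly in NumPy
(forward and backward passes written out, Adam optimizer), sized for
desk-scale corpora: 2 pre-norm encoder layers, 2 attention heads, model
width 64 by default.  The architecture at scale (deeper/wider presets) is
a configuration choice, not a code change.

Design notes
------------
* Pre-norm residual blocks (LayerNorm before attention / feed-forward)
  keep small-model training stable without warmup schedules.
* The output projection is evaluated only at masked positions — during
  both training and inference the loss and predictions depend on nothing
  else, and the vocabulary projection dominates FLOPs otherwise.
* Training masks each position independently with probability
  ``masking_rate`` (at least one per sequence) and always writes the
  literal [MASK] token, because at mutation time inputs always carry
  literal masks.
* All randomness flows through a generator seeded at construction;
  ``save``/``load`` round-trips weights bit-exactly through ``.npz``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .predictor import MaskedPredictor, TrainReport
from .tokenizer import TokenSequence, TokenVocabulary

__all__ = ["TransformerConfig", "TransformerPredictor"]

_GELU_C = float(np.sqrt(2.0 / np.pi))
_GELU_A = 0.044715


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * x**3)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    t = np.tanh(_GELU_C * (x + _GELU_A * x**3))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * _GELU_C * (1.0 + 3 * _GELU_A * x**2)


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    istd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * istd
    return g * xhat + b, (xhat, istd)


def _layernorm_bwd(dy, g, cache):
    xhat, istd = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = istd * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class TransformerConfig:
    """Model and optimizer hyperparameters.

    ``learning_rate`` applies to pre-training; population adaptation uses
    ``adapt_lr_factor`` times that rate.  The factor defaults to 1: with
    desk-scale populations of a few hundred molecules, one epoch is only a
    handful of optimizer steps, and continued training below the
    pre-training rate is too weak to move the proposal distribution within
    a generation.  Set it lower to anchor adaptation to the pre-trained
    solution when populations (and hence steps per epoch) are large.
    """

    n_layers: int = 2
    n_heads: int = 2
    d_model: int = 64
    d_ff: int = 128
    max_seq_len: int = 128
    learning_rate: float = 3e-3
    adapt_lr_factor: float = 1.0
    batch_size: int = 32
    init_scale: float = 0.02


class TransformerPredictor(MaskedPredictor):
    """Trainable masked language model over a :class:`TokenVocabulary`."""

    backend_name = "transformer"

    def __init__(
        self,
        vocab: TokenVocabulary,
        config: TransformerConfig | None = None,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.config = config or TransformerConfig()
        if self.config.d_model % self.config.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.rng_seed = int(seed)
        self.max_seq_len = self.config.max_seq_len
        self._rng = np.random.default_rng(seed)
        self.params = self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        # pre-training and population adaptation are distinct training
        # phases; each starts with a fresh optimizer state
        self._phase = "init"

    def _reset_optimizer(self) -> None:
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ init

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        V, d, ff = len(self.vocab), cfg.d_model, cfg.d_ff
        rng = self._rng
        s = cfg.init_scale

        def W(*shape):
            return rng.normal(0.0, s, size=shape)

        p: dict[str, np.ndarray] = {
            "emb": W(V, d),
            "pos": W(cfg.max_seq_len, d),
            "lnf_g": np.ones(d),
            "lnf_b": np.zeros(d),
            "out_W": W(d, V),
            "out_b": np.zeros(V),
        }
        for l in range(cfg.n_layers):
            p.update(
                {
                    f"l{l}_ln1_g": np.ones(d),
                    f"l{l}_ln1_b": np.zeros(d),
                    f"l{l}_Wq": W(d, d),
                    f"l{l}_bq": np.zeros(d),
                    f"l{l}_Wk": W(d, d),
                    f"l{l}_bk": np.zeros(d),
                    f"l{l}_Wv": W(d, d),
                    f"l{l}_bv": np.zeros(d),
                    f"l{l}_Wo": W(d, d),
                    f"l{l}_bo": np.zeros(d),
                    f"l{l}_ln2_g": np.ones(d),
                    f"l{l}_ln2_b": np.zeros(d),
                    f"l{l}_W1": W(d, ff),
                    f"l{l}_b1": np.zeros(ff),
                    f"l{l}_W2": W(ff, d),
                    f"l{l}_b2": np.zeros(d),
                }
            )
        return p

    # --------------------------------------------------------------- forward

    def _encode_batch(self, X: np.ndarray, valid: np.ndarray):
        """Run the encoder stack; returns final hidden states and caches."""
        p, cfg = self.params, self.config
        B, T = X.shape
        H, d = cfg.n_heads, cfg.d_model
        dh = d // H
        h = p["emb"][X] + p["pos"][:T]
        key_bias = np.where(valid[:, None, None, :], 0.0, -1e9)  # (B,1,1,T)
        caches = []
        for l in range(cfg.n_layers):
            a, ln1c = _layernorm_fwd(h, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            q = a @ p[f"l{l}_Wq"] + p[f"l{l}_bq"]
            k = a @ p[f"l{l}_Wk"] + p[f"l{l}_bk"]
            v = a @ p[f"l{l}_Wv"] + p[f"l{l}_bv"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            A = _softmax(scores)
            oh = A @ vh
            o = oh.transpose(0, 2, 1, 3).reshape(B, T, d)
            att_out = o @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]
            h1 = h + att_out
            m, ln2c = _layernorm_fwd(h1, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            u = m @ p[f"l{l}_W1"] + p[f"l{l}_b1"]
            act = _gelu(u)
            f = act @ p[f"l{l}_W2"] + p[f"l{l}_b2"]
            h2 = h1 + f
            caches.append((h, a, ln1c, qh, kh, vh, A, o, h1, m, ln2c, u, act))
            h = h2
        hf, lnfc = _layernorm_fwd(h, p["lnf_g"], p["lnf_b"])
        return hf, (X, valid, caches, h, lnfc)

    def _loss_and_grads(
        self,
        X: np.ndarray,
        valid: np.ndarray,
        rows: np.ndarray,
        cols: np.ndarray,
        targets: np.ndarray,
    ):
        """Masked cross-entropy and gradients for one padded batch.

        ``rows``/``cols`` index the masked positions; ``targets`` are the
        original token IDs there.
        """
        p, cfg = self.params, self.config
        B, T = X.shape
        H, d = cfg.n_heads, cfg.d_model
        hd = d // H
        hf, (X, valid, caches, h_last, lnfc) = self._encode_batch(X, valid)

        sel = hf[rows, cols]  # (M, d)
        logits = sel @ p["out_W"] + p["out_b"]  # (M, V)
        logp = logits - logits.max(1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(1, keepdims=True))
        M = len(targets)
        loss = -logp[np.arange(M), targets].mean()

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = np.exp(logp)
        dlogits[np.arange(M), targets] -= 1.0
        dlogits /= M
        grads["out_W"] = sel.T @ dlogits
        grads["out_b"] = dlogits.sum(0)
        dhf = np.zeros_like(hf)
        np.add.at(dhf, (rows, cols), dlogits @ p["out_W"].T)

        dh, dg, db = _layernorm_bwd(dhf, p["lnf_g"], lnfc)
        grads["lnf_g"], grads["lnf_b"] = dg, db

        for l in reversed(range(cfg.n_layers)):
            (h0, a, ln1c, qh, kh, vh, A, o, h1, m, ln2c, u, act) = caches[l]
            # feed-forward block
            dact_out = dh  # gradient on f (residual add)
            grads[f"l{l}_W2"] += act.reshape(-1, cfg.d_ff).T @ dact_out.reshape(-1, d)
            grads[f"l{l}_b2"] += dact_out.sum((0, 1))
            dact = dact_out @ p[f"l{l}_W2"].T
            du = dact * _gelu_grad(u)
            grads[f"l{l}_W1"] += m.reshape(-1, d).T @ du.reshape(-1, cfg.d_ff)
            grads[f"l{l}_b1"] += du.sum((0, 1))
            dm = du @ p[f"l{l}_W1"].T
            dh1_ln, dg, db = _layernorm_bwd(dm, p[f"l{l}_ln2_g"], ln2c)
            grads[f"l{l}_ln2_g"] += dg
            grads[f"l{l}_ln2_b"] += db
            dh1 = dh + dh1_ln
            # attention block
            datt_out = dh1
            grads[f"l{l}_Wo"] += o.reshape(-1, d).T @ datt_out.reshape(-1, d)
            grads[f"l{l}_bo"] += datt_out.sum((0, 1))
            do = datt_out @ p[f"l{l}_Wo"].T
            B_, T_ = do.shape[:2]
            doh = do.reshape(B_, T_, H, hd).transpose(0, 2, 1, 3)
            dA = doh @ vh.transpose(0, 1, 3, 2)
            dvh = A.transpose(0, 1, 3, 2) @ doh
            dscores = A * (dA - (dA * A).sum(-1, keepdims=True))
            dqh = dscores @ kh / np.sqrt(hd)
            dkh = dscores.transpose(0, 1, 3, 2) @ qh / np.sqrt(hd)
            dq = dqh.transpose(0, 2, 1, 3).reshape(B_, T_, d)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B_, T_, d)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B_, T_, d)
            grads[f"l{l}_Wq"] += a.reshape(-1, d).T @ dq.reshape(-1, d)
            grads[f"l{l}_bq"] += dq.sum((0, 1))
            grads[f"l{l}_Wk"] += a.reshape(-1, d).T @ dk.reshape(-1, d)
            grads[f"l{l}_bk"] += dk.sum((0, 1))
            grads[f"l{l}_Wv"] += a.reshape(-1, d).T @ dv.reshape(-1, d)
            grads[f"l{l}_bv"] += dv.sum((0, 1))
            da = dq @ p[f"l{l}_Wq"].T + dk @ p[f"l{l}_Wk"].T + dv @ p[f"l{l}_Wv"].T
            dh0_ln, dg, db = _layernorm_bwd(da, p[f"l{l}_ln1_g"], ln1c)
            grads[f"l{l}_ln1_g"] += dg
            grads[f"l{l}_ln1_b"] += db
            dh = dh1 + dh0_ln

        T = X.shape[1]
        grads["pos"][:T] = dh.sum(0)
        np.add.at(grads["emb"], X, dh)
        return float(loss), grads

    # -------------------------------------------------------------- training

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _make_batch(self, seqs: list[TokenSequence], rng: np.random.Generator, masking_rate: float):
        """Pad, apply dynamic masking (min one mask per sequence)."""
        pad = self.vocab.pad_id
        mask = self.vocab.mask_id
        T = max(len(s) for s in seqs)
        B = len(seqs)
        X = np.full((B, T), pad, dtype=np.int64)
        valid = np.zeros((B, T), dtype=bool)
        rows, cols, targets = [], [], []
        for b, s in enumerate(seqs):
            ids = np.asarray(s.ids)
            n = len(ids)
            X[b, :n] = ids
            valid[b, :n] = True
            m = rng.random(n) < masking_rate
            if not m.any():
                m[rng.integers(n)] = True
            for i in np.flatnonzero(m):
                rows.append(b)
                cols.append(int(i))
                targets.append(int(ids[i]))
                X[b, i] = mask
        return X, valid, np.asarray(rows), np.asarray(cols), np.asarray(targets)

    def _run_epoch(
        self,
        sequences: list[TokenSequence],
        rng: np.random.Generator,
        masking_rate: float,
        lr: float | None,
    ) -> float:
        """One pass over the data; ``lr=None`` evaluates without updating."""
        order = rng.permutation(len(sequences))
        bs = self.config.batch_size
        total, count = 0.0, 0
        for start in range(0, len(sequences), bs):
            batch = [sequences[i] for i in order[start : start + bs]]
            X, valid, rows, cols, targets = self._make_batch(batch, rng, masking_rate)
            loss, grads = self._loss_and_grads(X, valid, rows, cols, targets)
            if lr is not None:
                self._adam_step(grads, lr)
            total += loss * len(targets)
            count += len(targets)
        return total / max(count, 1)

    def _train(
        self, sequences: Sequence[TokenSequence], epochs: int, masking_rate: float, lr: float
    ) -> TrainReport:
        if not 0 < masking_rate < 1:
            raise ValueError("masking_rate must be in (0, 1)")
        kept = self.trainable_sequences(list(sequences))
        if not kept:
            raise ValueError("cannot train on an empty corpus")
        if len(kept) < len(list(sequences)):
            warnings.warn(
                f"skipped {len(list(sequences)) - len(kept)} sequences "
                f"(longer than {self.max_seq_len} tokens or containing unk)",
                stacklevel=2,
            )
        eval_rng = np.random.default_rng(self.rng_seed + 7919)
        start = self._run_epoch(kept, np.random.default_rng(eval_rng.integers(2**31)), masking_rate, lr=None)
        end = start
        for _ in range(epochs):
            end = self._run_epoch(kept, self._rng, masking_rate, lr=lr)
        return TrainReport(epochs, start, end, len(kept))

    def pretrain(
        self,
        corpus: Iterable[TokenSequence],
        epochs: int = 1,
        masking_rate: float = 0.15,
    ) -> TrainReport:
        if self._phase != "pretrain":
            self._reset_optimizer()
            self._phase = "pretrain"
        return self._train(list(corpus), epochs, masking_rate, self.config.learning_rate)

    def adapt(self, population: Sequence[TokenSequence]) -> TrainReport:
        if self._phase != "adapt":
            self._reset_optimizer()
            self._phase = "adapt"
        lr = self.config.learning_rate * self.config.adapt_lr_factor
        return self._train(list(population), 1, 0.15, lr)

    # ------------------------------------------------------------- inference

    def _masked_log_probs(self, seq: TokenSequence) -> np.ndarray:
        if len(seq) > self.max_seq_len:
            raise ValueError(
                f"sequence of {len(seq)} tokens exceeds max_seq_len={self.max_seq_len}"
            )
        positions = self.mask_positions(seq)
        X = np.asarray(seq.ids, dtype=np.int64)[None, :]
        valid = np.ones_like(X, dtype=bool)
        hf, _ = self._encode_batch(X, valid)
        sel = hf[0, positions]
        logits = sel @ self.params["out_W"] + self.params["out_b"]
        logp = logits - logits.max(1, keepdims=True)
        return logp - np.log(np.exp(logp).sum(1, keepdims=True))

    def masked_log_probs_batch(
        self, seqs: Sequence[TokenSequence]
    ) -> list[np.ndarray]:
        """Batched inference: one (n_masks, V) log-prob array per sequence."""
        pad = self.vocab.pad_id
        out: list[np.ndarray] = [None] * len(seqs)  # type: ignore[list-item]
        bs = self.config.batch_size
        idx = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
        for start in range(0, len(idx), bs):
            chunk = idx[start : start + bs]
            T = max(len(seqs[i]) for i in chunk)
            X = np.full((len(chunk), T), pad, dtype=np.int64)
            valid = np.zeros_like(X, dtype=bool)
            for b, i in enumerate(chunk):
                ids = seqs[i].ids
                X[b, : len(ids)] = ids
                valid[b, : len(ids)] = True
            hf, _ = self._encode_batch(X, valid)
            for b, i in enumerate(chunk):
                positions = self.mask_positions(seqs[i])
                sel = hf[b, positions]
                logits = sel @ self.params["out_W"] + self.params["out_b"]
                logp = logits - logits.max(1, keepdims=True)
                out[i] = logp - np.log(np.exp(logp).sum(1, keepdims=True))
        return out

    # ----------------------------------------------------------- persistence

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "adam_m": {k: v.copy() for k, v in self._adam_m.items()},
            "adam_v": {k: v.copy() for k, v in self._adam_v.items()},
            "adam_t": self._adam_t,
            "phase": self._phase,
            "rng_state": self._rng.bit_generator.state,
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self._adam_m = {k: v.copy() for k, v in state["adam_m"].items()}
        self._adam_v = {k: v.copy() for k, v in state["adam_v"].items()}
        self._adam_t = state["adam_t"]
        self._phase = state.get("phase", "init")
        self._rng.bit_generator.state = state["rng_state"]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vocab.save(directory / "vocab.txt")
        np.savez(directory / "weights.npz", **self.params)
        sidecar = {
            "backend": self.backend_name,
            "rng_seed": self.rng_seed,
            "config": asdict(self.config),
        }
        (directory / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "TransformerPredictor":
        directory = Path(directory)
        vocab = TokenVocabulary.load(directory / "vocab.txt")
        sidecar = json.loads((directory / "config.json").read_text())
        model = cls(
            vocab,
            config=TransformerConfig(**sidecar["config"]),
            seed=sidecar["rng_seed"],
        )
        with np.load(directory / "weights.npz") as data:
            model.params = {k: data[k].copy() for k in data.files}
        return model
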