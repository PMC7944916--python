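"""Autoregressive SMILES language model (the Generator policy).

A character/token-level recurrent policy: stacked LSTM layers over one-hot
token inputs, a dense softmax head over the vocabulary. Supervised
pre-training uses teacher forcing with the elementwise (binary-form)
cross-entropy loss summed over the vocabulary and averaged over unmasked
timesteps; pad positions are masked out. Generation is autoregressive
token-by-token sampling from the temperature-scaled softmax, starting at
'G' and stopping at 'E' or the length cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import smiles_data as sd
from .nn import Adam, Dense, LSTMStack, clip_gradients, softmax

EPS_PROB = 1e-8  # probability floor inside logs


def teacher_forcing_loss(
    y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Elementwise cross-entropy between one-hot targets and predictions.

    loss = -(1/T) * sum_t [ y_t·log(y_hat_t) + (1-y_t)·log(1-y_hat_t) ]

    where the inner product runs over the vocabulary dimension and T counts
    the unmasked timesteps. ``y`` and ``y_hat`` are (..., T, V); ``mask``
    (``..., T``), when given, excludes pad positions. Probabilities are
    floored at ``EPS_PROB`` so the loss is defined at 0 and 1.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    per_step = -(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat)).sum(axis=-1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        total = per_step[mask].sum()
        count = int(mask.sum())
    else:
        total = per_step.sum()
        count = per_step.size
    if count == 0:
        raise ValueError("no unmasked timesteps")
    return float(total / count)


@dataclass
class SampleResult:
    """One sampled SMILES with its per-token sampling log-probabilities."""

    smiles: str
    token_ids: list[int]              # emitted ids (after 'G'), incl. 'E' if reached
    stepwise_logprobs: list[float]    # ln p of each emitted token
    terminated: bool                  # 'E' emitted before the length cap
    provenance: list[str] = field(default_factory=list)  # 'G_b'/'G_u' per token


class SmilesGenerator(BaseEstimator):
    """SMILES recurrent language model / RL policy.

    Parameters
    ----------
    recurrent_layers, recurrent_units : int
        Stacked LSTM depth and width (2 x 256 at full scale).
    dropout : float
        Inter-layer dropout during pre-training.
    max_len : int
        Fixed padded sequence length including 'G' and 'E' (65 at full
        scale). Over-length training molecules are dropped and counted.
    learning_rate, batch_size, epochs, clip_bound :
        Adam pre-training schedule; gradients are clipped elementwise to
        [-clip_bound, clip_bound].
    temperature : float
        Default softmax temperature for sampling.
    random_state : int
        Seeds weight init, shuffling and sampling substreams.
    """

    def __init__(self, recurrent_layers: int = 2, recurrent_units: int = 256,
                 dropout: float = 0.3, max_len: int = sd.DEFAULT_MAX_LEN,
                 learning_rate: float = 1e-3, batch_size: int = 16,
                 epochs: int = 25, clip_bound: float = 3.0,
                 temperature: float = 1.0, random_state: int = 0) -> None:
        self.recurrent_layers = recurrent_layers
        self.recurrent_units = recurrent_units
        self.dropout = dropout
        self.max_len = max_len
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.clip_bound = clip_bound
        self.temperature = temperature
        self.random_state = random_state

    # -- model construction -------------------------------------------------

    def _build(self, vocab: sd.Vocabulary, rng: np.random.Generator) -> None:
        self.vocab_ = vocab
        self._lstm = LSTMStack(vocab.size, self.recurrent_units,
                               self.recurrent_layers, self.dropout, rng)
        self._head = Dense(self.recurrent_units, vocab.size, rng, name="head")
        self.params_ = {**self._lstm.params, **self._head.params}

    def _onehot(self, ids: np.ndarray) -> np.ndarray:
        out = np.zeros((*ids.shape, self.vocab_.size))
        np.put_along_axis(out, ids[..., None], 1.0, axis=-1)
        return out

    def _forward(self, input_ids: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, dict]:
        """Logits (B, T, V) for next-token prediction at every position."""
        x = self._onehot(input_ids)
        hidden, lstm_cache = self._lstm.forward(x, train=train, rng=rng)
        logits, head_cache = self._head.forward(hidden)
        return logits, {"lstm": lstm_cache, "head": head_cache}

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        head_grads, dhidden = self._head.backward(dlogits, cache["head"])
        lstm_grads, _ = self._lstm.backward(dhidden, cache["lstm"])
        return {**lstm_grads, **head_grads}

    # -- supervised pre-training --------------------------------------------

    def fit(self, X, y=None, vocab: sd.Vocabulary | None = None):
        """Teacher-forcing pre-training on a SMILES corpus.

        X : list of SMILES strings (already curated). The vocabulary is
        built from the corpus unless one is supplied.
        """
        corpus = list(X)
        if not corpus:
            raise ValueError("empty corpus")
        rng = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(rng.integers(2**31))
        shuffle_rng = np.random.default_rng(rng.integers(2**31))
        dropout_rng = np.random.default_rng(rng.integers(2**31))
        self._sample_rng = np.random.default_rng(rng.integers(2**31))

        self._build(vocab or sd.Vocabulary.from_corpus(corpus), init_rng)
        ids, self.n_dropped_ = self._encode_corpus(corpus)
        if ids.shape[0] == 0:
            raise ValueError("no sequence fits the configured max_len")

        opt = Adam(lr=self.learning_rate)
        self.history_ = []
        n = ids.shape[0]
        for _ in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                batch = ids[order[start:start + self.batch_size]]
                loss, grads = self._loss_and_grads(batch, dropout_rng)
                opt.step(self.params_, clip_gradients(grads, self.clip_bound))
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        return self

    def _encode_corpus(self, corpus: list[str]) -> tuple[np.ndarray, int]:
        rows, dropped = [], 0
        for smiles in corpus:
            tokens = sd.tokenize(smiles)
            try:
                padded = sd.pad_and_mark(tokens, self.max_len)
            except sd.OverLengthError:
                dropped += 1
                continue
            rows.append(self.vocab_.to_ids(padded))
        return np.asarray(rows, dtype=np.int64), dropped

    def _loss_and_grads(self, ids: np.ndarray,
                        dropout_rng: np.random.Generator
                        ) -> tuple[float, dict]:
        inputs, targets = ids[:, :-1], ids[:, 1:]
        logits, cache = self._forward(inputs, train=True, rng=dropout_rng)
        probs = softmax(logits)
        mask = targets != self.vocab_.pad_id
        y = self._onehot(targets)
        loss = teacher_forcing_loss(y, probs, mask)
        # gradient of the printed elementwise loss through the softmax
        p = np.clip(probs, EPS_PROB, 1.0 - EPS_PROB)
        g = -y / p + (1.0 - y) / (1.0 - p)         # dL/dp
        inner = (g * probs).sum(axis=-1, keepdims=True)
        dlogits = probs * (g - inner)
        dlogits *= mask[..., None] / max(int(mask.sum()), 1)
        return loss, self._backward(dlogits, cache)

    # -- sampling ------------------------------------------------------------

    def next_token_distribution(self, prefix_ids, temperature: float | None = None,
                                forbid_specials: bool = True) -> np.ndarray:
        """Distribution over the next token given a prefix (starting at 'G')."""
        temperature = self.temperature if temperature is None else temperature
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        prefix_ids = list(prefix_ids)
        if not prefix_ids or prefix_ids[0] != self.vocab_.start_id:
            raise ValueError("prefix must begin with the start token")
        state = self._lstm.init_state(1)
        logits = None
        for tok in prefix_ids:
            x = np.zeros((1, self.vocab_.size))
            x[0, tok] = 1.0
            h, state, _ = self._lstm.step(x, state)
            logits, _ = self._head.forward(h)
        return self._masked_softmax(logits, temperature, forbid_specials)[0]

    def _masked_softmax(self, logits: np.ndarray, temperature: float,
                        forbid_specials: bool = True) -> np.ndarray:
        scaled = logits / temperature
        if forbid_specials:
            scaled = scaled.copy()
            scaled[..., self.vocab_.pad_id] = -1e9  # no mid-string padding
            scaled[..., self.vocab_.start_id] = -1e9
        return softmax(scaled)

    def sample(self, n: int, temperature: float | None = None,
               seed: int | None = None) -> list[SampleResult]:
        """Draw ``n`` molecules autoregressively."""
        if n < 1:
            raise ValueError("n must be >= 1")
        temperature = self.temperature if temperature is None else temperature
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        rng = (np.random.default_rng(seed) if seed is not None
               else getattr(self, "_sample_rng", np.random.default_rng(0)))
        V = self.vocab_.size
        state = self._lstm.init_state(n)
        current = np.full(n, self.vocab_.start_id, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        ids: list[list[int]] = [[] for _ in range(n)]
        logps: list[list[float]] = [[] for _ in range(n)]
        for _ in range(self.max_len - 1):
            x = np.zeros((n, V))
            x[np.arange(n), current] = 1.0
            h, state, _ = self._lstm.step(x, state)
            logits, _ = self._head.forward(h)
            probs = self._masked_softmax(logits, temperature)
            u = rng.random((n, 1))
            chosen = (probs.cumsum(axis=1) > u).argmax(axis=1)
            for k in range(n):
                if not alive[k]:
                    continue
                ids[k].append(int(chosen[k]))
                logps[k].append(float(np.log(max(probs[k, chosen[k]], EPS_PROB))))
                if chosen[k] == self.vocab_.end_id:
                    alive[k] = False
            current = chosen
            if not alive.any():
                break
        return [
            SampleResult(
                smiles=sd.ids_to_smiles(ids[k], self.vocab_),
                token_ids=ids[k],
                stepwise_logprobs=logps[k],
                terminated=not alive[k],
            )
            for k in range(n)
        ]

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params_)
        sidecar = {
            "config": self.get_params(),
            "vocabulary": {
                "tokens": list(self.vocab_.tokens),
                "specials": {"start": self.vocab_.start_token,
                             "end": self.vocab_.end_token,
                             "pad": self.vocab_.pad_token},
            },
            "history": getattr(self, "history_", []),
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SmilesGenerator":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = cls(**sidecar["config"])
        sp = sidecar["vocabulary"]["specials"]
        vocab = sd.Vocabulary(tokens=tuple(sidecar["vocabulary"]["tokens"]),
                              start_token=sp["start"], end_token=sp["end"],
                              pad_token=sp["pad"])
        model._build(vocab, np.random.default_rng(0))
        with np.load(directory / "weights.npz") as data:
            for key in model.params_:
                model.params_[key][...] = data[key]
        model.history_ = sidecar.get("history", [])
        model._sample_rng = np.random.default_rng(model.random_state)
        return model

    def clone_model(self) -> "SmilesGenerator":
        """Deep copy with independent parameter arrays (same vocabulary)."""
        twin = SmilesGenerator(**self.get_params())
        twin._build(self.vocab_, np.random.default_rng(0))
        for key in twin.params_:
            twin.params_[key][...] = self.params_[key]
        twin.history_ = list(getattr(self, "history_", []))
        twin._sample_rng = np.random.default_rng(self.random_state)
        return twin


def train_generator(corpus, config: dict | None = None,
                    seed: int = 0) -> SmilesGenerator:
    """Functional wrapper: fit a :class:`SmilesGenerator` on a corpus."""
    model = SmilesGenerator(random_state=seed, **(config or {}))
    return model.fit(corpus)
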