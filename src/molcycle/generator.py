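"""Character-level LSTM language model over SMILES, in pure NumPy.

The model factorizes the probability of a SMILES string ``S = s_1 ... s_t``
as ``P(S) = prod_t P(s_t | s_1 ... s_{t-1})`` and is trained by next-character
cross-entropy with teacher forcing (backpropagation through time, Adam).
Sampling is autoregressive: each molecule starts from the ``G`` start symbol
with zeroed hidden/cell states and runs symbol by symbol until the ``\\n``
end symbol.

The implementation keeps the standard stacked-LSTM parameterization: per
layer a single input matrix ``Wx (D, 4H)``, recurrent matrix ``Wh (H, 4H)``
and one bias vector ``b (4H)`` covering the input, forget, cell and output
gates in that order, followed by a dense projection ``Wy (H, V)`` from the
top hidden state to vocabulary logits.  Softmax is applied only at sampling
or likelihood-evaluation time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from molcycle.corpus import EncodedCorpus, TokenVocabulary, one_hot

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture and optimization settings for the LSTM generator.

    Defaults are the full-scale architecture (three stacked layers of 1024
    units, 0.2 dropout, windows of 75 tokens in batches of 128).  The
    :meth:`desk` profile shrinks the network to 2 layers x 128 units for
    laptop-scale corpora.
    """

    vocab_size: int
    n_layers: int = 3
    hidden_size: int = 1024
    dropout: float = 0.2
    window_length: int = 75
    batch_size: int = 128
    learning_rate: float = 3e-3
    n_epochs: int = 10
    fine_tune_epochs: int = 1
    fine_tune_lr: float | None = None  # default: learning_rate / 10
    grad_clip: float = 5.0
    seed: int = 0
    max_sample_length: int = 120

    def __post_init__(self):
        if min(self.vocab_size, self.n_layers, self.hidden_size,
               self.window_length, self.batch_size) < 1:
            raise ValueError("all sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def desk(cls, vocab_size: int, **overrides) -> "GeneratorConfig":
        """Reduced test-scale profile: 2 layers x 128 hidden units."""
        defaults = dict(n_layers=2, hidden_size=128, n_epochs=20)
        defaults.update(overrides)
        return cls(vocab_size=vocab_size, **defaults)

    @property
    def effective_fine_tune_lr(self) -> float:
        return self.fine_tune_lr if self.fine_tune_lr is not None else self.learning_rate / 10.0


def lstm_parameter_count(
    vocab_size: int, n_layers: int, hidden_size: int, biases_per_gate: int = 1
) -> int:
    """Closed-form trainable parameter count of the stacked architecture.

    Per layer: ``4 * (H*(D+H) + biases_per_gate*H)`` where ``D`` is the layer
    input width (V for the first layer, H above), plus the dense output
    projection ``H*V + V``.  ``biases_per_gate`` distinguishes the one- and
    two-bias-vector gate conventions in circulation.
    """
    total = 0
    d = vocab_size
    for _ in range(n_layers):
        total += 4 * (hidden_size * (d + hidden_size) + biases_per_gate * hidden_size)
        d = hidden_size
    total += hidden_size * vocab_size + vocab_size
    return total


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GeneratorModel:
    """Stacked-LSTM next-character model with train / fine-tune / sample."""

    def __init__(self, config: GeneratorConfig, vocab: TokenVocabulary):
        if vocab.size != config.vocab_size:
            raise ValueError("config.vocab_size does not match the vocabulary")
        self.config = config
        self.vocab = vocab
        self.params = self._init_params(np.random.default_rng(config.seed))
        self._adam_state = None
        self.loss_trace: list[dict] = []

    # ---------------------------------------------------------------- setup

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        cfg = self.config
        H, V = cfg.hidden_size, cfg.vocab_size
        params: dict[str, np.ndarray] = {}
        d = V
        for layer in range(cfg.n_layers):
            scale_x = 1.0 / np.sqrt(d)
            scale_h = 1.0 / np.sqrt(H)
            params[f"Wx{layer}"] = rng.uniform(-scale_x, scale_x, (d, 4 * H)).astype(np.float32)
            params[f"Wh{layer}"] = rng.uniform(-scale_h, scale_h, (H, 4 * H)).astype(np.float32)
            b = np.zeros(4 * H, dtype=np.float32)
            b[H:2 * H] = 1.0  # forget-gate bias: remember by default
            params[f"b{layer}"] = b
            d = H
        params["Wy"] = rng.uniform(-1.0 / np.sqrt(H), 1.0 / np.sqrt(H), (H, V)).astype(np.float32)
        params["by"] = np.zeros(V, dtype=np.float32)
        return params

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, train_rng=None):
        """Forward pass over a (B, T) batch of token indices.

        Returns (logits, cache).  With ``train_rng`` given, inverted dropout
        is applied to the outputs of every LSTM layer except the top one.
        """
        cfg = self.config
        B, T = X.shape
        H, V = cfg.hidden_size, cfg.vocab_size
        dtype = self.params["by"].dtype
        x = one_hot(X, V).astype(dtype)  # (B, T, V)
        cache = {"X": X, "layers": []}
        inp = x
        for layer in range(cfg.n_layers):
            Wx, Wh, b = (self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                         self.params[f"b{layer}"])
            h = np.zeros((B, H), dtype=dtype)
            c = np.zeros((B, H), dtype=dtype)
            hs = np.empty((B, T, H), dtype=dtype)
            gates = np.empty((B, T, 4 * H), dtype=dtype)
            cs = np.empty((B, T, H), dtype=dtype)
            tanhc = np.empty((B, T, H), dtype=dtype)
            xW = inp @ Wx + b  # precompute the input contribution for all t
            for t in range(T):
                z = xW[:, t, :] + h @ Wh
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                gates[:, t, :H] = i
                gates[:, t, H:2 * H] = f
                gates[:, t, 2 * H:3 * H] = g
                gates[:, t, 3 * H:] = o
                cs[:, t] = c
                tanhc[:, t] = tc
                hs[:, t] = h
            layer_cache = {"inp": inp, "gates": gates, "cs": cs,
                           "tanhc": tanhc, "hs": hs}
            out = hs
            if train_rng is not None and cfg.dropout > 0 and layer < cfg.n_layers - 1:
                keep = 1.0 - cfg.dropout
                mask = (train_rng.random(hs.shape) < keep).astype(dtype) / keep
                out = hs * mask
                layer_cache["drop_mask"] = mask
            cache["layers"].append(layer_cache)
            inp = out
        logits = inp @ self.params["Wy"] + self.params["by"]
        cache["top_out"] = inp
        return logits, cache

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def _loss_and_grads(self, X, Y, train_rng):
        """Mean next-character cross-entropy and parameter gradients."""
        cfg = self.config
        B, T = X.shape
        H = cfg.hidden_size
        dtype = self.params["by"].dtype
        logits, cache = self._forward(X, train_rng=train_rng)
        probs = self._softmax(logits)
        n = B * T
        loss = -np.log(
            np.maximum(probs[np.arange(B)[:, None], np.arange(T)[None, :], Y], 1e-12)
        ).mean()

        dlogits = probs
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], Y] -= 1.0
        dlogits /= n

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        top = cache["top_out"]
        grads["Wy"] = top.reshape(n, H).T @ dlogits.reshape(n, -1)
        grads["by"] = dlogits.sum(axis=(0, 1))
        dout = dlogits @ self.params["Wy"].T  # gradient wrt top layer output

        for layer in range(cfg.n_layers - 1, -1, -1):
            lc = cache["layers"][layer]
            if "drop_mask" in lc:
                dout = dout * lc["drop_mask"]
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            gates, cs, tanhc, hs, inp = (lc["gates"], lc["cs"], lc["tanhc"],
                                         lc["hs"], lc["inp"])
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(self.params[f"b{layer}"])
            dinp = np.empty_like(inp)
            dh_next = np.zeros((B, H), dtype=dtype)
            dc_next = np.zeros((B, H), dtype=dtype)
            for t in range(T - 1, -1, -1):
                i = gates[:, t, :H]
                f = gates[:, t, H:2 * H]
                g = gates[:, t, 2 * H:3 * H]
                o = gates[:, t, 3 * H:]
                tc = tanhc[:, t]
                dh = dout[:, t] + dh_next
                dc = dc_next + dh * o * (1.0 - tc * tc)
                c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(dc)
                dz = np.empty((B, 4 * H), dtype=dtype)
                dz[:, :H] = dc * g * i * (1.0 - i)
                dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
                dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
                dz[:, 3 * H:] = dh * tc * o * (1.0 - o)
                h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
                dWx += inp[:, t].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dinp[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
                dc_next = dc * f
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"b{layer}"] = db
            dout = dinp
        return loss, grads

    # ------------------------------------------------------------- training

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = {
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
                "t": 0,
            }
        st = self._adam_state
        st["t"] += 1
        # global gradient-norm clipping
        norm = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
        clip = self.config.grad_clip
        scale = clip / norm if (clip > 0 and norm > clip) else 1.0
        t = st["t"]
        for k, g in grads.items():
            g = g * scale
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * g
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * (g * g)
            mhat = st["m"][k] / (1 - beta1 ** t)
            vhat = st["v"][k] / (1 - beta2 ** t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.params[k].dtype)

    def cross_entropy(self, X, Y) -> float:
        """Mean next-character cross-entropy (nats) without dropout."""
        logits, _ = self._forward(X)
        probs = self._softmax(logits)
        B, T = X.shape
        return float(-np.log(
            np.maximum(probs[np.arange(B)[:, None], np.arange(T)[None, :], Y], 1e-12)
        ).mean())

    def _run_epochs(self, corpus: EncodedCorpus, n_epochs, lr, rng, stage):
        cfg = self.config
        X, Y = corpus.windows()
        if X.shape[0] == 0:
            raise ValueError("corpus too short for a single training window")
        n = X.shape[0]
        # hold out a slice for monitoring; never trained on
        n_hold = max(1, n // 20) if n >= 5 else 0
        hold = (X[n - n_hold:], Y[n - n_hold:]) if n_hold else None
        n_train = n - n_hold
        for epoch in range(n_epochs):
            order = rng.permutation(n_train)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self._loss_and_grads(X[idx], Y[idx], train_rng=rng)
                self._adam_step(grads, lr)
                epoch_loss += loss
                n_batches += 1
            entry = {
                "stage": stage,
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
            }
            if hold is not None:
                entry["holdout_loss"] = self.cross_entropy(*hold)
            self.loss_trace.append(entry)
            logger.info("%s epoch %d: %s", stage, epoch, entry)

    def train(self, corpus: EncodedCorpus, n_epochs: int | None = None) -> "GeneratorModel":
        """Source-task training on the full encoded corpus."""
        if corpus.vocab.symbols != self.vocab.symbols:
            raise ValueError("corpus vocabulary does not match the model")
        rng = np.random.default_rng(self.config.seed + 1)
        self._run_epochs(corpus, n_epochs or self.config.n_epochs,
                         self.config.learning_rate, rng, stage="train")
        return self

    def fine_tune(self, selected: list[str], seed: int | None = None) -> "GeneratorModel":
        """Target-task retraining on selected molecules (transfer learning).

        The selected strings are re-encoded with the ORIGINAL vocabulary;
        molecules containing characters the model has never seen are skipped
        with a warning rather than crashing the cycle.
        """
        from molcycle import corpus as corpus_mod

        if not selected:
            raise ValueError("fine-tuning requires a non-empty selection")
        usable = []
        symbols = set(self.vocab.symbols)
        for s in selected:
            if set(s) <= symbols:
                usable.append(s)
            else:
                logger.warning("skipping molecule with out-of-vocabulary characters: %r", s)
        if not usable:
            raise ValueError("no selected molecule is encodable with the model vocabulary")
        enc = corpus_mod.encode(usable, self.vocab, self.config.window_length)
        rng = np.random.default_rng(self.config.seed + 2 if seed is None else seed)
        self._run_epochs(enc, self.config.fine_tune_epochs,
                         self.config.effective_fine_tune_lr, rng, stage="fine_tune")
        return self

    # ------------------------------------------------------------- sampling

    def _step(self, x_idx: np.ndarray, states):
        """One sampling step for a batch of chains; returns probs, new states."""
        cfg = self.config
        H, V = cfg.hidden_size, cfg.vocab_size
        inp = one_hot(x_idx, V).astype(self.params["by"].dtype)
        new_states = []
        for layer in range(cfg.n_layers):
            Wx, Wh, b = (self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                         self.params[f"b{layer}"])
            h, c = states[layer]
            z = inp @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            new_states.append((h, c))
            inp = h
        logits = inp @ self.params["Wy"] + self.params["by"]
        return self._softmax(logits), new_states

    def sample_molecules(
        self, n_chars: int, seed: int, n_chains: int = 64
    ) -> tuple[list[str], int]:
        """Sample complete molecules until at least ``n_chars`` characters.

        Runs ``n_chains`` molecules in parallel; each chain starts at the
        ``G`` symbol with zeroed states, draws the next symbol from the
        softmax distribution (temperature 1), and finishes at ``\\n``.
        Chains exceeding ``max_sample_length`` characters are discarded and
        restarted.  Returns (molecules, n_discarded_overlong); the emitted
        stream (molecules joined by the end symbol) has at least ``n_chars``
        characters unless the model pathologically never produces the end
        symbol, in which case a hard cap on total sampled tokens stops the
        loop.
        """
        cfg = self.config
        rng = np.random.default_rng(seed)
        H, V = cfg.hidden_size, cfg.vocab_size
        g_idx, nl_idx = self.vocab.start_index, self.vocab.end_index

        dtype = self.params["by"].dtype

        def fresh_states():
            return [(np.zeros((n_chains, H), dtype=dtype),
                     np.zeros((n_chains, H), dtype=dtype))
                    for _ in range(cfg.n_layers)]

        states = fresh_states()
        x = np.full(n_chains, g_idx, dtype=np.int64)
        bufs: list[list[str]] = [[] for _ in range(n_chains)]
        done = np.zeros(n_chains, dtype=bool)  # chains idle after quota is met
        molecules: list[str] = []
        n_discarded = 0
        emitted = 0  # characters in completed molecules, delimiters included
        sampled_tokens = 0
        token_cap = 10 * n_chars + 1000  # stop even if "\n" never appears
        while True:
            probs, states = self._step(x, states)
            # inverse-CDF multinomial draw, vectorized across chains
            u = rng.random((n_chains, 1))
            nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
            np.clip(nxt, 0, V - 1, out=nxt)
            for j in range(n_chains):
                if done[j]:
                    continue
                sampled_tokens += 1
                quota_met = emitted >= n_chars or sampled_tokens >= token_cap
                tok = int(nxt[j])
                if tok == nl_idx:
                    molecules.append("".join(bufs[j]))
                    emitted += len(bufs[j]) + 1
                    bufs[j] = []
                    nxt[j] = g_idx
                    self._reset_chain(states, j)
                    done[j] = emitted >= n_chars
                elif tok == g_idx:
                    # a stray start symbol mid-molecule: treat as delimiter noise
                    bufs[j] = []
                    self._reset_chain(states, j)
                    done[j] = quota_met
                else:
                    bufs[j].append(self.vocab.symbols[tok])
                    if len(bufs[j]) > cfg.max_sample_length:
                        n_discarded += 1
                        bufs[j] = []
                        nxt[j] = g_idx
                        self._reset_chain(states, j)
                        done[j] = quota_met
            if done.all():
                break
            x = nxt
        return molecules, n_discarded

    @staticmethod
    def _reset_chain(states, j):
        for h, c in states:
            h[j] = 0.0
            c[j] = 0.0

    def sample_characters(self, n_chars: int, seed: int, n_chains: int = 64) -> str:
        """Raw sampled character stream of length >= n_chars (molecules
        joined by the end symbol)."""
        molecules, _ = self.sample_molecules(n_chars, seed, n_chains)
        return "\n".join(molecules) + "\n"

    def mean_log_likelihood(self, molecules: list[str]) -> float:
        """Mean per-character log-likelihood of G+molecule+\\n sequences."""
        total_lp = 0.0
        total_n = 0
        for s in molecules:
            idx = np.concatenate((
                [self.vocab.start_index],
                self.vocab.encode_string(s),
                [self.vocab.end_index],
            ))
            X = idx[None, :-1]
            Y = idx[None, 1:]
            ce = self.cross_entropy(X, Y)
            total_lp += -ce * (len(idx) - 1)
            total_n += len(idx) - 1
        return total_lp / total_n

    # ---------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Checkpoint: weights plus embedded config and vocabulary."""
        meta = {"config": asdict(self.config), "vocab": self.vocab.to_json()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        vocab = TokenVocabulary.from_json(meta["vocab"])
        cfg_dict = meta["config"]
        model = cls(GeneratorConfig(**cfg_dict), vocab)
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(config: GeneratorConfig, vocab: TokenVocabulary) -> GeneratorModel:
    """Construct an untrained generator for a vocabulary."""
    return GeneratorModel(config, vocab)
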