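"""The multi-granular autoregressive record model.

Two modules factorize the probability of a record matrix:

1. A causal transformer *history encoder* maps the sequence of (optionally
   payload-augmented) visit vectors to per-timestep summaries
   ``H = [h_0 .. h_T]``: embed each row with a code-embedding matrix plus a
   learned positional embedding, then pass through ``M`` decoder blocks
   (masked multi-head self-attention with residual + layer norm, then a
   ReLU feed-forward with residual + layer norm).
2. A *masked-linear head* predicts the next row one code at a time:
   ``concat(h_t, v_{t+1})`` flows through ``N`` square masked linear layers
   (ReLU between layers, none at the last) and the code block of the output
   is read through a sigmoid, so output ``i`` is
   ``P(c_i = 1 | h_t, c_1..c_{i-1})``.

The mask gives every output full visibility of the history block, while the
code block is strictly lower-than-``i`` at the first layer and inclusive
afterwards — the leak-free reading of an "upper triangular" mask when more
than one layer is stacked (an inclusive first layer would let code ``i``
see its own target). The ``inclusive`` variant is selectable for ablation.

A record always enters the encoder behind an all-zero dummy first row, so
``h_0`` (the empty history) predicts the first visit and generation from
scratch has a start state. The stop code occupies the final column; the
training target for the row after the last visit is the all-zero sentinel
row with stop = 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .records import CodeVocabulary, encode_record

__all__ = ["ModelConfig", "MediSim", "head_masks"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``desk`` profile (default) keeps training on a single CPU in the
    minutes range; the ``full`` profile carries the full-scale depth.
    """

    nemb: int = 64
    n_blocks: int = 2
    n_heads: int = 4
    ff_mult: int = 4
    n_head_layers: int = 2
    max_visits: int = 11          # maximum number of real visits
    ln_eps: float = 1e-5
    head_mask: str = "leak_free"  # or "inclusive" (ablation)
    positional: str = "learned"   # or "sinusoidal"
    seed: int = 0

    @classmethod
    def profile(cls, name: str, **overrides) -> "ModelConfig":
        if name == "desk":
            base = {}
        elif name == "full":
            base = {"nemb": 768, "n_blocks": 12, "n_heads": 12}
        else:
            raise ValueError(f"unknown profile {name!r}")
        base.update(overrides)
        return cls(**base)


def head_masks(nemb: int, total_size: int, n_layers: int,
               mode: str = "leak_free") -> list:
    """Autoregressive masks for the square masked linear layers.

    Entry ``[b, a]`` gates the weight from input dim ``b`` to output dim
    ``a``. History dims (the first ``nemb``) are visible to every output
    and receive only history. On the code block the first layer is strictly
    upper triangular (``leak_free``) or inclusive (``inclusive``); later
    layers are always inclusive.
    """
    if mode not in ("leak_free", "inclusive"):
        raise ValueError(f"unknown head mask mode {mode!r}")
    width = nemb + total_size
    deg = np.concatenate([np.zeros(nemb), np.arange(1, total_size + 1)])
    masks = []
    for layer in range(n_layers):
        strict = (layer == 0 and mode == "leak_free")
        din, dout = deg[:, None], deg[None, :]
        m = np.where(din == 0, 1.0,
                     np.where(dout > din if strict else dout >= din, 1.0, 0.0))
        masks.append(m)
    return masks


def _sinusoidal(n_pos: int, nemb: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(nemb // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / nemb))
    out = np.zeros((n_pos, nemb))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out


class MediSim:
    """Estimator-style facade over the encoder + head parameter set.

    Follows the scikit-learn calling conventions where they apply:
    ``get_params``/``set_params`` over the constructor arguments, ``fit``
    (delegating to :mod:`medisim.training`), ``score`` returning the mean
    log-likelihood per present code (higher is better). Fitted state is the
    parameter dict ``params_``, initialised at construction so an untrained
    model is still a usable (random) generator.
    """

    def __init__(self, vocab: CodeVocabulary, config: ModelConfig | None = None,
                 codecs=()):
        self.vocab = vocab
        self.config = config or ModelConfig()
        self.codecs = list(codecs)
        self._init_params()

    # -- sklearn-ish surface ----------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"vocab": self.vocab, "config": self.config,
                "codecs": list(self.codecs)}

    def set_params(self, **kwargs) -> "MediSim":
        rebuild = False
        for k, v in kwargs.items():
            if k not in ("vocab", "config", "codecs"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k if k != "codecs" else "codecs",
                    list(v) if k == "codecs" else v)
            rebuild = True
        if rebuild:
            self._init_params()
        return self

    def fit(self, train_records, val_records=None, train_config=None):
        from .training import TrainConfig, fit
        fit(self, train_records, val_records or train_records,
            train_config or TrainConfig())
        return self

    def score(self, records) -> float:
        total_ll, total_n = 0.0, 0
        for record in records:
            ll, n = self.record_log_likelihood(record)
            total_ll += ll
            total_n += n
        return total_ll / max(total_n, 1)

    # -- parameters --------------------------------------------------------
    @property
    def total_size(self) -> int:
        return self.vocab.total_size

    @property
    def payload_width(self) -> int:
        return sum(c.width for c in self.codecs)

    @property
    def input_width(self) -> int:
        return self.total_size + self.payload_width

    @property
    def head_width(self) -> int:
        return self.config.nemb + self.total_size

    @property
    def n_positions(self) -> int:
        # dummy row + up to max_visits real rows + sentinel row
        return self.config.max_visits + 2

    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        scale = 0.02

        def normal(*shape):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        p = {}
        p["We"] = normal(self.input_width, cfg.nemb)
        if cfg.positional == "learned":
            p["Wp"] = normal(self.n_positions, cfg.nemb)
        else:
            p["Wp"] = Tensor(_sinusoidal(self.n_positions, cfg.nemb))
        for m in range(cfg.n_blocks):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"blk{m}.{w}"] = normal(cfg.nemb, cfg.nemb)
            p[f"blk{m}.ln1.g"] = Tensor(np.ones(cfg.nemb), requires_grad=True)
            p[f"blk{m}.ln1.b"] = Tensor(np.zeros(cfg.nemb), requires_grad=True)
            p[f"blk{m}.W"] = normal(cfg.nemb, cfg.ff_mult * cfg.nemb)
            p[f"blk{m}.b"] = Tensor(np.zeros(cfg.ff_mult * cfg.nemb),
                                    requires_grad=True)
            p[f"blk{m}.V"] = normal(cfg.ff_mult * cfg.nemb, cfg.nemb)
            p[f"blk{m}.c"] = Tensor(np.zeros(cfg.nemb), requires_grad=True)
            p[f"blk{m}.ln2.g"] = Tensor(np.ones(cfg.nemb), requires_grad=True)
            p[f"blk{m}.ln2.b"] = Tensor(np.zeros(cfg.nemb), requires_grad=True)
        for n in range(cfg.n_head_layers):
            p[f"head{n}.W"] = normal(self.head_width, self.head_width)
            p[f"head{n}.b"] = Tensor(np.zeros(self.head_width),
                                     requires_grad=True)
        for codec in self.codecs:
            for name, arr in codec.init_params(rng).items():
                p[f"codec.{codec.name}.{name}"] = Tensor(arr, requires_grad=True)
        self.params_ = p
        self._head_masks = head_masks(cfg.nemb, self.total_size,
                                      cfg.n_head_layers, cfg.head_mask)

    def trainable_params(self) -> dict:
        return {k: v for k, v in self.params_.items() if v.requires_grad}

    # -- forward passes -----------------------------------------------------
    def summarize_history(self, x) -> Tensor:
        """Per-timestep history summaries for input rows ``x``.

        ``x``: array or Tensor of shape (..., T, input_width); row ``t``'s
        summary depends on rows ``<= t`` only (causal attention).
        """
        cfg = self.config
        p = self.params_
        x = ad.as_tensor(x)
        T = x.shape[-2]
        if T > self.n_positions:
            raise ValueError(f"sequence of {T} rows exceeds the "
                             f"{self.n_positions} supported positions")
        if x.shape[-1] != self.input_width:
            raise ValueError(
                f"input width {x.shape[-1]} != expected {self.input_width}")
        h = ad.matmul(x, p["We"]) + p["Wp"][:T]
        causal = np.where(np.tril(np.ones((T, T))) > 0, 0.0, -1e9)
        dk = cfg.nemb // cfg.n_heads
        for m in range(cfg.n_blocks):
            q, k, v = (ad.matmul(h, p[f"blk{m}.{w}"]) for w in ("Wq", "Wk", "Wv"))

            def split(t):
                # (..., T, nemb) -> (..., heads, T, dk)
                new = t.reshape(t.shape[:-1] + (cfg.n_heads, dk))
                return new.swapaxes(-3, -2)

            qh, kh, vh = split(q), split(k), split(v)
            scores = ad.matmul(qh, kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk)) + causal
            attn = ad.matmul(ad.softmax(scores, axis=-1), vh)
            merged = attn.swapaxes(-3, -2)
            merged = merged.reshape(merged.shape[:-2] + (cfg.nemb,))
            h1 = h + ad.matmul(merged, p[f"blk{m}.Wo"])
            h2 = ad.layer_norm(h1, p[f"blk{m}.ln1.g"], p[f"blk{m}.ln1.b"],
                               eps=cfg.ln_eps)
            ff = ad.matmul(ad.relu(ad.matmul(h2, p[f"blk{m}.W"]) + p[f"blk{m}.b"]),
                           p[f"blk{m}.V"]) + p[f"blk{m}.c"]
            h = ad.layer_norm(h2 + ff, p[f"blk{m}.ln2.g"], p[f"blk{m}.ln2.b"],
                              eps=cfg.ln_eps)
        return h

    def head_logits(self, h, next_rows) -> Tensor:
        """Masked-linear head: logits over the code block.

        ``h``: (..., nemb) history summaries; ``next_rows``: (..., total_size)
        the (partially completed or teacher-forced) next visit rows.
        """
        z = ad.concat([ad.as_tensor(h), ad.as_tensor(next_rows)], axis=-1)
        n_layers = self.config.n_head_layers
        for n in range(n_layers):
            w = self.params_[f"head{n}.W"] * self._head_masks[n]
            z = ad.matmul(z, w) + self.params_[f"head{n}.b"]
            if n < n_layers - 1:
                z = ad.relu(z)
        return z[..., self.config.nemb:]

    def next_code_probabilities(self, h: np.ndarray,
                                partial_visit: np.ndarray) -> np.ndarray:
        """P(c_i = 1 | h, c_1..c_{i-1}) for all i simultaneously."""
        partial_visit = np.asarray(partial_visit, dtype=float)
        if partial_visit.shape[-1] != self.total_size:
            raise ValueError("partial visit has wrong width")
        if ((partial_visit < 0) | (partial_visit > 1)).any():
            raise ValueError("partial visit entries must lie in [0, 1]")
        with ad.no_grad():
            logits = self.head_logits(h, partial_visit)
        return ad._sigmoid(logits.data)

    # -- teacher-forced record pass -----------------------------------------
    def batch_arrays(self, records):
        """Pad a list of records/matrices into aligned input/target arrays.

        Returns ``(x_codes, payloads, targets, row_mask)`` where
        ``x_codes``: (B, R, total_size) encoder input rows (dummy + visits),
        ``payloads``: list (length B) of per-visit payload dict lists,
        ``targets``: (B, R, total_size) rows to predict (visits + sentinel),
        ``row_mask``: (B, R) 1.0 for rows inside the record.
        """
        mats = [m if hasattr(m, "values")
                else encode_record(m, self.vocab,
                                   max_visits=self.config.max_visits + 1)
                for m in records]
        B = len(mats)
        R = max(m.values.shape[0] for m in mats)
        x_codes = np.zeros((B, R, self.total_size))
        targets = np.zeros((B, R, self.total_size))
        row_mask = np.zeros((B, R))
        payloads = []
        for b, m in enumerate(mats):
            rows = m.values.astype(float)
            T1 = rows.shape[0]          # T visits + sentinel
            x_codes[b, 1:T1] = rows[:-1]  # dummy row 0 stays zero
            targets[b, :T1] = rows
            row_mask[b, :T1] = 1.0
            payloads.append(m.payloads or [{} for _ in range(T1 - 1)])
        return x_codes, payloads, targets, row_mask

    def encoder_input(self, x_codes: np.ndarray, payloads) -> Tensor:
        """Append codec payload embeddings to the code rows (Eq-5-style concat)."""
        if not self.codecs:
            return ad.as_tensor(x_codes)
        parts = [ad.as_tensor(x_codes)]
        B, R = x_codes.shape[:2]
        for codec in self.codecs:
            # per-record payload lists are aligned to visits (input row t is
            # visit t, rows 0 and padding carry no payload)
            grid = [[None] * R for _ in range(B)]
            for b in range(B):
                for t, pl in enumerate(payloads[b]):
                    if codec.name in pl and t + 1 < R:
                        grid[b][t + 1] = pl[codec.name]
            prefix = f"codec.{codec.name}."
            cparams = {k[len(prefix):]: v for k, v in self.params_.items()
                       if k.startswith(prefix)}
            parts.append(codec.embed_batch(grid, cparams))
        return ad.concat(parts, axis=-1)

    def record_logits(self, records):
        """Teacher-forced logits for a batch. Returns (logits, targets, mask)."""
        x_codes, payloads, targets, row_mask = self.batch_arrays(records)
        x = self.encoder_input(x_codes, payloads)
        h = self.summarize_history(x)
        logits = self.head_logits(h, targets)
        return logits, targets, row_mask

    def predict_record_probs(self, record) -> np.ndarray:
        """Teacher-forced per-position probabilities, (T+1, total_size)."""
        with ad.no_grad():
            logits, _, _ = self.record_logits([record])
        return ad._sigmoid(logits.data[0])

    def record_log_likelihood(self, record, eps: float = 1e-12):
        """(total log-likelihood, N_present) of one record, teacher-forced.

        The likelihood multiplies Bernoulli terms over *all* code positions
        up to and including the sentinel row; N_present counts the 1-entries
        (the stop event included).
        """
        mat = record if hasattr(record, "values") else encode_record(
            record, self.vocab, max_visits=self.config.max_visits + 1)
        probs = self.predict_record_probs(mat)
        y = mat.values.astype(float)
        ll, _ = ad.log_bernoulli(probs, y, eps=eps)
        return float(ll.sum()), int(y.sum())

    # -- persistence --------------------------------------------------------
    def save(self, path):
        header = {
            "config": asdict(self.config),
            "vocab": self.vocab.to_dict(),
            "codecs": [c.spec() for c in self.codecs],
        }
        arrays = {k: v.data for k, v in self.params_.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.frombuffer(
                json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, codec_registry=None):
        from .bridge import codec_from_spec
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__header__"}
        vocab = CodeVocabulary.from_dict(header["vocab"])
        config = ModelConfig(**header["config"])
        registry = codec_registry or codec_from_spec
        codecs = [registry(spec) for spec in header["codecs"]]
        model = cls(vocab, config, codecs=codecs)
        for k, arr in arrays.items():
            model.params_[k].data = arr.astype(np.float64)
        return model
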