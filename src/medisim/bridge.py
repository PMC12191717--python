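"""Encoder/generator codec pairs for complex per-visit payloads.

A codec couples the record model to one complex modality: ``embed`` maps a
payload to a fixed-width vector that is concatenated to the visit's
multi-hot row before the history encoder's embedding layer (so the code
embedding matrix simply grows by the codec width), and ``generate`` maps a
completed structured visit vector to a payload. Embedding parameters live
in the model's parameter dict under ``codec.<name>.*`` and train jointly
with the core model; missing payloads embed to a learned null vector.

The toy codecs here make the pathway testable at desk scale: a template
note codec over a small token vocabulary (each code present in the visit
emits its template token, plus uniform noise tokens) and a fixed-length
real-vector codec standing in for continuous embeddings such as imaging.
They are synthetic stand-ins, not language or image models. The
rule-based toy generators condition on the visit vector directly; the
trainable visit-conditioning map that a learned generator would consume is
the codec's embedding pathway itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ToyNoteCodec", "ToyVectorCodec", "ZeroCodec", "attach_codec",
           "detach_codec", "generate_payload", "annotate_cohort",
           "annotate_with_states", "codec_from_spec",
           "DownstreamSpec", "downstream_payload_eval"]


class ToyNoteCodec:
    """Note-like token sequences from a template grammar plus noise.

    ``generate`` emits, for every code present in the visit, its template
    token ``tok_<code>`` with probability ``template_prob``, then
    ``n_noise`` tokens drawn uniformly from ``noise_<0..n_noise_vocab-1>``.
    ``embed`` is a trainable linear map of the bag-of-tokens count vector.
    """

    def __init__(self, vocab, width: int = 8, template_prob: float = 1.0,
                 n_noise: int = 2, n_noise_vocab: int = 6,
                 name: str = "note"):
        self.name = name
        self.width = width
        self.template_prob = template_prob
        self.n_noise = n_noise
        self.n_noise_vocab = n_noise_vocab
        codes = (vocab.diagnosis_codes + vocab.procedure_codes
                 + vocab.medication_codes)
        self.token_vocab = ([f"tok_{c}" for c in codes]
                            + [f"noise_{i}" for i in range(n_noise_vocab)])
        self._tok_index = {t: i for i, t in enumerate(self.token_vocab)}

    def init_params(self, rng) -> dict:
        return {
            "Wemb": rng.normal(0, 0.1, (len(self.token_vocab), self.width)),
            "null": rng.normal(0, 0.1, self.width),
        }

    def token_counts(self, payload) -> np.ndarray:
        counts = np.zeros(len(self.token_vocab))
        for tok in payload:
            if tok not in self._tok_index:
                raise ValueError(f"token {tok!r} outside the codec vocabulary")
            counts[self._tok_index[tok]] += 1.0
        return counts

    def embed_batch(self, grid, params) -> Tensor:
        """(B, R) grid of payloads (``None`` = missing) -> (B, R, width)."""
        B, R = len(grid), len(grid[0])
        counts = np.zeros((B, R, len(self.token_vocab)))
        has = np.zeros((B, R, 1))
        for b in range(B):
            for t in range(R):
                if grid[b][t] is not None:
                    counts[b, t] = self.token_counts(grid[b][t])
                    has[b, t] = 1.0
        embedded = ad.matmul(ad.as_tensor(counts), params["Wemb"])
        return embedded * has + params["null"] * (1.0 - has)

    def generate(self, visit_row: np.ndarray, vocab, rng) -> list:
        tokens = []
        for i in np.nonzero(np.asarray(visit_row)[:vocab.stop_index] > 0.5)[0]:
            if rng.random() < self.template_prob:
                tokens.append(f"tok_{vocab.code_at(int(i))}")
        for _ in range(self.n_noise):
            tokens.append(f"noise_{rng.integers(self.n_noise_vocab)}")
        return tokens

    def spec(self) -> dict:
        return {"kind": "toy_note", "name": self.name, "width": self.width,
                "template_prob": self.template_prob, "n_noise": self.n_noise,
                "n_noise_vocab": self.n_noise_vocab,
                "token_vocab": list(self.token_vocab)}


class ToyVectorCodec:
    """Fixed-length real-vector payloads (continuous-embedding surrogate)."""

    def __init__(self, dim: int = 6, width: int = 4, noise_scale: float = 0.1,
                 name: str = "vector"):
        self.name = name
        self.dim = dim
        self.width = width
        self.noise_scale = noise_scale

    def init_params(self, rng) -> dict:
        return {"Wemb": rng.normal(0, 0.1, (self.dim, self.width)),
                "null": rng.normal(0, 0.1, self.width)}

    def embed_batch(self, grid, params) -> Tensor:
        B, R = len(grid), len(grid[0])
        vecs = np.zeros((B, R, self.dim))
        has = np.zeros((B, R, 1))
        for b in range(B):
            for t in range(R):
                if grid[b][t] is not None:
                    v = np.asarray(grid[b][t], dtype=float)
                    if v.shape != (self.dim,):
                        raise ValueError(f"payload must have length {self.dim}")
                    vecs[b, t] = v
                    has[b, t] = 1.0
        embedded = ad.matmul(ad.as_tensor(vecs), params["Wemb"])
        return embedded * has + params["null"] * (1.0 - has)

    def generate(self, visit_row: np.ndarray, vocab, rng) -> list:
        base = np.asarray(visit_row, dtype=float)[:vocab.stop_index]
        out = np.zeros(self.dim)
        n = min(self.dim, base.size)
        out[:n] = base[:n]
        out = out + rng.normal(0, self.noise_scale, self.dim)
        return out.tolist()

    def spec(self) -> dict:
        return {"kind": "toy_vector", "name": self.name, "dim": self.dim,
                "width": self.width, "noise_scale": self.noise_scale}


class ZeroCodec:
    """Information-free codec: embeds everything (and missing) to zero.

    Used to check the null-extension property — attaching it leaves the
    history summaries of payload-free records bit-identical.
    """

    def __init__(self, width: int = 4, name: str = "zero"):
        self.name = name
        self.width = width

    def init_params(self, rng) -> dict:
        return {}

    def embed_batch(self, grid, params) -> Tensor:
        return ad.as_tensor(np.zeros((len(grid), len(grid[0]), self.width)))

    def generate(self, visit_row, vocab, rng):
        return []

    def spec(self) -> dict:
        return {"kind": "zero", "name": self.name, "width": self.width}


def codec_from_spec(spec: dict):
    kind = spec.get("kind")
    if kind == "toy_note":
        # reconstructed from the stored token vocabulary
        codec = ToyNoteCodec.__new__(ToyNoteCodec)
        codec.name = spec["name"]
        codec.width = spec["width"]
        codec.template_prob = spec["template_prob"]
        codec.n_noise = spec["n_noise"]
        codec.n_noise_vocab = spec["n_noise_vocab"]
        codec.token_vocab = list(spec["token_vocab"])
        codec._tok_index = {t: i for i, t in enumerate(codec.token_vocab)}
        return codec
    if kind == "toy_vector":
        return ToyVectorCodec(dim=spec["dim"], width=spec["width"],
                              noise_scale=spec["noise_scale"],
                              name=spec["name"])
    if kind == "zero":
        return ZeroCodec(width=spec["width"], name=spec["name"])
    raise ValueError(f"unknown codec kind {kind!r}")


def attach_codec(model, codec):
    """Return a new model with the codec attached.

    The history encoder's input width grows by ``codec.width``; all
    existing parameters are carried over unchanged, with the new embedding
    rows of ``We`` freshly initialised. The input model is untouched.
    """
    from .model import MediSim

    if any(c.name == codec.name for c in model.codecs):
        raise ValueError(f"codec {codec.name!r} already attached")
    new = MediSim(model.vocab, model.config, codecs=model.codecs + [codec])
    old_rows = model.input_width
    for k, p in model.params_.items():
        if k == "We":
            new.params_["We"].data[:old_rows] = p.data
        else:
            new.params_[k].data = p.data.copy()
    return new


def detach_codec(model, name: str):
    """Return a new model with the named codec removed (inverse of attach)."""
    from .model import MediSim

    keep, row_lo = [], model.vocab.total_size
    span = None
    offset = model.vocab.total_size
    for c in model.codecs:
        if c.name == name:
            span = (offset, offset + c.width)
        else:
            keep.append(c)
        offset += c.width
    if span is None:
        raise ValueError(f"no codec named {name!r}")
    new = MediSim(model.vocab, model.config, codecs=keep)
    rows = [i for i in range(model.input_width)
            if not (span[0] <= i < span[1])]
    prefix = f"codec.{name}."
    for k, p in model.params_.items():
        if k.startswith(prefix):
            continue
        if k == "We":
            new.params_["We"].data = p.data[rows].copy()
        else:
            new.params_[k].data = p.data.copy()
    return new


def generate_payload(codec, visit_vector, vocab, seed: int):
    """Seed-reproducible payload generation for one completed visit row."""
    rng = np.random.default_rng(seed)
    return codec.generate(np.asarray(visit_vector, dtype=float), vocab, rng)


def annotate_cohort(records, codec, vocab, seed: int = 0):
    """New records whose visits carry codec-generated payloads.

    The payload of each visit is drawn from the codec's generative grammar
    applied to that visit's code vector, so it is redundant with the codes
    (no extra predictive information enters the record).
    """
    from dataclasses import replace

    from .records import PatientRecord

    rng = np.random.default_rng(seed)
    out = []
    for record in records:
        visits = []
        for visit in record.visits:
            row = np.zeros(vocab.total_size)
            for code in visit.all_codes():
                row[vocab.index_of(code)] = 1.0
            payloads = dict(visit.payloads)
            payloads[codec.name] = codec.generate(row, vocab, rng)
            visits.append(replace(visit, payloads=payloads))
        out.append(PatientRecord(visits=visits, id=record.id))
    return out


def annotate_with_states(records, states, n_states: int,
                         noise_scale: float = 0.05, seed: int = 0,
                         name: str = "vector"):
    """Attach latent-state-revealing vector payloads (side information).

    Each visit gets a ``name`` payload of length ``n_states``: the one-hot
    vector of the generator's latent state at that visit plus Gaussian
    noise. Unlike :func:`annotate_cohort` payloads, these carry information
    the visit codes only reflect noisily, so a model reading them through a
    codec can genuinely predict the next visit better.
    """
    from dataclasses import replace

    from .records import PatientRecord

    rng = np.random.default_rng(seed)
    out = []
    for record, st in zip(records, states):
        if len(st) != len(record.visits):
            raise ValueError("one state per visit required")
        visits = []
        for visit, s in zip(record.visits, st):
            vec = np.zeros(n_states)
            vec[int(s)] = 1.0
            vec = vec + rng.normal(0, noise_scale, n_states)
            payloads = dict(visit.payloads)
            payloads[name] = vec.tolist()
            visits.append(replace(visit, payloads=payloads))
        out.append(PatientRecord(visits=visits, id=record.id))
    return out


# -- downstream payload-to-code evaluation ---------------------------------

@dataclass
class DownstreamSpec:
    codec_name: str = "note"
    target_region: str = "diagnosis"
    deficient_fraction: float = 0.25
    test_fraction: float = 0.25
    seed: int = 0
    C: float = 1.0


def _payload_xy(records, codec, vocab, region: str):
    sl = vocab.region_slice(region)
    codes = [vocab.code_at(i) for i in range(sl.start, sl.stop)]
    X, Y = [], []
    for record in records:
        for visit in record.visits:
            payload = visit.payloads.get(codec.name)
            if payload is None:
                continue
            X.append(codec.token_counts(payload))
            Y.append([1.0 if c in visit.codes(region) else 0.0 for c in codes])
    return np.asarray(X), np.asarray(Y)


def downstream_payload_eval(real_cohort, synthetic_cohort, codec, vocab,
                            spec: DownstreamSpec | None = None) -> dict:
    """Four-regime payload-to-code classification benchmark.

    Trains one logistic-regression classifier per target code on each of
    full-real, deficient-real (a random ``deficient_fraction`` subset),
    synthetic, and real+synthetic training data, and reports micro-F1 and
    micro-AUROC on a held-out real test split.
    """
    from sklearn.linear_model import LogisticRegression

    from .metrics import f1_score

    spec = spec or DownstreamSpec()
    rng = np.random.default_rng(spec.seed)
    real = list(real_cohort)
    order = rng.permutation(len(real))
    n_test = max(1, int(round(spec.test_fraction * len(real))))
    test = [real[i] for i in order[:n_test]]
    train = [real[i] for i in order[n_test:]]
    n_def = int(np.floor(spec.deficient_fraction * len(train)))
    deficient = [train[i] for i in rng.permutation(len(train))[:n_def]]
    regimes = {
        "full_real": train,
        "deficient_real": deficient,
        "synthetic": list(synthetic_cohort),
        "real_plus_synthetic": train + list(synthetic_cohort),
    }
    X_test, Y_test = _payload_xy(test, codec, vocab, spec.target_region)
    table = {}
    for regime, records in regimes.items():
        X, Y = _payload_xy(records, codec, vocab, spec.target_region)
        probs = np.zeros_like(Y_test)
        for j in range(Y_test.shape[1]):
            yj = Y[:, j]
            if yj.min() == yj.max():
                probs[:, j] = float(yj.mean())
                continue
            clf = LogisticRegression(C=spec.C, max_iter=1000)
            clf.fit(X, yj)
            probs[:, j] = clf.predict_proba(X_test)[:, 1]
        f1, counts = f1_score(probs, Y_test)
        auroc = _micro_auroc(probs, Y_test)
        table[regime] = {"f1": f1, "auroc": auroc, "counts": counts,
                         "n_train_records": len(records)}
    return table


def _micro_auroc(probs: np.ndarray, y: np.ndarray) -> float | None:
    from sklearn.metrics import roc_auc_score

    flat_y = y.ravel()
    if flat_y.min() == flat_y.max():
        return None
    return float(roc_auc_score(flat_y, probs.ravel()))
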