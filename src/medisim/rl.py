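"""Iterative self-supervised refinement with a discriminator reward.

Each iteration: (1) simulate a synthetic dataset the size of the real
training set from the dummy start state, (2) train a deliberately weak
recurrent real-vs-synthetic classifier on it from scratch (real records are
the positive class), (3) run REINFORCE, ascending the mean
log-probability x reward product over sampled batches with the reward
treated as a constant (no gradient flows through the classifier), and
(4) checkpoint on validation perplexity after every ``eval_interval``
steps, ending the run after ``patience`` consecutive non-improving checks.
The loop repeats until ``max_iterations`` or an iteration yields no
improvement at all. Because the best checkpoint is always restored, the
refined model's validation perplexity never exceeds the input model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .simulate import SamplerConfig, generate_from_scratch, sample_raw

__all__ = ["RewardModel", "RLConfig", "train_reward_model",
           "reinforce_step", "refine"]


class RewardModel:
    """Weak recurrent real-vs-synthetic classifier V: record -> (0, 1).

    A single small tanh recurrent layer over the multi-hot visit rows
    (sentinel included) with a sigmoid readout of the final hidden state.
    Capacity is deliberately limited so the reward captures coarse realism
    without overfitting the current generator.
    """

    def __init__(self, vocab, hidden_size: int = 16, seed: int = 0,
                 max_visits: int = 100):
        self.vocab = vocab
        self.hidden_size = hidden_size
        self.max_visits = max_visits
        rng = np.random.default_rng(seed)
        w = vocab.total_size
        s = 1.0 / np.sqrt(hidden_size)
        self.params_ = {
            "Wx": Tensor(rng.normal(0, s, (w, hidden_size)), requires_grad=True),
            "Wh": Tensor(rng.normal(0, s, (hidden_size, hidden_size)),
                         requires_grad=True),
            "bh": Tensor(np.zeros(hidden_size), requires_grad=True),
            "wo": Tensor(rng.normal(0, s, (hidden_size, 1)), requires_grad=True),
            "bo": Tensor(np.zeros(1), requires_grad=True),
        }

    def _batch(self, records):
        from .records import encode_record
        mats = [m.values if hasattr(m, "values")
                else encode_record(m, self.vocab,
                                   max_visits=self.max_visits).values
                for m in records]
        B = len(mats)
        R = max(m.shape[0] for m in mats)
        x = np.zeros((B, R, self.vocab.total_size))
        mask = np.zeros((B, R, 1))
        for b, m in enumerate(mats):
            x[b, :m.shape[0]] = m
            mask[b, :m.shape[0]] = 1.0
        return x, mask

    def logits(self, records) -> Tensor:
        x, mask = self._batch(records)
        p = self.params_
        B, R = x.shape[:2]
        h = ad.as_tensor(np.zeros((B, self.hidden_size)))
        for t in range(R):
            new = ad.tanh(ad.matmul(ad.as_tensor(x[:, t]), p["Wx"])
                          + ad.matmul(h, p["Wh"]) + p["bh"])
            m = mask[:, t]
            h = new * m + h * (1.0 - m)   # frozen past the sentinel row
        return (ad.matmul(h, p["wo"]) + p["bo"])[:, 0]

    def value(self, records) -> np.ndarray:
        """V(record) in (0, 1) for each record."""
        with ad.no_grad():
            z = self.logits(records)
        return ad._sigmoid(z.data)

    def fit(self, real_records, synthetic_records, epochs: int = 5,
            lr: float = 1e-2, batch_size: int = 64, seed: int = 0,
            holdout_fraction: float = 0.2):
        """BCE training with real as the positive class.

        Sets ``holdout_accuracy_`` on a stratified held-out split and
        returns ``self``.
        """
        rng = np.random.default_rng(seed)

        def split(items):
            items = list(items)
            order = rng.permutation(len(items))
            k = max(1, int(round(holdout_fraction * len(items))))
            return ([items[i] for i in order[k:]],
                    [items[i] for i in order[:k]])

        real_tr, real_ho = split(real_records)
        syn_tr, syn_ho = split(synthetic_records)
        data = [(r, 1.0) for r in real_tr] + [(s, 0.0) for s in syn_tr]
        opt = Adam(self.params_, lr=lr)
        for _ in range(epochs):
            order = rng.permutation(len(data))
            for lo in range(0, len(data), batch_size):
                batch = [data[i] for i in order[lo:lo + batch_size]]
                records = [b[0] for b in batch]
                labels = np.array([b[1] for b in batch])
                opt.zero_grad()
                z = self.logits(records)
                loss = ad.bce_with_logits(z, labels).mean()
                loss.backward()
                opt.step()
        preds = np.concatenate([self.value(real_ho) >= 0.5,
                                self.value(syn_ho) < 0.5])
        self.holdout_accuracy_ = float(np.mean(preds))
        return self


@dataclass
class RLConfig:
    batch_size: int = 32        # B: records sampled per REINFORCE step
    eval_interval: int = 25     # v: steps between validation checks
    patience: int = 4           # p: non-improving checks ending a run
    max_iterations: int = 10
    max_steps_per_iteration: int = 200
    learning_rate: float = 1e-4
    reward_hidden_size: int = 16
    reward_epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.eval_interval, self.patience) < 1:
            raise ValueError("batch_size, eval_interval, patience must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


def train_reward_model(real_cohort, synthetic_cohort, vocab,
                       config: RLConfig | None = None,
                       max_visits: int = 100) -> RewardModel:
    """Fresh weak discriminator per iteration (GAN-style)."""
    config = config or RLConfig()
    if not real_cohort or not synthetic_cohort:
        raise ValueError("cohorts must be non-empty")
    rm = RewardModel(vocab, hidden_size=config.reward_hidden_size,
                     seed=config.seed, max_visits=max_visits)
    rm.fit(real_cohort, synthetic_cohort, epochs=config.reward_epochs,
           seed=config.seed)
    return rm


def record_log_prob_tensor(model, records):
    """Differentiable per-record log-likelihoods, shape (B,)."""
    logits, targets, row_mask = model.record_logits(records)
    weight = row_mask[..., None] * np.ones(model.total_size)
    nll = ad.bce_with_logits(logits, targets, weight=weight)
    return -nll.sum(axis=(-1, -2))


def reinforce_step(model, reward_model, batch_size: int, seed: int,
                   optimizer: Adam, temperature: float = 1.0):
    """One policy-gradient ascent step on E[log P(R') * V(R')].

    Samples ``batch_size`` records from scratch, scores them with the
    (constant) reward model, and ascends the gradient of the mean
    log-probability x reward product. The log-probability is taken over the
    raw sampled rows (terminal row as drawn, no sentinel appended to capped
    records), so it is exactly the log of the sampling probability — the
    score-function identity holds without bias. Returns a dict with the
    expected reward estimate and the mean reward of the batch.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    samples, raw = sample_raw(
        model, batch_size, SamplerConfig(seed=seed, temperature=temperature))
    values = reward_model.value(samples) if not callable(reward_model) \
        else np.asarray(reward_model(samples), dtype=float)
    optimizer.zero_grad()
    logp = record_log_prob_tensor(model, raw)
    objective = (logp * values).mean()
    loss = -objective
    loss.backward()
    optimizer.step()
    return {"expected_reward": float(objective.data),
            "mean_reward": float(values.mean()),
            "mean_log_prob": float(logp.data.mean())}


def refine(model, real_train, real_val, rl_config: RLConfig | None = None):
    """Full iterative refinement loop. Returns ``(model, log)``.

    ``log`` is a list of per-iteration dicts (reward-model held-out
    accuracy, step records, best validation perplexity). The model is left
    holding the best-validation-perplexity parameters observed anywhere in
    the loop, including the starting point.
    """
    from .evaluation import perplexity

    cfg = rl_config or RLConfig()
    params = model.trainable_params()
    best = {k: p.data.copy() for k, p in params.items()}
    best_pp = perplexity(model, real_val)
    log = []
    seed_seq = np.random.SeedSequence(cfg.seed)
    opt = Adam(params, lr=cfg.learning_rate)

    for iteration in range(cfg.max_iterations):
        it_seed = seed_seq.spawn(1)[0]
        gen_seed, rm_seed, *step_seeds = [
            int(s.generate_state(1)[0] % (2 ** 31))
            for s in it_seed.spawn(2 + cfg.max_steps_per_iteration)]
        synthetic = generate_from_scratch(
            model, len(real_train), SamplerConfig(seed=gen_seed))
        rm_cfg = RLConfig(**{**cfg.__dict__, "seed": rm_seed})
        reward_model = train_reward_model(
            real_train, synthetic, model.vocab, rm_cfg,
            max_visits=model.config.max_visits + 1)
        entry = {"iteration": iteration,
                 "reward_model_accuracy": reward_model.holdout_accuracy_,
                 "steps": [], "improved": False}
        bad_checks = 0
        for step in range(cfg.max_steps_per_iteration):
            rec = reinforce_step(model, reward_model, cfg.batch_size,
                                 step_seeds[step], opt)
            entry["steps"].append(rec)
            if (step + 1) % cfg.eval_interval == 0:
                pp = perplexity(model, real_val)
                if pp < best_pp:
                    best_pp = pp
                    best = {k: p.data.copy() for k, p in params.items()}
                    entry["improved"] = True
                    bad_checks = 0
                else:
                    bad_checks += 1
                if bad_checks >= cfg.patience:
                    break
        entry["best_val_perplexity"] = best_pp
        log.append(entry)
        # restore the running best before generating the next iteration's data
        for k, p in params.items():
            p.data = best[k].copy()
        if not entry["improved"]:
            break

    for k, p in params.items():
        p.data = best[k].copy()
    return model, log
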