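"""Evaluation metrics: micro-averaged F1 and present-code-normalized perplexity.

Perplexity here is the exponentiated negative log-likelihood of a cohort
normalized by the number of *present* medical codes (stop events included),
while the likelihood itself multiplies Bernoulli terms over all code
positions, present and absent, up to and including the sentinel row. The
normalizer choice changes numbers materially and is therefore exposed: the
``include_absent`` flag can drop the absent-code terms from the likelihood
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import log_bernoulli
from .records import encode_record

__all__ = ["MetricReport", "f1_score", "perplexity", "record_probs"]


@dataclass
class MetricReport:
    protocol: str
    perplexity: float | None = None
    f1: float | None = None
    auroc: float | None = None
    counts: dict = field(default_factory=dict)
    per_visit: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol, "perplexity": self.perplexity,
            "f1": self.f1, "auroc": self.auroc, "counts": self.counts,
            "per_visit": self.per_visit, "flags": self.flags,
        }


def f1_score(predicted, observed, threshold: float = 0.5):
    """Micro-averaged F1 = 2TP / (2TP + FP + FN) over all positions.

    ``predicted`` holds probabilities (thresholded at ``threshold``),
    ``observed`` binary outcomes; any matching shapes. Returns
    ``(f1, counts)``; a degenerate table with no positives anywhere is
    reported as F1 = 0 with a ``zero_positives`` flag in the counts.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel() > 0.5
    hard = p >= threshold
    tp = int(np.sum(hard & y))
    fp = int(np.sum(hard & ~y))
    fn = int(np.sum(~hard & y))
    counts = {"TP": tp, "FP": fp, "FN": fn, "N": int(p.size),
              "threshold": threshold}
    denom = 2 * tp + fp + fn
    if denom == 0:
        counts["zero_positives"] = True
        return 0.0, counts
    return 2.0 * tp / denom, counts


def record_probs(model, record) -> tuple:
    """(probs, values): teacher-forced probabilities and binary outcomes
    aligned over the T+1 matrix rows (sentinel included)."""
    if hasattr(record, "values"):
        mat = record
    else:
        max_rows = getattr(getattr(model, "config", None), "max_visits", None)
        mat = encode_record(record, model.vocab,
                            max_visits=(max_rows + 1) if max_rows else 10 ** 6)
    probs = np.asarray(model.predict_record_probs(mat), dtype=float)
    values = mat.values.astype(float)
    if probs.shape != values.shape:
        raise ValueError(f"model produced shape {probs.shape}, "
                         f"record has {values.shape}")
    return probs, values


def perplexity(model, records, include_absent: bool = True,
               form: str = "log", eps: float = 1e-12) -> float:
    """Cohort perplexity ``exp(-(1/N) * sum_R log P(R))``.

    ``form='log'`` accumulates log-probabilities (the numerically safe
    route); ``form='product'`` multiplies raw record probabilities and takes
    the ``-1/N`` power — usable only on small cohorts, kept to check the
    algebraic identity of the two definitions. Probabilities of realized
    outcomes are clamped at ``eps``; the number of clamped positions is
    recorded on the function attribute ``perplexity.last_clamped``.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort must be non-empty")
    total_ll, total_n, clamped = 0.0, 0, 0
    record_lls = []
    for record in records:
        probs, values = record_probs(model, record)
        ll, n_cl = log_bernoulli(probs, values, eps=eps)
        clamped += n_cl
        if not include_absent:
            ll = ll * (values > 0.5)
        record_lls.append(float(ll.sum()))
        total_ll += float(ll.sum())
        total_n += int(values.sum())
    perplexity.last_clamped = clamped
    if total_n == 0:
        raise ValueError("cohort has no present codes")
    if form == "log":
        return float(np.exp(-total_ll / total_n))
    if form == "product":
        prod = float(np.prod([np.exp(x) for x in record_lls]))
        return float(prod ** (-1.0 / total_n))
    raise ValueError(f"unknown form {form!r}")


perplexity.last_clamped = 0
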