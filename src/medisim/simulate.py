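"""Complete deficient records by sequential sampling.

Generation proceeds left to right along the temporal dimension, stopping at
any incomplete visit: the history of all completed visits is summarized,
then the visit vector is filled one code at a time by Bernoulli sampling
from the head's conditionals. Modality-deficient visits keep their observed
region prefix clamped; longitudinally deficient records grow new visits
after the observed prefix until the stop code fires or the visit cap is
reached; dual deficiency completes modalities first, then extends. Complex
payloads, when codecs are attached, are generated last for each visit and
feed the history of subsequent visits.

Observed content is never resampled: completed records agree with their
deficient input on every observed position.

The model object must provide ``vocab``, ``config.max_visits``,
``summarize_history`` / ``encoder_input`` and ``next_code_probabilities``
(duck-typed; trivial stub models are enough for the contract tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .records import (REGIONS, DeficientRecord, PatientRecord, Visit,
                      encode_record)

__all__ = ["SamplerConfig", "complete_record", "complete_batch",
           "generate_from_scratch", "sample_raw", "enrich_cohort"]


@dataclass
class SamplerConfig:
    seed: int = 0
    temperature: float = 1.0   # on head logits; 1.0 = plain Bernoulli
    max_visits: int | None = None  # override of the model's visit cap


class RegionOrderError(ValueError):
    """Observed regions are not a prefix of the model's region ordering."""


def _visit_to_row(visit: Visit, vocab) -> np.ndarray:
    row = np.zeros(vocab.total_size)
    for code in visit.all_codes():
        row[vocab.index_of(code)] = 1.0
    return row


def _row_to_visit(row: np.ndarray, vocab, payloads=None) -> Visit:
    sets = {r: set() for r in REGIONS}
    for i in np.nonzero(row[:vocab.stop_index])[0]:
        sets[vocab.region_of_index(int(i))].add(vocab.code_at(int(i)))
    return Visit(diagnosis=sets["diagnosis"], procedure=sets["procedure"],
                 medication=sets["medication"], payloads=payloads or {})


def _history_last(model, visit_lists) -> np.ndarray:
    """h after the last completed visit for each record (batched, padded)."""
    vocab = model.vocab
    B = len(visit_lists)
    R = max(len(v) for v in visit_lists) + 1  # dummy row in front
    x_codes = np.zeros((B, R, vocab.total_size))
    payloads = []
    for b, visits in enumerate(visit_lists):
        for t, visit in enumerate(visits):
            x_codes[b, t + 1] = _visit_to_row(visit, vocab)
        payloads.append([dict(v.payloads) for v in visits])
    if hasattr(model, "encoder_input"):
        x = model.encoder_input(x_codes, payloads)
    else:
        x = x_codes
    with ad.no_grad():
        h = model.summarize_history(x)
    if not isinstance(h, np.ndarray):   # autodiff Tensor
        h = h.data
    h = np.asarray(h)
    return np.stack([h[b, len(v)] for b, v in enumerate(visit_lists)])


def _apply_temperature(probs: np.ndarray, temperature: float) -> np.ndarray:
    if temperature == 1.0:
        return probs
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    logits = np.log(p / (1 - p)) / temperature
    with np.errstate(over="ignore"):   # saturates to the correct 0/1 limit
        return 1.0 / (1.0 + np.exp(-logits))


def _sample_rows(model, h: np.ndarray, init_rows: np.ndarray,
                 sample_mask: np.ndarray, rng, temperature: float) -> np.ndarray:
    """Sequentially sample the masked positions of a batch of visit rows."""
    rows = init_rows.astype(float).copy()
    total = model.vocab.total_size
    for i in range(total):
        need = sample_mask[:, i]
        if not need.any():
            continue
        probs = _apply_temperature(
            np.atleast_2d(model.next_code_probabilities(h, rows))[:, i],
            temperature)
        draws = (rng.random(rows.shape[0]) < probs).astype(float)
        rows[need, i] = draws[need]
    return rows


def _check_region_prefix(deficient: DeficientRecord, vocab):
    if deficient.observed_regions is None:
        return
    prefix = vocab.region_order[:len(deficient.observed_regions)]
    if tuple(deficient.observed_regions) != prefix:
        raise RegionOrderError(
            f"observed regions {deficient.observed_regions} must be a prefix "
            f"of the model's region ordering {vocab.region_order}")


def _generate_payloads(model, row: np.ndarray, existing: dict, rng) -> dict:
    payloads = dict(existing)
    for codec in getattr(model, "codecs", []):
        if codec.name not in payloads:
            payloads[codec.name] = codec.generate(row, model.vocab, rng)
    return payloads


def complete_batch(deficients, model, config: SamplerConfig | None = None):
    """Vectorized :func:`complete_record` over a batch of deficient records."""
    config = config or SamplerConfig()
    vocab = model.vocab
    rng = np.random.default_rng(config.seed)
    cap = config.max_visits or model.config.max_visits
    for d in deficients:
        _check_region_prefix(d, vocab)

    completed = [[] for _ in deficients]
    # phase 1: left to right over observed visits, filling missing regions
    n_obs = [len(d.record.visits) for d in deficients]
    for t in range(max(n_obs, default=0)):
        idx = [b for b in range(len(deficients)) if t < n_obs[b]]
        need_fill = [b for b in idx
                     if deficients[b].observed_regions is not None]
        rows = {b: _visit_to_row(deficients[b].record.visits[t], vocab)
                for b in idx}
        if need_fill:
            h = _history_last(model, [completed[b] for b in need_fill])
            init = np.stack([rows[b] for b in need_fill])
            mask = np.zeros_like(init, dtype=bool)
            for j, b in enumerate(need_fill):
                for region in vocab.region_order:
                    if region not in deficients[b].observed_regions:
                        mask[j, vocab.region_slice(region)] = True
            filled = _sample_rows(model, h, init, mask, rng, config.temperature)
            for j, b in enumerate(need_fill):
                rows[b] = filled[j]
        for b in idx:
            observed = deficients[b].record.visits[t]
            payloads = _generate_payloads(model, rows[b], observed.payloads, rng)
            completed[b].append(_row_to_visit(rows[b], vocab, payloads))

    # phase 2: temporal extension for longitudinal/dual deficiencies
    extend = [b for b, d in enumerate(deficients)
              if d.kind in ("longitudinal", "dual")]
    active = [b for b in extend if len(completed[b]) < cap]
    while active:
        h = _history_last(model, [completed[b] for b in active])
        init = np.zeros((len(active), vocab.total_size))
        mask = np.ones_like(init, dtype=bool)
        rows = _sample_rows(model, h, init, mask, rng, config.temperature)
        still = []
        for j, b in enumerate(active):
            if rows[j, vocab.stop_index] >= 0.5:
                continue  # sentinel sampled: the record ends here
            payloads = _generate_payloads(model, rows[j], {}, rng)
            completed[b].append(_row_to_visit(rows[j], vocab, payloads))
            if len(completed[b]) < cap:
                still.append(b)
        active = still

    return [PatientRecord(visits=completed[b], id=d.record.id)
            for b, d in enumerate(deficients)]


def complete_record(deficient: DeficientRecord, model,
                    config: SamplerConfig | None = None) -> PatientRecord:
    """Complete one deficient record (see module docstring for semantics)."""
    return complete_batch([deficient], model, config)[0]


def generate_from_scratch(model, n: int,
                          config: SamplerConfig | None = None) -> list:
    """Simulate ``n`` records from the all-zero dummy start state."""
    config = config or SamplerConfig()
    if n == 0:
        return []
    deficients = [DeficientRecord(
        record=PatientRecord(visits=[], id=f"g{i:06d}"), kind="longitudinal",
        observed_visits=0) for i in range(n)]
    # observed_visits=0 bypasses induce_deficiency validation on purpose: the
    # empty prefix is the dummy start state of from-scratch generation.
    return complete_batch(deficients, model, config)


def sample_raw(model, n: int, config: SamplerConfig | None = None):
    """From-scratch sampling that also returns the raw sampled rows.

    Returns ``(records, matrices)``. ``records`` are canonical
    :class:`PatientRecord` objects (terminal rows reduced to the pure stop
    sentinel). ``matrices[b]`` is a :class:`RecordMatrix` holding every row
    exactly as sampled: the terminal row keeps any code bits drawn before
    the stop bit, and records that hit the visit cap have no terminal row.
    The product of Bernoulli probabilities over every position of these raw
    rows is exactly the probability with which the sequence was sampled,
    which score-function (REINFORCE) gradients require; the canonicalized
    records do not have that property.
    """
    from .records import RecordMatrix

    config = config or SamplerConfig()
    vocab = model.vocab
    if n == 0:
        return [], []
    rng = np.random.default_rng(config.seed)
    cap = config.max_visits or model.config.max_visits
    visits = [[] for _ in range(n)]
    raw = [[] for _ in range(n)]
    active = list(range(n))
    while active:
        h = _history_last(model, [visits[b] for b in active])
        init = np.zeros((len(active), vocab.total_size))
        mask = np.ones_like(init, dtype=bool)
        rows = _sample_rows(model, h, init, mask, rng, config.temperature)
        still = []
        for j, b in enumerate(active):
            raw[b].append(rows[j].copy())
            if rows[j, vocab.stop_index] >= 0.5:
                continue   # terminal row sampled: the record ends here
            visits[b].append(_row_to_visit(rows[j], vocab))
            if len(visits[b]) < cap:
                still.append(b)
        active = still
    records = [PatientRecord(visits=v, id=f"g{i:06d}")
               for i, v in enumerate(visits)]
    matrices = [RecordMatrix(values=np.array(r), vocab=vocab)
                for r in raw]
    return records, matrices


def enrich_cohort(deficient_cohort, model, mode: str,
                  config: SamplerConfig | None = None):
    """Batch completion with provenance. ``mode``: temporal/modality/dual.

    ``deficient_cohort`` may hold :class:`DeficientRecord` items or plain
    records (then treated as deficient views of the given ``mode``:
    temporal records are prefixes to extend, modality records carry
    diagnosis codes only). Returns ``(completed_records, provenance)`` where
    provenance marks, per record, which visits and which codes within
    partially observed visits were simulated.
    """
    kind = {"temporal": "longitudinal", "modality": "modality",
            "dual": "dual"}.get(mode)
    if kind is None:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    deficients = []
    for item in deficient_cohort:
        if isinstance(item, DeficientRecord):
            deficients.append(item)
        else:
            regions = (model.vocab.region_order[:1]
                       if kind in ("modality", "dual") else None)
            record = item
            if regions is not None:
                # plain records are treated as deficient views: codes outside
                # the observed regions are stripped before completion
                from .records import _strip_regions
                record = PatientRecord(
                    visits=[_strip_regions(v, regions) for v in item.visits],
                    id=item.id)
            deficients.append(DeficientRecord(
                record=record, kind=kind,
                observed_visits=len(item.visits) if kind != "modality" else None,
                observed_regions=regions))
    completed = complete_batch(deficients, model, config)
    provenance = []
    for d, full in zip(deficients, completed):
        obs = d.record.visits
        simulated_visits = list(range(len(obs), len(full.visits)))
        simulated_codes = {}
        for t, visit in enumerate(obs):
            extra = sorted(full.visits[t].all_codes() - visit.all_codes())
            if extra:
                simulated_codes[t] = extra
        provenance.append({
            "id": full.id,
            "observed_visits": len(obs),
            "simulated_visits": simulated_visits,
            "simulated_codes": simulated_codes,
        })
    return completed, provenance
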