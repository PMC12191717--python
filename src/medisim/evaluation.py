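"""Evaluation protocols: temporal prediction, modality imputation, and the
downstream-enrichment benchmark.

``temporal_eval`` scores teacher-forced next-visit prediction (each visit
from its true predecessors, with within-visit autoregressive conditioning
active); ``modality_eval`` scores procedure+medication prediction with the
diagnoses clamped to their observed values, either teacher-forced (prior
visits fully observed) or sequential (prior visits' imputed regions carry
the model's own samples, so error can compound); and
``enrichment_benchmark`` measures whether completing deficient records
improves a downstream bag-of-codes phenotype classifier, against the
deficient data below and the real full data above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricReport, f1_score, perplexity, record_probs
from .records import encode_record, induce_deficiency
from .simulate import SamplerConfig, complete_batch
from .synthetic import PhenotypeRule, inject_noise, label_phenotype

__all__ = ["temporal_eval", "modality_eval", "EnrichmentSpec",
           "enrichment_benchmark", "perplexity", "f1_score"]


def temporal_eval(model, test_cohort, threshold: float = 0.5) -> MetricReport:
    """Teacher-forced next-visit prediction from the second visit onward.

    Visit t+1 (t >= 1) is predicted from visits 1..t; the first visit has
    no history and is excluded. The sentinel row (the stop decision) is
    included. Micro-F1 and perplexity pool every evaluated position; the
    per-visit-index breakdown reports F1 by 1-based target visit number.
    """
    all_p, all_y, by_visit = [], [], {}
    total_ll, total_n = 0.0, 0
    for record in test_cohort:
        probs, values = record_probs(model, record)
        for row in range(1, values.shape[0]):
            all_p.append(probs[row])
            all_y.append(values[row])
            by_visit.setdefault(row + 1, [[], []])
            by_visit[row + 1][0].append(probs[row])
            by_visit[row + 1][1].append(values[row])
            p = np.clip(probs[row], 1e-12, 1 - 1e-12)
            total_ll += float(np.where(values[row] > 0.5,
                                       np.log(p), np.log1p(-p)).sum())
            total_n += int(values[row].sum())
    if not all_p:
        raise ValueError("no record in the cohort has more than one visit")
    f1, counts = f1_score(np.array(all_p), np.array(all_y), threshold)
    per_visit = {k: f1_score(np.array(v[0]), np.array(v[1]), threshold)[0]
                 for k, v in sorted(by_visit.items())}
    return MetricReport(
        protocol="temporal", f1=f1, counts=counts,
        perplexity=float(np.exp(-total_ll / max(total_n, 1))),
        per_visit=per_visit)


def modality_eval(model, test_cohort, conditioning: str = "teacher_forced",
                  threshold: float = 0.5,
                  seed: int = 0) -> MetricReport:
    """Procedure+medication prediction with diagnoses clamped to observed.

    ``teacher_forced``: every prior visit (and the within-visit prefix) is
    ground truth. ``sequential``: earlier visits carry the model's own
    imputed procedure/medication codes, matching the left-to-right
    completion framework; within the evaluated visit the prefix is still
    ground truth so each position has a well-defined probability.
    """
    if conditioning not in ("teacher_forced", "sequential"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    vocab = model.vocab
    eval_slices = [vocab.region_slice(r) for r in ("procedure", "medication")]
    all_p, all_y = [], []
    total_ll, total_n = 0.0, 0
    rng = np.random.default_rng(seed)
    for record in test_cohort:
        mat = encode_record(record, vocab,
                            max_visits=model.config.max_visits + 1)
        if conditioning == "teacher_forced":
            probs, values = record_probs(model, mat)
        else:
            probs, values = _sequential_modality_probs(model, record, rng)
        for row in range(values.shape[0] - 1):  # real visits only
            for sl in eval_slices:
                all_p.append(probs[row, sl])
                all_y.append(values[row, sl])
                p = np.clip(probs[row, sl], 1e-12, 1 - 1e-12)
                total_ll += float(np.where(values[row, sl] > 0.5,
                                           np.log(p), np.log1p(-p)).sum())
                total_n += int(values[row, sl].sum())
    pred, obs = np.concatenate(all_p), np.concatenate(all_y)
    f1, counts = f1_score(pred, obs, threshold)
    pp = float(np.exp(-total_ll / total_n)) if total_n else None
    report = MetricReport(protocol=f"modality/{conditioning}", f1=f1,
                          counts=counts, perplexity=pp)
    if counts.get("zero_positives"):
        report.flags["zero_positives"] = True
    return report


def _sequential_modality_probs(model, record, rng):
    """Probabilities for px/rx positions with imputed prior visits."""
    import medisim.autodiff as ad

    vocab = model.vocab
    mat = encode_record(record, vocab, max_visits=model.config.max_visits + 1)
    values = mat.values.astype(float)
    T = mat.n_visits
    probs = np.zeros_like(values)
    from .records import Visit
    from .simulate import _history_last, _row_to_visit

    dx_sl = vocab.region_slice("diagnosis")
    history = []  # visits with true dx + imputed px/rx
    for t in range(T):
        h = _history_last(model, [history])
        true_row = values[t]
        # teacher-forced within-visit probabilities at every position
        probs[t] = model.next_code_probabilities(h, true_row[None])[0]
        # imputed version of this visit for subsequent conditioning
        init = np.zeros((1, vocab.total_size))
        init[0, dx_sl] = true_row[dx_sl]
        mask = np.zeros_like(init, dtype=bool)
        for r in ("procedure", "medication"):
            mask[0, vocab.region_slice(r)] = True
        from .simulate import _sample_rows
        sampled = _sample_rows(model, h, init, mask, rng, 1.0)
        history.append(_row_to_visit(sampled[0], vocab))
    # sentinel row probabilities (not evaluated, kept for shape parity)
    h = _history_last(model, [history])
    probs[T] = model.next_code_probabilities(h, values[T][None])[0]
    return probs, values


@dataclass
class EnrichmentSpec:
    """Three-regime downstream benchmark configuration.

    The regimes are three *training* datasets for the same downstream task
    — deficient, enriched (deficient completed by the model), and full real
    — evaluated on one common held-out real test cohort with real labels.
    The label is: target diagnosis present in visits ``k+1 .. k+horizon``
    (1-based). Training labels for the deficient and full regimes come from
    the real records; the enriched regime's labels come from its own
    completed records, because the real continuation is exactly what is
    missing in the enrichment setting. Features are bag-of-code counts over
    the first ``k + horizon`` visits. The target diagnosis is excluded
    from the feature bag by default so the full-data ceiling reflects the
    temporal signal rather than reading the label off its own window.
    """

    rules: tuple = ()
    k: int = 5                   # observed prefix length
    horizon: int = 5             # label window: visits k+1 .. k+horizon
    n_bootstrap: int = 100
    noise: bool = False          # downstream noise knob (modality benchmark)
    exclude_target_feature: bool = True
    mode: str = "temporal"       # or "modality"
    seed: int = 0


def _bag_of_codes(records, vocab, upto: int) -> np.ndarray:
    X = np.zeros((len(records), vocab.stop_index))
    for i, record in enumerate(records):
        for visit in record.visits[:upto]:
            for code in visit.all_codes():
                X[i, vocab.index_of(code)] += 1.0
    return X


def enrichment_benchmark(train_cohort, test_cohort, model, vocab,
                         spec: EnrichmentSpec,
                         simulator=None) -> dict:
    """Train a bag-of-codes classifier per phenotype rule on each regime.

    Regimes (training data only — all are scored on the real ``test_cohort``):
    ``deficient`` (the truncated / diagnosis-only training records),
    ``enriched`` (the same records completed by the model), and ``full``
    (the untouched real training records, the performance ceiling).
    ``simulator`` overrides the completion callable for oracle controls: it
    receives the deficient records and must return completed ones. Returns
    ``{rule_name: {regime: {f1, ci_low, ci_high}}}`` with percentile
    bootstrap CIs over ``n_bootstrap`` test resamples.
    """
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(spec.seed)
    upto = spec.k + spec.horizon

    def deficient_view(records):
        if spec.mode == "temporal":
            # records with more than k visits lose their continuation; shorter
            # records were observed to terminate, so they are not deficient
            return [induce_deficiency(r, "longitudinal",
                                      observed_visits=spec.k)
                    if len(r.visits) > spec.k
                    else induce_deficiency(r, "none")
                    for r in records]
        if spec.mode == "modality":
            return [induce_deficiency(r, "modality",
                                      observed_regions=("diagnosis",),
                                      vocab=vocab)
                    for r in records]
        raise ValueError(f"unknown mode {spec.mode!r}")

    def default_sim(defs):
        return complete_batch(defs, model,
                              SamplerConfig(seed=int(rng.integers(2 ** 31))))

    sim = simulator or default_sim
    train_def = deficient_view(train_cohort)
    regimes = {
        "deficient": [d.record for d in train_def],
        "enriched": sim(train_def),
        "full": list(train_cohort),
    }
    test_records = list(test_cohort)
    if spec.noise:
        regimes = {name: [inject_noise(r, vocab, rng) for r in records]
                   for name, records in regimes.items()}
        test_records = [inject_noise(r, vocab, rng) for r in test_records]

    table = {}
    for rule in spec.rules:
        y_test = np.array([label_phenotype(r, rule) for r in test_cohort])
        drop = ([vocab.index_of(rule.target_diagnosis)]
                if spec.exclude_target_feature else [])
        cols = [i for i in range(vocab.stop_index) if i not in drop]
        name = f"{rule.target_diagnosis}@{rule.window_start}-{rule.window_end}"
        table[name] = {}
        X_test = _bag_of_codes(test_records, vocab, upto)[:, cols]
        # paired bootstrap: every regime is scored on the same test resamples
        boot_idx = [rng.integers(len(y_test), size=len(y_test))
                    for _ in range(spec.n_bootstrap)]
        for regime, train_view in regimes.items():
            # the enriched regime's labels live in its simulated window (the
            # real continuation is unavailable by construction); the other
            # regimes label from the real records
            label_source = train_view if regime == "enriched" else train_cohort
            y_train = np.array([label_phenotype(r, rule)
                                for r in label_source])
            X = _bag_of_codes(train_view, vocab, upto)[:, cols]
            if y_train.min() == y_train.max():
                probs = np.full(len(test_cohort), float(y_train.mean()))
            else:
                clf = LogisticRegression(max_iter=1000)
                clf.fit(X, y_train)
                probs = clf.predict_proba(X_test)[:, 1]
            f1, _ = f1_score(probs, y_test)
            boots = [f1_score(probs[idx], y_test[idx])[0]
                     for idx in boot_idx]
            table[name][regime] = {
                "f1": f1,
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "prevalence": float(y_test.mean()),
            }
    return table
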