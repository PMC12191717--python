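"""Synthetic patient-cohort generator with exactly queryable ground truth.

The generator emulates the statistical structure of longitudinal claims /
inpatient records that the record model assumes, at desk scale:

- a small latent Markov health state per patient drives diagnosis emission;
- procedure codes are emitted conditionally on the diagnoses of the same
  visit, medication codes conditionally on diagnoses and procedures
  (mirroring the model's autoregressive region ordering);
- record length is geometric (continuation probability per visit) capped at
  ``max_visits``.

Every conditional used during sampling is queryable in closed form through
:class:`GroundTruth`, which also provides the exact next-code conditionals
of the induced matrix process (the Bayes-optimal predictor) and the
entropy-rate perplexity lower bound. The latent state is never written to
cohort files; it exists only inside the ground-truth object for oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .records import CodeVocabulary, PatientRecord, Visit

__all__ = [
    "TriggerRule", "GeneratorConfig", "GroundTruth", "PhenotypeRule",
    "default_config", "sample_cohort", "label_phenotype", "inject_noise",
]


class ConfigError(ValueError):
    """Invalid generator configuration (probability out of range etc.)."""


@dataclass(frozen=True)
class TriggerRule:
    """Bernoulli emission for one procedure/medication code.

    Probability is ``p_on`` when the trigger code is present in the same
    visit, ``p_off`` otherwise. ``trigger`` is ``None`` (constant ``p_off``)
    or a pair ``(region, index)`` referencing a code sampled earlier in the
    cascade (a diagnosis, or a procedure for medication rules).
    """

    trigger: tuple | None
    p_on: float
    p_off: float

    def prob(self, trigger_present: bool) -> float:
        if self.trigger is None:
            return self.p_off
        return self.p_on if trigger_present else self.p_off


@dataclass(frozen=True)
class GeneratorConfig:
    initial_state_probs: tuple
    transition_matrix: tuple          # row-stochastic, (S, S)
    dx_emission: tuple                # (S, n_dx) Bernoulli probabilities
    px_rules: tuple                   # TriggerRule per procedure code
    rx_rules: tuple                   # TriggerRule per medication code
    continuation_prob: float = 0.75   # geometric length: P(another visit)
    max_visits: int = 11              # cap on real visits per record
    region_order: tuple = ("diagnosis", "procedure", "medication")
    seed: int = 0

    def __post_init__(self):
        pi = np.asarray(self.initial_state_probs, dtype=float)
        A = np.asarray(self.transition_matrix, dtype=float)
        E = np.asarray(self.dx_emission, dtype=float)
        if pi.ndim != 1 or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise ConfigError("initial_state_probs must be a distribution")
        if A.shape != (pi.size, pi.size):
            raise ConfigError("transition_matrix shape mismatch")
        if (A < 0).any() or np.abs(A.sum(axis=1) - 1.0).max() > 1e-9:
            raise ConfigError("transition rows must sum to 1")
        if E.ndim != 2 or E.shape[0] != pi.size:
            raise ConfigError("dx_emission must be (n_states, n_dx)")
        if ((E < 0) | (E > 1)).any():
            raise ConfigError("dx_emission probabilities must lie in [0, 1]")
        for rule in tuple(self.px_rules) + tuple(self.rx_rules):
            for p in (rule.p_on, rule.p_off):
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"rule probability {p} outside [0, 1]")
        if not (0.0 <= self.continuation_prob < 1.0 or
                (self.continuation_prob == 1.0 and self.max_visits < np.inf)):
            raise ConfigError("continuation_prob must lie in [0, 1]")
        if self.max_visits < 1:
            raise ConfigError("max_visits must be >= 1")

    # -- derived views -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.initial_state_probs)

    @property
    def n_dx(self) -> int:
        return len(self.dx_emission[0])

    @property
    def n_px(self) -> int:
        return len(self.px_rules)

    @property
    def n_rx(self) -> int:
        return len(self.rx_rules)

    def vocabulary(self) -> CodeVocabulary:
        return CodeVocabulary(
            diagnosis_codes=[f"d{i}" for i in range(self.n_dx)],
            procedure_codes=[f"p{i}" for i in range(self.n_px)],
            medication_codes=[f"m{i}" for i in range(self.n_rx)],
            region_order=self.region_order,
        )

    def length_pmf(self) -> np.ndarray:
        """P(T = t) for t = 1..max_visits (geometric, mass capped at the end)."""
        q = self.continuation_prob
        pmf = np.array([(q ** (t - 1)) * (1 - q) for t in range(1, self.max_visits)]
                       + [q ** (self.max_visits - 1)])
        return pmf


def default_config(seed: int = 0) -> GeneratorConfig:
    """The packaged desk-scale study conditions: 3 latent states, 4/3/3 codes.

    Chosen to be recognisably claims-like at toy scale: one dominant
    diagnosis per state with cross-talk, strongly triggered procedures
    (e.g. P(p0 | d0 present) = 0.9), medications triggered by diagnoses or
    procedures, persistent states (0.8 self-transition), and a mean record
    length of about four visits (continuation 0.75, capped at 11).
    """
    return GeneratorConfig(
        initial_state_probs=(0.5, 0.3, 0.2),
        transition_matrix=(
            (0.8, 0.15, 0.05),
            (0.1, 0.8, 0.1),
            (0.05, 0.15, 0.8),
        ),
        dx_emission=(
            (0.8, 0.10, 0.10, 0.05),
            (0.1, 0.80, 0.20, 0.05),
            (0.05, 0.15, 0.70, 0.40),
        ),
        px_rules=(
            TriggerRule(("diagnosis", 0), 0.9, 0.1),
            TriggerRule(("diagnosis", 1), 0.7, 0.05),
            TriggerRule(None, 0.0, 0.15),
        ),
        rx_rules=(
            TriggerRule(("diagnosis", 0), 0.8, 0.05),
            TriggerRule(("procedure", 1), 0.6, 0.10),
            TriggerRule(("diagnosis", 2), 0.5, 0.05),
        ),
        continuation_prob=0.75,
        max_visits=11,
        seed=seed,
    )


def benchmark_config(seed: int = 0) -> GeneratorConfig:
    """The packaged strong-temporal-signal enrichment benchmark.

    Two highly persistent latent states (0.92 self-transition) and long
    records (continuation 0.95, capped at 12 visits), so a record's early
    visits are strongly predictive of its later ones. Diagnosis ``d0`` is
    the phenotype target (common in state 0, rare in state 1); ``d1`` and
    ``d2`` are state markers carrying the temporal signal; one triggered
    procedure and medication give the other regions content. Pair with
    ``benchmark_rule()`` (d0 in visits 6-10) and a prefix of k=5 observed
    visits.
    """
    return GeneratorConfig(
        initial_state_probs=(0.5, 0.5),
        transition_matrix=(
            (0.92, 0.08),
            (0.08, 0.92),
        ),
        dx_emission=(
            (0.55, 0.70, 0.10),
            (0.02, 0.10, 0.70),
        ),
        px_rules=(
            TriggerRule(("diagnosis", 1), 0.6, 0.05),
        ),
        rx_rules=(
            TriggerRule(("diagnosis", 2), 0.6, 0.05),
        ),
        continuation_prob=0.95,
        max_visits=12,
        seed=seed,
    )


def benchmark_rule() -> "PhenotypeRule":
    """The phenotype paired with ``benchmark_config()``: d0 in visits 6-10."""
    return PhenotypeRule(target_diagnosis="d0", window_start=6, window_end=10)


# -- sampling --------------------------------------------------------------

def _sample_visit(state: int, config: GeneratorConfig, rng) -> Visit:
    E = np.asarray(config.dx_emission)
    dx_bits = rng.random(config.n_dx) < E[state]
    dx = frozenset(f"d{i}" for i in np.nonzero(dx_bits)[0])

    def trigger_present(trigger, dx_bits, px_bits):
        if trigger is None:
            return False
        region, idx = trigger
        return bool(dx_bits[idx]) if region == "diagnosis" else bool(px_bits[idx])

    px_bits = np.zeros(config.n_px, dtype=bool)
    for j, rule in enumerate(config.px_rules):
        px_bits[j] = rng.random() < rule.prob(trigger_present(rule.trigger, dx_bits, None))
    rx_bits = np.zeros(config.n_rx, dtype=bool)
    for j, rule in enumerate(config.rx_rules):
        rx_bits[j] = rng.random() < rule.prob(trigger_present(rule.trigger, dx_bits, px_bits))
    return Visit(
        diagnosis=dx,
        procedure=frozenset(f"p{i}" for i in np.nonzero(px_bits)[0]),
        medication=frozenset(f"m{i}" for i in np.nonzero(rx_bits)[0]),
    )


def sample_cohort(config: GeneratorConfig, n_patients: int,
                  seed: int | None = None, return_states: bool = False):
    """Draw ``n_patients`` records; reproducible for a given config + seed.

    With ``return_states`` the per-visit latent state sequences are also
    returned as ``(records, states)``; the sampled records are identical
    either way (the flag only records what was already drawn).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi = np.asarray(config.initial_state_probs)
    A = np.asarray(config.transition_matrix)
    records, all_states = [], []
    for p in range(n_patients):
        state = rng.choice(config.n_states, p=pi)
        states = [int(state)]
        visits = [_sample_visit(state, config, rng)]
        while (len(visits) < config.max_visits
               and rng.random() < config.continuation_prob):
            state = rng.choice(config.n_states, p=A[state])
            states.append(int(state))
            visits.append(_sample_visit(state, config, rng))
        records.append(PatientRecord(visits=visits, id=f"s{p:06d}"))
        all_states.append(states)
    if return_states:
        return records, all_states
    return records


# -- ground truth ----------------------------------------------------------

class GroundTruth:
    """Closed-form accessors for every conditional the generator uses.

    Also exposes the exact conditionals of the induced *matrix* process
    (visit rows followed by a stop sentinel row), which is the Bayes-optimal
    autoregressive predictor that any fitted model approximates.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.vocab = config.vocabulary()
        self.pi = np.asarray(config.initial_state_probs, dtype=float)
        self.A = np.asarray(config.transition_matrix, dtype=float)
        self.E = np.asarray(config.dx_emission, dtype=float)

    # ---- simple conditionals --------------------------------------------
    def _rule_for(self, code: str) -> TriggerRule:
        if code.startswith("p"):
            return self.config.px_rules[int(code[1:])]
        if code.startswith("m"):
            return self.config.rx_rules[int(code[1:])]
        raise ValueError(f"{code!r} has no trigger rule (diagnosis codes "
                         "are state-conditioned)")

    def p_code_given_context(self, code: str, present=(), absent=()) -> float:
        """P(code | same-visit context) for a triggered (px/rx) code.

        The context must determine the trigger's status; a rule without a
        trigger needs no context.
        """
        rule = self._rule_for(code)
        if rule.trigger is None:
            return rule.p_off
        region, idx = rule.trigger
        trig = ("d" if region == "diagnosis" else "p") + str(idx)
        if trig in set(present):
            return rule.p_on
        if trig in set(absent):
            return rule.p_off
        raise ValueError(f"context does not determine trigger {trig!r}")

    def p_dx_given_state_posterior(self, code: str, posterior) -> float:
        """P(diagnosis code present in a visit | state distribution)."""
        posterior = np.asarray(posterior, dtype=float)
        return float(posterior @ self.E[:, int(code[1:])])

    def p_code_given_state(self, code: str, state: int) -> float:
        """Marginal presence probability of any code in a visit at ``state``."""
        if code.startswith("d"):
            return float(self.E[state, int(code[1:])])
        rule = self._rule_for(code)
        if rule.trigger is None:
            return rule.p_off
        region, idx = rule.trigger
        if region == "diagnosis":
            p_trig = float(self.E[state, idx])
        else:
            p_trig = self.p_code_given_state(f"p{idx}", state)
        return rule.p_on * p_trig + rule.p_off * (1.0 - p_trig)

    def p_code_next_visit(self, code: str, state_posterior) -> float:
        """P(code present in the next visit | posterior over current state)."""
        post = np.asarray(state_posterior, dtype=float)
        nxt = post @ self.A
        return float(sum(nxt[s] * self.p_code_given_state(code, s)
                         for s in range(self.config.n_states)))

    # ---- matrix-process conditionals (Bayes-optimal predictor) ----------
    def _visit_dx_bits(self, visit: Visit) -> np.ndarray:
        bits = np.zeros(self.config.n_dx)
        for c in visit.diagnosis:
            bits[int(c[1:])] = 1.0
        return bits

    def _dx_likelihood(self, dx_bits: np.ndarray) -> np.ndarray:
        """P(dx pattern | state) for every state; px/rx are state-free."""
        return np.prod(np.where(dx_bits > 0.5, self.E, 1.0 - self.E), axis=1)

    def state_posterior(self, visits) -> np.ndarray:
        """Forward-filtered posterior over the state of the *last* visit.

        Only diagnoses inform the state (procedures and medications are
        conditionally independent of the state given the diagnoses).
        """
        b = self.pi.copy()
        for t, visit in enumerate(visits):
            if t > 0:
                b = b @ self.A
            b = b * self._dx_likelihood(self._visit_dx_bits(visit))
            total = b.sum()
            if total <= 0.0:
                raise ValueError("visit impossible under the generator")
            b = b / total
        return b

    def sample_continuation(self, prior_visits, rng) -> list:
        """Draw future visits from the exact conditional given the prefix.

        Samples the current state from the forward-filtered posterior, then
        runs the generator forward (state transitions, visit emissions, and
        the remaining geometric length) until the record ends. Returns the
        list of additional visits (possibly empty). This is the cheating
        oracle for enrichment controls: completions drawn from the true
        process rather than a learned model.
        """
        t = len(prior_visits)
        if t == 0:
            raise ValueError("prefix must contain at least one visit")
        state = int(rng.choice(self.config.n_states,
                               p=self.state_posterior(prior_visits)))
        future = []
        while (t + len(future) < self.config.max_visits
               and rng.random() < self.config.continuation_prob):
            state = int(rng.choice(self.config.n_states, p=self.A[state]))
            future.append(_sample_visit(state, self.config, rng))
        return future

    def next_row_probabilities(self, prior_visits, partial_row: np.ndarray,
                               upto: int | None = None) -> np.ndarray:
        """Exact P(entry i = 1 | prior visits, entries < i of the next row).

        ``partial_row`` is a length ``total_size`` 0/1 vector over the
        model's flat code space (stop code last). Row index t+1 where
        t = len(prior_visits); the row is a real visit with the remaining
        continuation probability or the stop sentinel otherwise. Returns the
        full vector of conditionals (entry i computed as if entries >= i
        were still unsampled).
        """
        vocab = self.vocab
        t = len(prior_visits)
        if t == 0:
            b_next = self.pi.copy()
            q = 1.0  # a record always has at least one visit
        else:
            b_next = self.state_posterior(prior_visits) @ self.A
            q = self.config.continuation_prob if t < self.config.max_visits else 0.0

        if self.config.region_order != ("diagnosis", "procedure", "medication"):
            raise NotImplementedError(
                "exact conditionals assume the cascade-aligned region order")
        total = vocab.total_size
        out = np.zeros(total)
        # posterior over next state, progressively conditioned on observed dx
        # bits of the partial row; real/sentinel mixture tracked via odds.
        b = b_next.copy()
        p_prefix_real = 1.0  # P(observed all-zero prefix | row is a real visit)
        any_code_on = False
        for i in range(total):
            if i == vocab.stop_index:
                if any_code_on:
                    out[i] = 0.0
                else:
                    p_real = q * p_prefix_real
                    out[i] = (1.0 - q) / (p_real + (1.0 - q)) if (p_real + (1.0 - q)) > 0 else 1.0
                continue
            region = vocab.region_of_index(i)
            sl = vocab.region_slice(region)
            local = i - sl.start
            if region == "diagnosis":
                p_one_real = float(b @ self.E[:, local]) / b.sum()
            else:
                code = ("p" if region == "procedure" else "m") + str(local)
                rule = self._rule_for(code)
                if rule.trigger is None:
                    p_one_real = rule.p_off
                else:
                    reg, idx = rule.trigger
                    trig_idx = vocab.region_slice(reg).start + idx
                    p_one_real = rule.prob(partial_row[trig_idx] > 0.5)
            if any_code_on:
                out[i] = p_one_real
            else:
                p_real = q * p_prefix_real
                w_real = p_real / (p_real + (1.0 - q)) if (p_real + (1.0 - q)) > 0 else 0.0
                out[i] = w_real * p_one_real
            # condition on the realized value of entry i for later entries
            bit = partial_row[i] > 0.5
            if region == "diagnosis":
                lik = self.E[:, local] if bit else 1.0 - self.E[:, local]
                b = b * lik
            if bit:
                any_code_on = True
            else:
                p_prefix_real *= (1.0 - p_one_real)
            if upto is not None and i >= upto:
                break
        return out

    # ---- entropy-rate perplexity bound ----------------------------------
    def record_log_prob(self, record: PatientRecord) -> float:
        """Exact log P(record) under the generator (length + content)."""
        T = len(record.visits)
        pmf = self.config.length_pmf()
        if not (1 <= T <= self.config.max_visits):
            raise ValueError("record length impossible under the generator")
        logp = float(np.log(pmf[T - 1]))
        b = self.pi.copy()
        for t, visit in enumerate(record.visits):
            if t > 0:
                b = b @ self.A
            dx_bits = self._visit_dx_bits(visit)
            b = b * self._dx_likelihood(dx_bits)
            scale = b.sum()
            if scale <= 0.0:
                return -np.inf
            logp += np.log(scale)
            b = b / scale
            logp += self._log_px_rx(visit)
        return logp

    def _log_px_rx(self, visit: Visit) -> float:
        logp = 0.0
        px = {int(c[1:]) for c in visit.procedure}
        rx = {int(c[1:]) for c in visit.medication}
        dx = {int(c[1:]) for c in visit.diagnosis}

        def trig_on(trigger):
            if trigger is None:
                return False
            region, idx = trigger
            return idx in (dx if region == "diagnosis" else px)

        for j, rule in enumerate(self.config.px_rules):
            p = rule.prob(trig_on(rule.trigger))
            logp += np.log(p if j in px else 1.0 - p)
        for j, rule in enumerate(self.config.rx_rules):
            p = rule.prob(trig_on(rule.trigger))
            logp += np.log(p if j in rx else 1.0 - p)
        return float(logp)

    def expected_present_codes(self) -> float:
        """E[count of present codes per record], counting the stop event."""
        pmf = self.config.length_pmf()
        surv = np.concatenate([[1.0], 1.0 - np.cumsum(pmf)[:-1]])  # P(T >= t)
        total = 1.0  # stop event
        state_marg = self.pi.copy()
        for t in range(self.config.max_visits):
            if t > 0:
                state_marg = state_marg @ self.A
            per_visit = float(state_marg @ self.E.sum(axis=1))
            for code in ([f"p{j}" for j in range(self.config.n_px)]
                         + [f"m{j}" for j in range(self.config.n_rx)]):
                per_visit += sum(state_marg[s] * self.p_code_given_state(code, s)
                                 for s in range(self.config.n_states))
            total += surv[t] * per_visit
        return total

    def entropy_rate_bound(self, method: str = "auto", n_mc: int = 20000,
                           seed: int = 12345) -> float:
        """Perplexity of the true model: exp(H_total / E[N_present]).

        ``H_total`` is the expected negative log-likelihood of a record.
        Exhaustive enumeration over all records is used when the outcome
        space is small enough; otherwise the expectation is taken by Monte
        Carlo with the per-record likelihood still computed exactly. This is
        the infimum of the cohort perplexity achievable by any model.
        """
        n_codes = self.config.n_dx + self.config.n_px + self.config.n_rx
        enum_cost = sum((2 ** n_codes) ** t
                        for t in range(1, self.config.max_visits + 1))
        if method == "auto":
            method = "enumerate" if enum_cost <= 300_000 else "monte_carlo"
        if method == "enumerate":
            h_total = self._exact_expected_nll()
        elif method == "monte_carlo":
            cohort = sample_cohort(self.config, n_mc, seed=seed)
            h_total = -float(np.mean([self.record_log_prob(r) for r in cohort]))
        else:
            raise ValueError(f"unknown method {method!r}")
        return float(np.exp(h_total / self.expected_present_codes()))

    def _exact_expected_nll(self) -> float:
        n_dx, n_px, n_rx = self.config.n_dx, self.config.n_px, self.config.n_rx
        visit_space = []
        for bits in itertools.product([0, 1], repeat=n_dx + n_px + n_rx):
            visit_space.append(Visit(
                diagnosis=frozenset(f"d{i}" for i in range(n_dx) if bits[i]),
                procedure=frozenset(f"p{i}" for i in range(n_px) if bits[n_dx + i]),
                medication=frozenset(
                    f"m{i}" for i in range(n_rx) if bits[n_dx + n_px + i]),
            ))
        h = 0.0
        for T in range(1, self.config.max_visits + 1):
            for combo in itertools.product(visit_space, repeat=T):
                lp = self.record_log_prob(PatientRecord(visits=list(combo)))
                if np.isfinite(lp):
                    h -= np.exp(lp) * lp
        return h


# -- downstream labels and noise ------------------------------------------

@dataclass(frozen=True)
class PhenotypeRule:
    """Label = 1 iff ``target_diagnosis`` appears in visits
    ``window_start..window_end`` (1-based, inclusive)."""

    target_diagnosis: str
    window_start: int
    window_end: int


def label_phenotype(record: PatientRecord, rule: PhenotypeRule) -> int:
    lo, hi = rule.window_start - 1, rule.window_end  # 0-based half-open
    for visit in record.visits[lo:hi]:
        if rule.target_diagnosis in visit.diagnosis:
            return 1
    return 0


def inject_noise(record: PatientRecord, vocab: CodeVocabulary,
                 rng) -> PatientRecord:
    """Replace exactly one present code per (non-empty) visit with a random
    different code from the vocabulary — the downstream-benchmark noise knob."""
    all_codes = (vocab.diagnosis_codes + vocab.procedure_codes
                 + vocab.medication_codes)
    new_visits = []
    for visit in record.visits:
        present = sorted(visit.all_codes())
        if not present:
            new_visits.append(Visit(payloads=dict(visit.payloads)))
            continue
        removed = present[rng.integers(len(present))]
        candidates = [c for c in all_codes if c not in present]
        remaining = set(present) - {removed}
        if candidates:
            remaining.add(candidates[rng.integers(len(candidates))])
        sets = {"diagnosis": set(), "procedure": set(), "medication": set()}
        for c in remaining:
            sets[vocab.region_of_index(vocab.index_of(c))].add(c)
        new_visits.append(Visit(diagnosis=sets["diagnosis"],
                                procedure=sets["procedure"],
                                medication=sets["medication"],
                                payloads=dict(visit.payloads)))
    return PatientRecord(visits=new_visits, id=record.id)
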