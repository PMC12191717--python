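"""Evaluation protocols: hand-checkable temporal/modality scores and the
structural identities of the enrichment benchmark."""

import numpy as np
import pytest

import medisim as ms
from medisim.evaluation import (EnrichmentSpec, enrichment_benchmark,
                                modality_eval, temporal_eval)


class TestTemporalEval:
    def test_constant_half_oracle(self, constant_model_factory, vocab,
                                  gen_config):
        """p=0.5 everywhere: every position predicted positive, so
        TP = present codes, FN = 0, and perplexity = 2 exactly."""
        records = [r for r in ms.sample_cohort(gen_config, 50, seed=101)
                   if len(r.visits) > 1]
        model = constant_model_factory(0.5)
        report = temporal_eval(model, records)
        n_pos, n_present = 0, 0
        for r in records:
            mat = ms.encode_record(r, vocab, max_visits=101)
            rows = mat.values[1:]          # visit 1 has no history
            n_pos += rows.size
            n_present += int(rows.sum())
        assert report.counts["TP"] == n_present
        assert report.counts["FN"] == 0
        assert report.counts["FP"] == n_pos - n_present
        # present-code normalization, as in the cohort perplexity metric
        np.testing.assert_allclose(report.perplexity,
                                   2.0 ** (n_pos / n_present), rtol=1e-12)
        np.testing.assert_allclose(
            report.f1, 2 * n_present / (2 * n_present + n_pos - n_present))

    def test_per_visit_breakdown_keys(self, constant_model_factory,
                                      gen_config):
        records = [r for r in ms.sample_cohort(gen_config, 50, seed=103)
                   if len(r.visits) > 1]
        report = temporal_eval(constant_model_factory(0.5), records)
        longest = max(len(r.visits) for r in records)
        assert min(report.per_visit) == 2
        assert max(report.per_visit) == longest + 1   # sentinel row

    def test_single_visit_contributes_sentinel_only(
            self, constant_model_factory, vocab):
        from medisim.records import PatientRecord, Visit
        records = [PatientRecord(visits=[Visit(diagnosis=["d0"])])]
        report = temporal_eval(constant_model_factory(0.5), records)
        # only the stop decision is evaluated: one present code (stop)
        assert report.counts["N"] == vocab.total_size
        assert report.counts["TP"] == 1

    def test_empty_records_rejected(self, constant_model_factory):
        from medisim.records import PatientRecord
        with pytest.raises(ValueError):
            temporal_eval(constant_model_factory(0.5),
                          [PatientRecord(visits=[])])


class TestModalityEval:
    def test_constant_oracle_counts(self, constant_model_factory, vocab,
                                    gen_config):
        records = ms.sample_cohort(gen_config, 40, seed=107)
        report = modality_eval(constant_model_factory(0.5), records,
                               conditioning="teacher_forced")
        n_pos, n_present = 0, 0
        for r in records:
            for v in r.visits:
                n_pos += len(vocab.procedure_codes) + len(
                    vocab.medication_codes)
                n_present += len(v.procedure) + len(v.medication)
        assert report.counts["TP"] == n_present
        assert report.counts["N"] == n_pos
        np.testing.assert_allclose(report.perplexity,
                                   2.0 ** (n_pos / n_present), rtol=1e-12)

    def test_zero_positives_flag(self, constant_model_factory, vocab):
        from medisim.records import PatientRecord, Visit
        records = [PatientRecord(visits=[Visit(diagnosis=["d0"]),
                                         Visit(diagnosis=["d1"])])]
        report = modality_eval(constant_model_factory(0.3), records)
        assert report.f1 == 0.0
        assert report.flags.get("zero_positives") is True

    def test_sequential_conditioning_runs(self, vocab, gen_config):
        records = ms.sample_cohort(gen_config, 8, seed=109)
        model = ms.MediSim(vocab, ms.ModelConfig(nemb=16, n_blocks=1,
                                                 n_heads=2, seed=17))
        report = modality_eval(model, records, conditioning="sequential",
                               seed=5)
        assert report.protocol == "modality/sequential"
        assert 0.0 <= report.f1 <= 1.0

    def test_unknown_conditioning_rejected(self, constant_model_factory,
                                           gen_config):
        with pytest.raises(ValueError):
            modality_eval(constant_model_factory(0.5),
                          ms.sample_cohort(gen_config, 2, seed=1),
                          conditioning="oracle")


@pytest.fixture(scope="module")
def bench():
    cfg = ms.benchmark_config()
    return {
        "cfg": cfg,
        "vocab": cfg.vocabulary(),
        "train": ms.sample_cohort(cfg, 150, seed=111),
        "test": ms.sample_cohort(cfg, 150, seed=113),
        "rule": ms.benchmark_rule(),
    }


class TestEnrichmentBenchmark:

    def test_perfect_simulator_equals_full(self, bench):
        """A simulator that returns the real records makes the enriched
        regime identical to the full regime, row for row."""
        train = bench["train"]

        def cheat(defs):
            return list(train)

        spec = EnrichmentSpec(rules=(bench["rule"],), k=5, horizon=5,
                              n_bootstrap=10, seed=0)
        table = enrichment_benchmark(train, bench["test"], model=None,
                                     vocab=bench["vocab"], spec=spec,
                                     simulator=cheat)
        row = table[next(iter(table))]
        assert row["enriched"]["f1"] == row["full"]["f1"]
        assert row["enriched"]["ci_low"] == row["full"]["ci_low"]

    def test_non_extending_simulator_degenerates(self, bench):
        """If completion adds nothing, the enriched regime has no label
        window, labels collapse to zero, and its F1 is zero."""
        def passthrough(defs):
            return [d.record for d in defs]

        spec = EnrichmentSpec(rules=(bench["rule"],), k=5, horizon=5,
                              n_bootstrap=10, seed=0)
        table = enrichment_benchmark(bench["train"], bench["test"],
                                     model=None, vocab=bench["vocab"],
                                     spec=spec, simulator=passthrough)
        row = table[next(iter(table))]
        assert row["enriched"]["f1"] == 0.0
        assert row["full"]["f1"] > 0.0

    def test_deficient_view_keeps_short_records(self, bench):
        """Records that terminated within k visits are complete: the
        deficient regime must contain them unchanged."""
        seen = {}

        def spy(defs):
            seen["kinds"] = [d.kind for d in defs]
            return [d.record for d in defs]

        spec = EnrichmentSpec(rules=(bench["rule"],), k=5, horizon=5,
                              n_bootstrap=2, seed=0)
        enrichment_benchmark(bench["train"], bench["test"], model=None,
                             vocab=bench["vocab"], spec=spec, simulator=spy)
        for rec, kind in zip(bench["train"], seen["kinds"]):
            expected = "longitudinal" if len(rec.visits) > 5 else "none"
            assert kind == expected

    def test_report_structure_and_prevalence(self, bench):
        def cheat(defs):
            return list(bench["train"])

        spec = EnrichmentSpec(rules=(bench["rule"],), n_bootstrap=5, seed=1)
        table = enrichment_benchmark(bench["train"], bench["test"],
                                     model=None, vocab=bench["vocab"],
                                     spec=spec, simulator=cheat)
        row = table["d0@6-10"]
        assert set(row) == {"deficient", "enriched", "full"}
        for entry in row.values():
            assert entry["ci_low"] <= entry["ci_high"]
            assert 0.0 <= entry["f1"] <= 1.0
            assert 0.0 < entry["prevalence"] < 1.0

    def test_unknown_mode_rejected(self, bench):
        spec = EnrichmentSpec(rules=(bench["rule"],), mode="spatial")
        with pytest.raises(ValueError):
            enrichment_benchmark(bench["train"], bench["test"], model=None,
                                 vocab=bench["vocab"], spec=spec,
                                 simulator=lambda defs: [d.record
                                                         for d in defs])
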