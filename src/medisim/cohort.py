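"""Cohort file format (JSON Lines) and reproducible splitting.

One record per line::

    {"id": "p0001", "visits": [{"dx": ["d0"], "px": [], "rx": ["m1"],
                                "payloads": {"note": ["tok_d0", "noise3"]}}, ...]}

``dx``/``px``/``rx`` hold diagnosis/procedure/medication code identifiers;
``payloads`` is optional per visit and maps a modality name to its payload
(JSON-serializable). Visits are 1-based in prose, 0-based in the API.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .records import CodeVocabulary, PatientRecord, Visit

_VISIT_KEYS = {"dx", "px", "rx", "payloads"}
_RECORD_KEYS = {"id", "visits"}


class CohortParseError(ValueError):
    """Raised with the 1-based line number of the offending line."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def record_to_json(record: PatientRecord) -> dict:
    visits = []
    for v in record.visits:
        d = {"dx": sorted(v.diagnosis), "px": sorted(v.procedure),
             "rx": sorted(v.medication)}
        if v.payloads:
            d["payloads"] = v.payloads
        visits.append(d)
    out = {"visits": visits}
    if record.id is not None:
        out["id"] = record.id
    return out


def record_from_json(d: dict, line_number: int = 0) -> PatientRecord:
    unknown = set(d) - _RECORD_KEYS
    if unknown:
        raise CohortParseError(line_number, f"unknown field(s) {sorted(unknown)}")
    if "visits" not in d or not isinstance(d["visits"], list):
        raise CohortParseError(line_number, "missing or non-list 'visits'")
    visits = []
    for i, vd in enumerate(d["visits"]):
        if not isinstance(vd, dict):
            raise CohortParseError(line_number, f"visit {i} is not an object")
        unknown = set(vd) - _VISIT_KEYS
        if unknown:
            raise CohortParseError(
                line_number, f"visit {i}: unknown field(s) {sorted(unknown)}")
        visits.append(Visit(diagnosis=vd.get("dx", []),
                            procedure=vd.get("px", []),
                            medication=vd.get("rx", []),
                            payloads=vd.get("payloads", {})))
    return PatientRecord(visits=visits, id=d.get("id"))


def write_cohort(records, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for record in records:
            fh.write(json.dumps(record_to_json(record), sort_keys=True))
            fh.write("\n")


def read_cohort(path) -> list:
    path = Path(path)
    records = []
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(i, f"invalid JSON ({exc.msg})") from exc
            records.append(record_from_json(d, line_number=i))
    return records


def write_vocabulary(vocab: CodeVocabulary, path) -> None:
    Path(path).write_text(json.dumps(vocab.to_dict(), indent=2))


def read_vocabulary(path) -> CodeVocabulary:
    return CodeVocabulary.from_dict(json.loads(Path(path).read_text()))


def split_cohort(records, fractions=(0.72, 0.08, 0.20), seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible train/validation/test split.

    Sizes are ``round(f * n)`` for the leading fractions with the remainder
    in the last split, so the parts always partition the input.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    records = list(records)
    n = len(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val:]]
    return train, val, test
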