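"""Vocabulary, record, matrix, and deficiency data model.

A longitudinal health record is an ordered sequence of visits; each visit is
a set of medical codes partitioned into three modality regions — diagnoses,
procedures, medications — plus optional complex payloads (e.g. note-like
token sequences) carried alongside the codes. The model's native input is
the multi-hot binary matrix form of a record, with one reserved stop-code
column whose activation marks the end of the record: the matrix carries one
appended sentinel row that is all-zero except for the stop entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

REGIONS = ("diagnosis", "procedure", "medication")

DEFAULT_MAX_VISITS = 100


class VocabularyError(KeyError):
    """A code identifier is not resolvable in the vocabulary."""


class RecordLengthError(ValueError):
    """A record exceeds the configured maximum number of visits."""


class DeficiencyParameterError(ValueError):
    """Invalid deficiency parameters (e.g. T' >= T for truncation)."""


@dataclass(frozen=True)
class CodeVocabulary:
    """Ordered code index space with a reserved trailing stop-code slot.

    The three modality regions are laid out contiguously in a configurable
    order (default diagnosis -> procedure -> medication); code index i in
    the flat space is the autoregressive position of that code. The stop
    code always occupies the final index.
    """

    diagnosis_codes: tuple
    procedure_codes: tuple
    medication_codes: tuple
    region_order: tuple = REGIONS

    def __post_init__(self):
        object.__setattr__(self, "diagnosis_codes", tuple(self.diagnosis_codes))
        object.__setattr__(self, "procedure_codes", tuple(self.procedure_codes))
        object.__setattr__(self, "medication_codes", tuple(self.medication_codes))
        object.__setattr__(self, "region_order", tuple(self.region_order))
        if sorted(self.region_order) != sorted(REGIONS):
            raise VocabularyError(f"region_order must be a permutation of {REGIONS}")
        all_codes = (self.diagnosis_codes + self.procedure_codes
                     + self.medication_codes)
        if len(set(all_codes)) != len(all_codes):
            raise VocabularyError("code identifiers must be unique across regions")

    def _region_codes(self, region: str) -> tuple:
        return {
            "diagnosis": self.diagnosis_codes,
            "procedure": self.procedure_codes,
            "medication": self.medication_codes,
        }[region]

    @property
    def total_size(self) -> int:
        """|D| + |P| + |M| + 1 (stop code)."""
        return (len(self.diagnosis_codes) + len(self.procedure_codes)
                + len(self.medication_codes) + 1)

    @property
    def stop_index(self) -> int:
        return self.total_size - 1

    def region_slice(self, region: str) -> slice:
        """Half-open index range of a region in the flat code space."""
        offset = 0
        for r in self.region_order:
            n = len(self._region_codes(r))
            if r == region:
                return slice(offset, offset + n)
            offset += n
        raise ValueError(f"unknown region {region!r}")

    def index_of(self, code) -> int:
        for region in self.region_order:
            codes = self._region_codes(region)
            if code in codes:
                return self.region_slice(region).start + codes.index(code)
        raise VocabularyError(f"unknown code identifier {code!r}")

    def code_at(self, index: int):
        for region in self.region_order:
            sl = self.region_slice(region)
            if sl.start <= index < sl.stop:
                return self._region_codes(region)[index - sl.start]
        raise VocabularyError(f"index {index} out of code range")

    def region_of_index(self, index: int) -> str:
        if index == self.stop_index:
            return "stop"
        for region in self.region_order:
            sl = self.region_slice(region)
            if sl.start <= index < sl.stop:
                return region
        raise VocabularyError(f"index {index} is not a modality code index")

    def to_dict(self) -> dict:
        return {
            "diagnosis_codes": list(self.diagnosis_codes),
            "procedure_codes": list(self.procedure_codes),
            "medication_codes": list(self.medication_codes),
            "region_order": list(self.region_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeVocabulary":
        return cls(
            diagnosis_codes=d["diagnosis_codes"],
            procedure_codes=d["procedure_codes"],
            medication_codes=d["medication_codes"],
            region_order=tuple(d.get("region_order", REGIONS)),
        )


@dataclass
class Visit:
    """One timestep's code sets plus optional complex payloads."""

    diagnosis: frozenset = frozenset()
    procedure: frozenset = frozenset()
    medication: frozenset = frozenset()
    payloads: dict = field(default_factory=dict)

    def __post_init__(self):
        self.diagnosis = frozenset(self.diagnosis)
        self.procedure = frozenset(self.procedure)
        self.medication = frozenset(self.medication)

    def codes(self, region: str) -> frozenset:
        return getattr(self, region)

    def all_codes(self) -> frozenset:
        return self.diagnosis | self.procedure | self.medication

    def __eq__(self, other):
        if not isinstance(other, Visit):
            return NotImplemented
        return (self.diagnosis == other.diagnosis
                and self.procedure == other.procedure
                and self.medication == other.medication
                and self.payloads == other.payloads)


@dataclass
class PatientRecord:
    """An ordered sequence of visits (1 <= T <= max_visits)."""

    visits: list
    id: str | None = None

    def __len__(self) -> int:
        return len(self.visits)

    def __eq__(self, other):
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return self.visits == other.visits and self.id == other.id


@dataclass
class RecordMatrix:
    """T+1 x total_size binary matrix form of a record.

    The final row is the sentinel: all-zero except the stop column. Complex
    payloads are carried alongside (``payloads[t]`` for visit t, 0-based),
    never inside the binary matrix.
    """

    values: np.ndarray
    vocab: CodeVocabulary
    payloads: list | None = None

    @property
    def n_visits(self) -> int:
        return self.values.shape[0] - 1


KINDS = ("longitudinal", "modality", "dual", "none")


@dataclass
class DeficientRecord:
    """A record plus the description of which parts are observed.

    ``record`` holds only the observed content (the deficient view);
    ``observed_regions`` must be a prefix of the vocabulary region order so
    that conditioning respects the autoregressive code order.
    """

    record: PatientRecord
    kind: str = "none"
    observed_visits: int | None = None
    observed_regions: tuple | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")


def encode_record(record: PatientRecord, vocab: CodeVocabulary,
                  max_visits: int = DEFAULT_MAX_VISITS) -> RecordMatrix:
    """Convert a record into its multi-hot matrix form, appending the sentinel."""
    T = len(record.visits)
    if T + 1 > max_visits:
        raise RecordLengthError(
            f"record has {T} visits; with the sentinel row this exceeds "
            f"max_visits={max_visits}")
    values = np.zeros((T + 1, vocab.total_size), dtype=np.int8)
    payloads = []
    for t, visit in enumerate(record.visits):
        for code in visit.all_codes():
            values[t, vocab.index_of(code)] = 1
        payloads.append(dict(visit.payloads))
    values[T, vocab.stop_index] = 1
    return RecordMatrix(values=values, vocab=vocab, payloads=payloads)


def decode_record(matrix: RecordMatrix) -> PatientRecord:
    """Inverse of :func:`encode_record` (drops the sentinel row)."""
    vocab = matrix.vocab
    visits = []
    slices = {r: vocab.region_slice(r) for r in REGIONS}
    for t in range(matrix.n_visits):
        row = matrix.values[t]
        sets = {}
        for region, sl in slices.items():
            idx = np.nonzero(row[sl])[0]
            sets[region] = frozenset(vocab.code_at(sl.start + i) for i in idx)
        payloads = {} if matrix.payloads is None else dict(matrix.payloads[t])
        visits.append(Visit(diagnosis=sets["diagnosis"],
                            procedure=sets["procedure"],
                            medication=sets["medication"],
                            payloads=payloads))
    return PatientRecord(visits=visits)


def _strip_regions(visit: Visit, observed_regions) -> Visit:
    kept = {r: (visit.codes(r) if r in observed_regions else frozenset())
            for r in REGIONS}
    return Visit(diagnosis=kept["diagnosis"], procedure=kept["procedure"],
                 medication=kept["medication"], payloads=dict(visit.payloads))


def induce_deficiency(record: PatientRecord, kind: str,
                      observed_visits: int | None = None,
                      observed_regions=None,
                      vocab: CodeVocabulary | None = None) -> DeficientRecord:
    """Derive a deficient view of a record; the original is left untouched.

    - ``longitudinal``: keep the first ``observed_visits`` (T') visits intact.
    - ``modality``: keep all visits but strip codes outside ``observed_regions``.
    - ``dual``: strip modalities, then truncate.

    ``observed_regions`` must be a prefix of the region order (checked when a
    vocabulary is supplied).
    """
    T = len(record.visits)
    if kind in ("longitudinal", "dual"):
        if observed_visits is None or not (1 <= observed_visits < T):
            raise DeficiencyParameterError(
                f"need 1 <= observed_visits < {T}, got {observed_visits}")
    if kind in ("modality", "dual"):
        if not observed_regions:
            raise DeficiencyParameterError("observed_regions required")
        observed_regions = tuple(observed_regions)
        if vocab is not None:
            prefix = vocab.region_order[:len(observed_regions)]
            if tuple(observed_regions) != prefix:
                raise DeficiencyParameterError(
                    f"observed_regions {observed_regions} is not a prefix of "
                    f"the region order {vocab.region_order}")

    if kind == "none":
        visits = [replace(v) for v in record.visits]
    elif kind == "longitudinal":
        visits = [replace(v) for v in record.visits[:observed_visits]]
    elif kind == "modality":
        visits = [_strip_regions(v, observed_regions) for v in record.visits]
    elif kind == "dual":
        visits = [_strip_regions(v, observed_regions)
                  for v in record.visits[:observed_visits]]
    else:
        raise ValueError(f"unknown deficiency kind {kind!r}")
    return DeficientRecord(
        record=PatientRecord(visits=visits, id=record.id),
        kind=kind,
        observed_visits=observed_visits if kind in ("longitudinal", "dual") else None,
        observed_regions=observed_regions if kind in ("modality", "dual") else None,
    )
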