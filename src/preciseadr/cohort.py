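"""Adverse-event report domain model, readers/writers, and cohort splitting.

A report is one spontaneous safety report: the patient's diseases
(indications), the drugs taken, demographics (age, sex, weight), the
reporter's qualification, the report date, and the observed adverse drug
reactions (ADRs) — the multi-label target. IDs for diseases, drugs and
ADRs are opaque strings (MedDRA-like / DrugBank-like); no ontology
resolution is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["AdverseEventReport", "Vocabulary", "ReportFormatError",
           "ReportValidationError", "read_reports", "write_reports",
           "build_vocabulary", "split_cohort"]

TSV_COLUMNS = ["report_id", "diseases", "drugs", "age", "sex", "weight",
               "qualification", "date", "adrs"]
SET_DELIMITER = ";"

#: reporter qualification codes: 1 physician, 2 pharmacist, 3 other health
#: professional, 4 lawyer, 5 consumer
QUALIFICATIONS = frozenset({1, 2, 3, 4, 5})
#: sex codes: 1 male, 2 female
SEXES = frozenset({1, 2})


class ReportFormatError(ValueError):
    """Raised when a report file is structurally malformed."""


class ReportValidationError(ValueError):
    """Raised when a row violates a report invariant."""


@dataclass(frozen=True)
class AdverseEventReport:
    """One safety report; `adrs` is the prediction target."""

    report_id: str
    diseases: frozenset[str]
    drugs: frozenset[str]
    age: int | None     # years; None only in raw reports, filtered before use
    sex: int | None     # 1 = male, 2 = female; None = not reported
    weight: float | None  # kilograms; FAERS weights are sparse, may be missing
    qualification: int  # reporter qualification code 1..5
    date: str           # ISO-8601
    adrs: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "diseases", frozenset(self.diseases))
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "adrs", frozenset(self.adrs))
        if self.sex is not None and self.sex not in SEXES:
            raise ReportValidationError(
                f"report {self.report_id!r}: sex code {self.sex} not in {{1,2}}")
        if self.qualification not in QUALIFICATIONS:
            raise ReportValidationError(
                f"report {self.report_id!r}: qualification {self.qualification} "
                "not in {1..5}")
        if self.age is not None and self.age < 0:
            raise ReportValidationError(
                f"report {self.report_id!r}: negative age {self.age}")
        if self.weight is not None and not self.weight > 0:
            raise ReportValidationError(
                f"report {self.report_id!r}: non-positive weight {self.weight}")

    @property
    def has_demographics(self) -> bool:
        return self.age is not None and self.sex is not None


@dataclass(frozen=True)
class Vocabulary:
    """Bijections between entity IDs and contiguous integer indices.

    Built from training reports only: the label space (and the graph's
    disease/drug node sets) is frozen at training time.
    """

    disease_index: dict[str, int]
    drug_index: dict[str, int]
    adr_index: dict[str, int]
    diseases: tuple[str, ...] = field(init=False)
    drugs: tuple[str, ...] = field(init=False)
    adrs: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        for name, idx in [("disease_index", self.disease_index),
                          ("drug_index", self.drug_index),
                          ("adr_index", self.adr_index)]:
            if sorted(idx.values()) != list(range(len(idx))):
                raise ValueError(f"{name} is not a contiguous bijection")
        inv = lambda m: tuple(k for k, _ in sorted(m.items(), key=lambda kv: kv[1]))
        object.__setattr__(self, "diseases", inv(self.disease_index))
        object.__setattr__(self, "drugs", inv(self.drug_index))
        object.__setattr__(self, "adrs", inv(self.adr_index))

    @property
    def n_diseases(self) -> int:
        return len(self.disease_index)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    @property
    def n_adrs(self) -> int:
        return len(self.adr_index)


def _parse_set(token: str) -> frozenset[str]:
    token = token.strip()
    if not token:
        return frozenset()
    parts = [p for p in token.split(SET_DELIMITER) if p]
    if len(parts) != len(set(parts)):
        raise ReportValidationError(f"duplicate IDs in set field {token!r}")
    return frozenset(parts)


def _row_to_report(row: dict, rownum: int) -> AdverseEventReport:
    try:
        weight_raw = row.get("weight", "")
        if isinstance(weight_raw, str):
            weight = float(weight_raw) if weight_raw.strip() else None
        else:
            weight = None if weight_raw is None or pd.isna(weight_raw) else float(weight_raw)
        diseases = row["diseases"]
        drugs = row["drugs"]
        adrs = row["adrs"]
        if isinstance(diseases, str):
            diseases, drugs, adrs = map(_parse_set, (diseases, drugs, adrs))

        def opt_int(v):
            if v is None:
                return None
            if isinstance(v, str) and not v.strip():
                return None
            return int(v)

        return AdverseEventReport(
            report_id=str(row["report_id"]),
            diseases=frozenset(map(str, diseases)),
            drugs=frozenset(map(str, drugs)),
            age=opt_int(row["age"]),
            sex=opt_int(row["sex"]),
            weight=weight,
            qualification=int(row["qualification"]),
            date=str(row["date"]),
            adrs=frozenset(map(str, adrs)),
        )
    except ReportValidationError as exc:
        raise ReportValidationError(f"row {rownum}: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise ReportFormatError(f"row {rownum}: unparseable ({exc})") from exc


def read_reports(path, format: str = "tsv") -> list[AdverseEventReport]:
    """Read adverse-event reports from a TSV or JSONL file, in file order.

    TSV dialect: UTF-8, header row with columns
    ``report_id diseases drugs age sex weight qualification date adrs``;
    set-valued columns are ";"-delimited. JSONL mirrors the schema with
    JSON arrays for the set-valued fields and null for missing weight.
    """
    reports: list[AdverseEventReport] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ReportFormatError(f"missing required columns: {sorted(missing)}")
        for i, row in enumerate(df.to_dict("records"), start=2):
            reports.append(_row_to_report(row, i))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ReportFormatError(f"row {i}: invalid JSON") from exc
                obj.setdefault("weight", None)
                reports.append(_row_to_report(obj, i))
    else:
        raise ValueError(f"unknown format {format!r}")
    return reports


def write_reports(reports: Sequence[AdverseEventReport], path,
                  format: str = "tsv") -> None:
    """Write reports; set-valued fields are sorted for reproducible diffs."""
    if format == "tsv":
        rows = []
        for r in reports:
            rows.append({
                "report_id": r.report_id,
                "diseases": SET_DELIMITER.join(sorted(r.diseases)),
                "drugs": SET_DELIMITER.join(sorted(r.drugs)),
                "age": "" if r.age is None else r.age,
                "sex": "" if r.sex is None else r.sex,
                "weight": "" if r.weight is None else repr(r.weight),
                "qualification": r.qualification,
                "date": r.date,
                "adrs": SET_DELIMITER.join(sorted(r.adrs)),
            })
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in reports:
                fh.write(json.dumps({
                    "report_id": r.report_id,
                    "diseases": sorted(r.diseases),
                    "drugs": sorted(r.drugs),
                    "age": r.age,
                    "sex": r.sex,
                    "weight": r.weight,
                    "qualification": r.qualification,
                    "date": r.date,
                    "adrs": sorted(r.adrs),
                }) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def build_vocabulary(reports: Iterable[AdverseEventReport]) -> Vocabulary:
    """Index every distinct disease/drug/ADR ID, in lexicographic order.

    Deterministic under permutation of the input; call on the training
    split only so downstream label spaces stay leakage-free.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot build a vocabulary from zero reports")
    diseases: set[str] = set()
    drugs: set[str] = set()
    adrs: set[str] = set()
    for r in reports:
        diseases |= r.diseases
        drugs |= r.drugs
        adrs |= r.adrs
    index = lambda ids: {x: i for i, x in enumerate(sorted(ids))}
    return Vocabulary(index(diseases), index(drugs), index(adrs))


def split_cohort(reports: Sequence[AdverseEventReport],
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0,
                 ) -> tuple[list[AdverseEventReport], list[AdverseEventReport],
                            list[AdverseEventReport]]:
    """Random disjoint train/val/test partition, reproducible per seed."""
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(reports)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = [reports[i] for i in order[:n_train]]
    val = [reports[i] for i in order[n_train:n_train + n_val]]
    test = [reports[i] for i in order[n_train + n_val:]]
    return train, val, test
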