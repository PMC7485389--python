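"""Discharge-record parsing, validation, and age/sex stratification.

The unit of analysis is the discharge record ("case"), not the unique
patient: repeat admissions are kept as separate records. Each record
carries an age in whole years, a sex, and the set of ICD-10 codes
registered at discharge (principal diagnosis plus comorbidities). All
codes on a record are treated symmetrically when counting co-occurrence.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("record_id", "age", "sex", "icd10")

#: Dotted ICD-10 pattern: category letter + two digits, optional "." plus one
#: alphanumeric subcategory character ("X" is the registry's placeholder,
#: e.g. I10.X for essential hypertension).
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[A-Z0-9])?$")

#: Soft cap on codes per record: principal diagnosis plus up to five main
#: comorbidities in the source registry. Exceeding it logs a warning only.
DEFAULT_MAX_CODES = 6


class CodeCheck(NamedTuple):
    """Outcome of ICD-10 syntactic validation (rejection is a state, not an error)."""

    accepted: bool
    code: str
    reason: str | None = None


def validate_icd10(code: str) -> CodeCheck:
    """Normalize and syntactically validate one ICD-10 code.

    Accepted codes are whitespace-stripped and uppercased; they must match
    the dotted pattern ``L##`` or ``L##.C`` where L is a letter, # a digit
    and C an alphanumeric character. Idempotent on accepted codes.
    """
    if not isinstance(code, str) or not code.strip():
        return CodeCheck(False, str(code), "empty")
    norm = code.strip().upper()
    if _ICD10_RE.match(norm):
        return CodeCheck(True, norm)
    return CodeCheck(False, norm, "pattern")


@dataclass(frozen=True)
class DischargeRecord:
    record_id: str
    age: int
    sex: str  # "female" | "male" | "unknown"
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"record {self.record_id}: negative age {self.age}")
        if not self.codes:
            raise ValueError(f"record {self.record_id}: empty code set")


@dataclass
class RecordSet:
    """Validated, retained discharge records.

    ``n_records`` is the cohort size N that all co-occurrence statistics
    condition on. ``exclusions`` tallies dropped input records by reason so
    that n_input = n_records + sum(exclusions.values()).
    """

    records: list[DischargeRecord]
    provenance: str = ""
    exclusions: Counter = field(default_factory=Counter)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return self.n_records


@dataclass(frozen=True)
class AgeBracket:
    """Closed age interval [lo, hi]; ``hi=None`` marks the open-ended last bracket."""

    label: str
    lo: int
    hi: int | None

    def contains(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age <= self.hi)


def default_age_brackets() -> list[AgeBracket]:
    """Ten decade brackets 0-10, 11-20, ..., 81-90, and open-ended 91-100.

    The final bracket keeps the conventional "91-100" label but admits
    centenarians (91 years and over).
    """
    brackets = [AgeBracket("0-10", 0, 10)]
    for lo in range(11, 90, 10):
        brackets.append(AgeBracket(f"{lo}-{lo + 9}", lo, lo + 9))
    brackets.append(AgeBracket("91-100", 91, None))
    return brackets


def _check_partition(brackets: Sequence[AgeBracket]) -> None:
    ordered = sorted(brackets, key=lambda b: b.lo)
    if not ordered or ordered[0].lo != 0:
        raise ValueError("age brackets must start at 0")
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.hi is None or nxt.lo != prev.hi + 1:
            raise ValueError(
                f"age brackets must partition [0, inf): gap/overlap at {prev.label}/{nxt.label}"
            )
    if ordered[-1].hi is not None:
        raise ValueError("final age bracket must be open-ended")


_SEX_MAP = {
    "f": "female", "female": "female", "m": "male", "male": "male",
}


def normalize_sex(value: object) -> str:
    """Map free-form sex values to female/male; anything else becomes unknown."""
    if isinstance(value, str):
        return _SEX_MAP.get(value.strip().lower(), "unknown")
    return "unknown"


def parse_records(
    path,
    *,
    sep: str | None = None,
    max_codes: int = DEFAULT_MAX_CODES,
    provenance: str | None = None,
) -> RecordSet:
    """Read a long-format discharge table (one diagnosis row per line).

    Required columns: record_id, age, sex, icd10. Rows are grouped by
    record_id into one record each. Inclusion/exclusion:

    * rows with a blank/missing record_id, age, or icd10 → record excluded
      as ``incomplete``;
    * non-integer or negative age → ``invalid_age``;
    * syntactically invalid codes are discarded; a record left with no
      valid code → ``non_existing_code``;
    * more than ``max_codes`` distinct codes is a warning, not an error
      (the cap describes the source system, not a hard schema).

    Missing required columns or an empty file raise ``ValueError``.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"no data rows in {path}")

    exclusions: Counter = Counter()
    records: list[DischargeRecord] = []
    for rid, group in df.groupby("record_id", sort=False):
        if not str(rid).strip():
            exclusions["incomplete"] += 1
            continue
        ages = {a.strip() for a in group["age"]}
        sexes = {s.strip() for s in group["sex"]}
        if "" in ages or any(not c.strip() for c in group["icd10"]):
            exclusions["incomplete"] += 1
            continue
        try:
            age_vals = {int(a) for a in ages}
        except ValueError:
            exclusions["invalid_age"] += 1
            continue
        if len(age_vals) != 1 or len(sexes) != 1:
            # contradictory per-row demographics for one record id
            exclusions["incomplete"] += 1
            continue
        age = age_vals.pop()
        if age < 0:
            exclusions["invalid_age"] += 1
            continue
        codes = set()
        for raw in group["icd10"]:
            chk = validate_icd10(raw)
            if chk.accepted:
                codes.add(chk.code)
        if not codes:
            exclusions["non_existing_code"] += 1
            continue
        if len(codes) > max_codes:
            logger.warning("record %s carries %d codes (> %d)", rid, len(codes), max_codes)
        records.append(
            DischargeRecord(str(rid), age, normalize_sex(sexes.pop()), frozenset(codes))
        )

    rs = RecordSet(records, provenance=provenance or str(path), exclusions=exclusions)
    logger.info(
        "parsed %s: retained %d records, excluded %s", path, rs.n_records, dict(exclusions)
    )
    return rs


def stratify_by_age(rs: RecordSet, brackets: Sequence[AgeBracket] | None = None) -> dict[str, RecordSet]:
    """Split a RecordSet into per-bracket RecordSets (disjoint, exhaustive)."""
    brackets = list(brackets) if brackets is not None else default_age_brackets()
    _check_partition(brackets)
    out = {b.label: RecordSet([], provenance=f"{rs.provenance}[{b.label}]") for b in brackets}
    for rec in rs:
        for b in brackets:
            if b.contains(rec.age):
                out[b.label].records.append(rec)
                break
    return out


@dataclass(frozen=True)
class CodeRange:
    """An inclusive ICD-10 category range such as Q20-Q28 or I30-I52."""

    label: str
    lo: str
    hi: str

    def __post_init__(self) -> None:
        pat = re.compile(r"^[A-Z][0-9]{2}$")
        if not (pat.match(self.lo) and pat.match(self.hi)) or self.lo > self.hi:
            raise ValueError(f"malformed code range {self.label}: {self.lo}-{self.hi}")

    def matches(self, code: str) -> bool:
        return self.lo <= code[:3] <= self.hi


def parse_code_range(text: str, label: str | None = None) -> CodeRange:
    """Parse "Q20-Q28" (hyphen or en dash) into a CodeRange."""
    parts = re.split(r"[-–]", text.strip().upper())
    if len(parts) != 2:
        raise ValueError(f"malformed code range: {text!r}")
    return CodeRange(label or text.strip(), parts[0].strip(), parts[1].strip())


def prevalence_summary(
    rs: RecordSet,
    groups: Iterable[CodeRange | str],
    brackets: Sequence[AgeBracket] | None = None,
) -> pd.DataFrame:
    """Percent of records per sex x age-bracket cell whose codes hit each range.

    Returns a tidy DataFrame (sex, bracket, group, n_records, n_hit, percent);
    cells with no records are omitted.
    """
    brackets = list(brackets) if brackets is not None else default_age_brackets()
    ranges = [g if isinstance(g, CodeRange) else parse_code_range(g) for g in groups]
    strata = stratify_by_age(rs, brackets)
    rows = []
    for b in brackets:
        sub = strata[b.label]
        for sex in ("female", "male", "unknown"):
            cell = [r for r in sub if r.sex == sex]
            if not cell:
                continue
            for rng in ranges:
                hit = sum(1 for r in cell if any(rng.matches(c) for c in r.codes))
                rows.append(
                    {
                        "sex": sex,
                        "bracket": b.label,
                        "group": rng.label,
                        "n_records": len(cell),
                        "n_hit": hit,
                        "percent": 100.0 * hit / len(cell),
                    }
                )
    return pd.DataFrame(rows, columns=["sex", "bracket", "group", "n_records", "n_hit", "percent"])
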