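"""Usage census of curated tables and rare-term flagging.

The first step in auditing a curated dataset is simply counting: how
many distinct terms does each field use, and how often is each one
used.  Very low usage is an error signal — infrequently used terms in
a large curated corpus frequently turn out to be typos, abbreviation
drift, or mistaken picks from a long selection list — so the census
feeds a threshold-based rare-outlier flagger.  This is deliberate
threshold scrutiny, not a statistical outlier model: the flags are
candidates for human review, never auto-corrections.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from .model import OntoQCError

ValueKind = Literal["legacy-text", "curie"]

#: default thresholds, exposed in output headers for provenance
DEFAULT_MIN_COUNT = 3
DEFAULT_MIN_FRACTION = 0.001
DEFAULT_DELIMITER = ";"


class UnknownFieldError(OntoQCError, KeyError):
    def __init__(self, fieldname: str):
        super().__init__(f"field not in table: {fieldname}")


@dataclass
class CuratedTable:
    """A curated delimited table plus a spec of which columns matter.

    ``field_spec`` maps column name -> value kind: ``legacy-text`` for
    free-text home-made vocabulary columns, ``curie`` for columns that
    already hold ontology identifiers.  Empty strings are missing
    values.  Cells may pack multiple terms behind a delimiter.
    """

    df: pd.DataFrame
    field_spec: dict[str, ValueKind]
    provenance: str = "<memory>"
    id_field: str | None = None

    def __post_init__(self) -> None:
        for name in self.field_spec:
            if name not in self.df.columns:
                raise UnknownFieldError(name)
        self.df = self.df.fillna("")

    def __len__(self) -> int:
        return len(self.df)

    def record_ids(self) -> list[str]:
        if self.id_field and self.id_field in self.df.columns:
            return [str(v) for v in self.df[self.id_field]]
        return [str(i) for i in self.df.index]

    @classmethod
    def read(cls, path: str | Path, field_spec: dict[str, ValueKind],
             id_field: str | None = None) -> "CuratedTable":
        """Read a TSV/CSV file (delimiter inferred from the extension)."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        return cls(df=df, field_spec=field_spec, provenance=str(path),
                   id_field=id_field)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        self.df.to_csv(path, sep=sep, index=False)


@dataclass
class UsageCensus:
    """Exact multiset count of the non-missing values in one field."""

    field: str
    counts: dict[str, int]
    total: int
    missing: int = 0
    n_records: int = 0

    def fraction(self, term: str) -> float:
        return self.counts[term] / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "count": c,
             "fraction": c / self.total if self.total else 0.0}
            for t, c in sorted(self.counts.items(),
                               key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["term", "count", "fraction"])


@dataclass(frozen=True)
class RareTermFlag:
    term: str
    count: int
    fraction: float
    error_class: str = "rare-outlier"


def compute_census(table: CuratedTable, fieldname: str,
                   delimiter: str = DEFAULT_DELIMITER) -> UsageCensus:
    """Count how often each term value is used in ``fieldname``.

    Multi-valued cells are split on ``delimiter`` before counting; each
    packed term counts once.  Missing (empty) cells are never counted
    as terms — they are reported as a completeness statistic instead.
    """
    if fieldname not in table.field_spec:
        raise UnknownFieldError(fieldname)
    counts: Counter[str] = Counter()
    missing = 0
    for cell in table.df[fieldname]:
        cell = str(cell).strip()
        if not cell:
            missing += 1
            continue
        parts = [p.strip() for p in cell.split(delimiter)] if delimiter else [cell]
        counts.update(p for p in parts if p)
    return UsageCensus(field=fieldname, counts=dict(counts),
                       total=sum(counts.values()), missing=missing,
                       n_records=len(table))


def flag_rare_terms(census: UsageCensus,
                    min_count: int = DEFAULT_MIN_COUNT,
                    min_fraction: float = DEFAULT_MIN_FRACTION) -> list[RareTermFlag]:
    """Flag terms used fewer than ``min_count`` times or below
    ``min_fraction`` of the field's usage.

    Flags come back in deterministic order: ascending count, then
    lexicographic.  Raising either threshold can only add flags
    (monotone), never remove one.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    flags = [
        RareTermFlag(term=t, count=c, fraction=census.fraction(t))
        for t, c in census.counts.items()
        if c < min_count or census.fraction(t) < min_fraction
    ]
    flags.sort(key=lambda f: (f.count, f.term))
    return flags
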