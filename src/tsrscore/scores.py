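"""Observer score tables: per-case stroma percentages on the 10% grid.

Visual stroma estimation is recorded in increments of 10% per rater.  The
table also carries the majority consensus (or a ``needs_meeting`` flag when
all raters disagree) and the stroma-low/-high dichotomy at the 50% cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

NEEDS_MEETING = "needs_meeting"
STROMA_LOW = "stroma-low"
STROMA_HIGH = "stroma-high"

#: cut-off separating stroma-low (<= cut-off) from stroma-high (> cut-off)
DICHOTOMY_CUTOFF = 50.0


def dichotomize(percent: float, cutoff: float = DICHOTOMY_CUTOFF) -> str:
    """Classify a stroma percentage as stroma-low (<= cutoff) or stroma-high."""
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(f"stroma percent {percent} outside [0, 100]")
    return STROMA_LOW if percent <= cutoff else STROMA_HIGH


def _check_grid_score(value, where: str) -> int:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric score {value!r} in {where}") from None
    if not v.is_integer() or int(v) % 10 != 0 or not 0 <= v <= 100:
        raise ValidationError(
            f"score {value!r} in {where} is not a multiple of 10 in [0, 100]"
        )
    return int(v)


@dataclass
class ObserverTable:
    """Per-case, per-rater stroma percentages with consensus and dichotomy.

    ``data`` columns: ``case_id``, ``rater1..raterN``, ``consensus``
    (integer percent or ``needs_meeting``), ``dichotomy`` (present only for
    cases with a resolved consensus).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(self.data) and "case_id" not in cols:
            raise ValidationError("score table must contain a case_id column")
        for col in self.rater_columns:
            for i, v in self.data[col].items():
                _check_grid_score(v, f"column {col}, row {i}")
        if "consensus" in cols and "dichotomy" in cols:
            for _, row in self.data.iterrows():
                cons = row["consensus"]
                if cons == NEEDS_MEETING or pd.isna(cons):
                    continue
                expected = dichotomize(float(cons))
                if row["dichotomy"] != expected:
                    raise ValidationError(
                        f"case {row['case_id']}: dichotomy {row['dichotomy']!r} "
                        f"inconsistent with consensus {cons}"
                    )

    @property
    def rater_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("rater")]

    @property
    def n_cases(self) -> int:
        return len(self.data)

    def rater_scores(self) -> pd.DataFrame:
        """Case x rater matrix of percentages (float)."""
        return self.data[self.rater_columns].astype(float)

    def consensus_values(self, include_unresolved: bool = False) -> pd.Series:
        """Resolved consensus percentages; unresolved cases dropped unless asked."""
        if "consensus" not in self.data.columns:
            raise ValidationError("table has no consensus column")
        s = self.data.set_index("case_id")["consensus"]
        if include_unresolved:
            return s
        mask = s.apply(lambda v: v != NEEDS_MEETING and not pd.isna(v))
        return s[mask].astype(float)


def read_scores(path) -> ObserverTable:
    """Read an observer score table from CSV (empty file -> empty table)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if "consensus" in df.columns:
        def _norm(v):
            if pd.isna(v) or v == NEEDS_MEETING:
                return v
            return int(float(v))
        df["consensus"] = df["consensus"].apply(_norm)
    if "dichotomy" in df.columns:
        df["dichotomy"] = df["dichotomy"].fillna("")
    return ObserverTable(data=df)


def write_scores(table: ObserverTable, path) -> None:
    """Write an observer table to CSV (value-exact round-trip)."""
    table.data.to_csv(path, index=False)
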