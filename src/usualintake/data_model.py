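"""Domain types, long-format diary I/O, validation and descriptive summaries.

Daily food-diary data for an occasionally-consumed component are
*semicontinuous*: each person-day record carries a consumed amount in grams
that is exactly zero on non-consumption days and strictly positive otherwise.
The consumption indicator is therefore always *derived* from the amount
(``indicator = amount > 0``), never read from a file, so the two can never
disagree.

The descriptive summary mirrors the standard presentation of consumption
frequency: each person is assigned to one of five bins by the ratio of
consumption days to recorded days (0, (0, .25], (.25, .5], (.5, .75], > .75),
and per bin the median of person-mean amounts on consumption days is reported.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "FREQUENCY_BIN_LABELS",
    "IntakeDataset",
    "ConsumptionSummary",
    "SchemaError",
    "ValidationError",
    "read_intake_table",
    "write_intake_table",
    "describe_consumption",
    "consumption_ratios",
    "assign_frequency_bin",
]

#: Canonical column names of the long format (one row per person-day).
REQUIRED_COLUMNS = ("person_id", "day_index", "weekend", "amount")

#: Frequency-bin labels, printed exactly as in the descriptive table.
FREQUENCY_BIN_LABELS = (
    "0 records",
    ">0 and ≤0.25",
    ">0.25 and ≤0.5",
    ">0.5 and ≤0.75",
    ">0.75",
)


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """A record violates a dataset invariant (e.g. negative amount)."""


@dataclasses.dataclass(frozen=True)
class IntakeDataset:
    """Validated long-format daily intake records.

    Parameters
    ----------
    table
        One row per person-day with columns ``person_id``, ``day_index``,
        ``weekend`` (0/1), ``amount`` (grams, >= 0), ``indicator``
        (0/1, derived) and any number of covariate columns.
    covariate_names
        Ordered covariate columns shared by both model parts.
    """

    table: pd.DataFrame
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.table
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} is missing")
        for col in self.covariate_names:
            if col not in df.columns:
                raise SchemaError(f"covariate column {col!r} is missing")
        amount = pd.to_numeric(df["amount"], errors="coerce")
        bad = amount.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"non-numeric amount in row {df.index[row]}")
        neg = amount < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValidationError(
                f"negative amount {amount.iloc[row]} in row {df.index[row]}"
            )
        if not np.isfinite(amount).all():
            raise ValidationError("amounts must be finite")
        table = df.copy()
        table["amount"] = amount.astype(float)
        table["indicator"] = (table["amount"] > 0).astype(int)
        table["weekend"] = pd.to_numeric(table["weekend"]).astype(int)
        if not table["weekend"].isin((0, 1)).all():
            raise ValidationError("weekend must be a 0/1 indicator")
        day = pd.to_numeric(table["day_index"]).astype(int)
        if (day < 1).any():
            raise ValidationError("day_index must be >= 1")
        table["day_index"] = day
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @property
    def m(self) -> int:
        """Number of persons."""
        return self.table["person_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.table)

    def person_groups(self) -> "pd.core.groupby.DataFrameGroupBy":
        return self.table.groupby("person_id", sort=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntakeDataset):
            return NotImplemented
        if self.covariate_names != other.covariate_names:
            return False
        cols = list(REQUIRED_COLUMNS) + ["indicator", *self.covariate_names]
        a = self.table[cols].sort_values(["person_id", "day_index"]).reset_index(drop=True)
        b = other.table[cols].sort_values(["person_id", "day_index"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


def read_intake_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
    delimiter: str = ",",
    exclude_ids: Iterable | None = None,
) -> IntakeDataset:
    """Read a delimited person-day table into a validated :class:`IntakeDataset`.

    Parameters
    ----------
    schema
        Optional mapping from canonical column names (``person_id``,
        ``day_index``, ``weekend``, ``amount``, and covariates) to the column
        names used in the file. Unmapped names are taken verbatim.
    covariates
        Covariate columns (canonical names) to carry along.
    exclude_ids
        Optional person ids to drop before validation, e.g. a pre-computed
        under-reporter list. No plausibility screening is performed here.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=delimiter)
    rename = {}
    for canon in (*REQUIRED_COLUMNS, *covariates):
        source = schema.get(canon, canon)
        if source not in df.columns:
            raise SchemaError(
                f"column {source!r} (for {canon!r}) not found in {path}"
            )
        rename[source] = canon
    df = df.rename(columns=rename)
    if exclude_ids is not None:
        df = df[~df["person_id"].isin(set(exclude_ids))]
    if df.empty:
        raise ValidationError(f"no records left after exclusions in {path}")
    keep = [*REQUIRED_COLUMNS, *covariates]
    return IntakeDataset(df[keep].reset_index(drop=True), tuple(covariates))


def write_intake_table(
    dataset: IntakeDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write a dataset back to delimited text (round-trips with the reader)."""
    cols = [*REQUIRED_COLUMNS, *dataset.covariate_names]
    dataset.table[cols].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Descriptive summaries of consumption frequency and amount
# ---------------------------------------------------------------------------

def consumption_ratios(dataset: IntakeDataset) -> pd.Series:
    """Per person: consumption days / recorded days, indexed by person_id."""
    g = dataset.table.groupby("person_id", sort=True)["indicator"]
    return g.mean()


def assign_frequency_bin(ratio: float) -> str:
    """Map a consumption-day ratio in [0, 1] to its frequency-bin label.

    Upper bounds are closed: a ratio of exactly 0.25 falls in ">0 and <=0.25";
    exactly 0 has its own category.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    if ratio == 0:
        return FREQUENCY_BIN_LABELS[0]
    if ratio <= 0.25:
        return FREQUENCY_BIN_LABELS[1]
    if ratio <= 0.5:
        return FREQUENCY_BIN_LABELS[2]
    if ratio <= 0.75:
        return FREQUENCY_BIN_LABELS[3]
    return FREQUENCY_BIN_LABELS[4]


@dataclasses.dataclass(frozen=True)
class ConsumptionSummary:
    """Frequency-bin summary per stratum.

    ``table`` has one row per (stratum, bin): count, percentage (1 d.p.) of
    the stratum, and the median over persons in the bin of each person's mean
    amount on consumption days (NaN for the zero-records bin).
    """

    table: pd.DataFrame
    strata: str

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def describe_consumption(dataset: IntakeDataset, strata: str) -> ConsumptionSummary:
    """Summarise consumption frequency and amounts by a categorical covariate.

    Each person is assigned one frequency bin from their consumption-day
    ratio; per stratum the bin counts, percentages and median person-mean
    consumption-day amounts are tabulated.
    """
    df = dataset.table
    if strata not in df.columns:
        raise SchemaError(f"stratum column {strata!r} not found")
    per_person = df.groupby("person_id", sort=True).agg(
        ratio=("indicator", "mean"),
        stratum=(strata, "first"),
    )
    consumed = df[df["indicator"] == 1]
    mean_amt = consumed.groupby("person_id", sort=True)["amount"].mean()
    per_person["mean_amount"] = mean_amt.reindex(per_person.index)
    per_person["bin"] = [assign_frequency_bin(r) for r in per_person["ratio"]]

    rows = []
    for stratum, grp in per_person.groupby("stratum", sort=True):
        n_stratum = len(grp)
        for label in FREQUENCY_BIN_LABELS:
            sel = grp[grp["bin"] == label]
            count = len(sel)
            pct = round(100.0 * count / n_stratum, 1) if n_stratum else np.nan
            amounts = sel["mean_amount"].dropna()
            rows.append(
                {
                    "stratum": stratum,
                    "bin": label,
                    "count": count,
                    "percent": pct,
                    "median_amount": amounts.median() if len(amounts) else np.nan,
                }
            )
    return ConsumptionSummary(pd.DataFrame(rows), strata)
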