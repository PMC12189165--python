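"""Cohort table model: ingestion, validation, exclusion filtering, descriptives.

The unit of analysis is a specimen (one cranium) with known sex and age at
death, a lateral-angle measurement of the internal acoustic meatus (degrees,
may be missing) and the biauricular breadth (AUB, mm, may be missing).
Tables are flat delimited text with one row per specimen.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the cohort schema
COLUMNS = [
    "specimen_id",
    "collection",
    "sex",
    "age_years",
    "lateral_angle_deg",
    "aub_mm",
    "excluded_flag",
    "exclusion_reason",
]

REQUIRED_COLUMNS = ["specimen_id", "collection", "sex", "age_years"]

#: collections named in the study design; anything else maps to "other"
KNOWN_COLLECTIONS = ["Vienna", "Graz", "Terzer", "NMDID", "other"]

SEX_LABELS = ("F", "M")

#: measurement plausibility bounds (open intervals)
ANGLE_BOUNDS = (0.0, 90.0)
AUB_BOUNDS = (40.0, 180.0)

#: variables summarised by default, in report order
DEFAULT_VARIABLES = ["age_years", "lateral_angle_deg", "aub_mm"]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the specimen invariants."""


@dataclass(frozen=True)
class ExclusionRules:
    """Row-exclusion policy applied before analysis.

    Parameters
    ----------
    max_age_years
        Global upper age limit; the study design covers birth to 30 years.
    collection_age_caps
        Per-collection age caps on top of the global limit.  The Graz
        anatomical collection contributes only specimens up to 21 years:
        its older specimens form a separate cluster with unknown inclusion
        criteria and are dropped.
    drop_flagged
        Drop rows whose ``excluded_flag`` is set (trauma, pathology,
        missing scans).
    """

    max_age_years: float = 30.0
    collection_age_caps: Mapping[str, float] = field(
        default_factory=lambda: {"Graz": 21.0}
    )
    drop_flagged: bool = True

    def __post_init__(self):
        if self.max_age_years < 0:
            raise ValueError("max_age_years must be >= 0")
        for coll, cap in self.collection_age_caps.items():
            if coll not in KNOWN_COLLECTIONS:
                raise ValueError(f"age cap for unknown collection {coll!r}")
            if cap < 0:
                raise ValueError(f"age cap for {coll!r} must be >= 0")


@dataclass(frozen=True)
class ExclusionRecord:
    specimen_id: str
    rule: str
    detail: str


class CohortTable:
    """Validated cohort of specimen records, backed by a pandas DataFrame.

    Construct via :func:`read_cohort_table`, :meth:`from_frame`, or the
    synthetic generator.  The underlying frame always carries the full
    canonical schema (:data:`COLUMNS`); missing measurements are NaN.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col == "excluded_flag":
                    df[col] = False
                elif col == "exclusion_reason":
                    df[col] = ""
                else:
                    df[col] = np.nan
        df = df[COLUMNS].reset_index(drop=True)
        df["specimen_id"] = df["specimen_id"].astype(str)
        df["age_years"] = pd.to_numeric(df["age_years"])
        df["lateral_angle_deg"] = pd.to_numeric(df["lateral_angle_deg"])
        df["aub_mm"] = pd.to_numeric(df["aub_mm"])
        df["excluded_flag"] = (
            df["excluded_flag"].fillna(False).astype(bool)
        )
        df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
        self._df = df
        if validate:
            self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self._df
        bad_sex = ~df["sex"].isin(SEX_LABELS)
        if bad_sex.any():
            rows = df.index[bad_sex].tolist()
            vals = df.loc[bad_sex, "sex"].unique().tolist()
            raise CohortValidationError(
                f"unknown sex code(s) {vals} in row(s) {rows}; "
                f"allowed labels are {list(SEX_LABELS)}"
            )
        if df["age_years"].isna().any():
            rows = df.index[df["age_years"].isna()].tolist()
            raise CohortValidationError(f"missing age_years in row(s) {rows}")
        neg_age = df["age_years"] < 0
        if neg_age.any():
            rows = df.index[neg_age].tolist()
            raise CohortValidationError(f"negative age_years in row(s) {rows}")
        unknown = ~df["collection"].isin(KNOWN_COLLECTIONS)
        if unknown.any():
            vals = df.loc[unknown, "collection"].unique().tolist()
            warnings.warn(
                f"unknown collection(s) {vals} mapped to 'other'",
                stacklevel=3,
            )
            df.loc[unknown, "collection"] = "other"
        for col, (lo, hi) in [
            ("lateral_angle_deg", ANGLE_BOUNDS),
            ("aub_mm", AUB_BOUNDS),
        ]:
            vals = df[col]
            bad = vals.notna() & ~((vals > lo) & (vals < hi))
            if bad.any():
                rows = df.index[bad].tolist()
                raise CohortValidationError(
                    f"{col} outside ({lo}, {hi}) in row(s) {rows}; "
                    "missing values must be empty cells, not sentinels"
                )

    # -- construction / IO ---------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        return cls(df)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "CohortTable":
        return cls(pd.DataFrame(list(records)))

    def to_csv(self, path_or_buf=None, *, sep: str = ",") -> str | None:
        out = self._df.copy()
        out["excluded_flag"] = out["excluded_flag"].map(
            {True: "true", False: "false"}
        )
        return out.to_csv(path_or_buf, sep=sep, index=False)

    # -- accessors -----------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying frame (copy; mutate freely)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        n = len(self._df)
        colls = self._df["collection"].value_counts().to_dict()
        return f"CohortTable(n={n}, collections={colls})"

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self._df.loc[np.asarray(mask)], validate=False)


def read_cohort_table(source, *, sep: str | None = None,
                      decimal: str = ".") -> CohortTable:
    """Read a delimited-text cohort table and validate every row.

    Parameters
    ----------
    source
        Path, file object, or string of delimited text with a header row.
        Comma separation is the default; tab is accepted (``sep=None``
        sniffs between the two).
    sep, decimal
        Dialect overrides, as in :func:`pandas.read_csv`.

    Returns
    -------
    CohortTable
        Rows validated against the specimen invariants.  Missing
        measurements stay missing (empty cell -> NaN); out-of-range
        sentinels such as ``-1`` are rejected.

    Raises
    ------
    CohortValidationError
        Unknown sex code, negative age, or out-of-range measurement,
        naming the offending row(s).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if sep is None:
        df = pd.read_csv(source, sep=None, engine="python", decimal=decimal,
                         skipinitialspace=True)
    else:
        df = pd.read_csv(source, sep=sep, decimal=decimal)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s) {missing}")
    if "excluded_flag" in df.columns and df["excluded_flag"].dtype == object:
        df["excluded_flag"] = (
            df["excluded_flag"]
            .astype(str)
            .str.strip()
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False,
                  "nan": False, "": False})
        )
    return CohortTable(df)


def apply_exclusions(
    table: CohortTable, rules: ExclusionRules | None = None
) -> tuple[CohortTable, list[ExclusionRecord]]:
    """Filter a cohort by the study's exclusion rules.

    Each removed row is logged with the first rule it violates (rules are
    checked in a fixed order: flag, global age cap, per-collection cap);
    the retained set itself does not depend on rule order.  Idempotent.
    """
    if rules is None:
        rules = ExclusionRules()
    df = table.df
    log: list[ExclusionRecord] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        if rules.drop_flagged and row["excluded_flag"]:
            reason = row["exclusion_reason"] or "flagged"
            log.append(ExclusionRecord(row["specimen_id"], "flagged", reason))
            keep[i] = False
            continue
        if row["age_years"] > rules.max_age_years:
            log.append(ExclusionRecord(
                row["specimen_id"], "max_age",
                f"age {row['age_years']:g} > {rules.max_age_years:g}"))
            keep[i] = False
            continue
        cap = rules.collection_age_caps.get(row["collection"])
        if cap is not None and row["age_years"] > cap:
            log.append(ExclusionRecord(
                row["specimen_id"], "collection_age_cap",
                f"{row['collection']} age {row['age_years']:g} > {cap:g}"))
            keep[i] = False
    logger.info("exclusions: %d of %d rows removed", (~keep).sum(), len(df))
    return table.subset(keep), log


def summarize(
    table: CohortTable,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Descriptive statistics per (collection, sex, variable) stratum.

    Returns one row per stratum with ``n`` (non-missing count), ``mean``,
    ``sd`` (n-1 denominator), ``median``, ``min``, ``max``.  A stratum
    with a single observation reports sd as missing (the n-1 denominator
    is undefined); an empty stratum reports n=0 and missing statistics.
    Rows are ordered by collection (study order: Vienna, Graz, Terzer,
    NMDID, other) then sex (F before M) then variable.
    """
    if variables is None:
        variables = DEFAULT_VARIABLES
    if len(table) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = table.df
    coll_order = [c for c in KNOWN_COLLECTIONS if c in set(df["collection"])]
    rows = []
    for coll in coll_order:
        for sex in SEX_LABELS:
            stratum = df[(df["collection"] == coll) & (df["sex"] == sex)]
            for var in variables:
                vals = stratum[var].dropna().to_numpy(dtype=float)
                n = len(vals)
                if n == 0:
                    stats = dict(mean=np.nan, sd=np.nan, median=np.nan,
                                 min=np.nan, max=np.nan)
                else:
                    stats = dict(
                        mean=vals.mean(),
                        sd=vals.std(ddof=1) if n > 1 else np.nan,
                        median=float(np.median(vals)),
                        min=vals.min(),
                        max=vals.max(),
                    )
                rows.append({"collection": coll, "sex": sex, "variable": var,
                             "n": n, **stats})
    return pd.DataFrame(rows)
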