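"""Sighting records, validation, inclusion filters and the group-by-individual matrix.

The unit of observation is one row per (group sighting x individual): a dated
group of photo-identified animals, with per-individual attributes (sex, age
class) and per-group covariates (observed group size, number identified,
trammel-net-within-100-m flag).  All downstream analyses -- association
indices, permutation nulls, network metrics, community division and lagged
association rates -- consume the binary group-by-individual (GBI) matrix
built here under the gambit of the group: every member of a detected group is
taken to be associating with every other member.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SightingTable",
    "GroupByIndividual",
    "ResidenceProfile",
    "ExclusionReport",
    "ValidationError",
    "read_sightings",
    "write_sightings",
    "daily_dedup",
    "apply_inclusion_filters",
    "build_gbi",
    "residence_profiles",
    "RESIDENCE_BINS",
]

SEX_VALUES = ("F", "M", "UN")
AGE_VALUES = ("A", "J", "C")

#: residence classes by number of sightings: (label, lower, upper) inclusive
RESIDENCE_BINS = (
    ("very_frequent", 22, None),
    ("frequent", 14, 21),
    ("low_frequent", 10, 13),
    ("rare", 4, 9),
    ("occasional", 1, 3),
)

REQUIRED_COLUMNS = (
    "date",
    "group_id",
    "individual_id",
    "sex",
    "age_class",
    "group_size_observed",
    "n_identified",
    "trammel_net",
)


class ValidationError(ValueError):
    """Raised when a sighting table violates its structural invariants."""


@dataclass(frozen=True)
class SightingTable:
    """Long-format table of photo-identification group sightings.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per (group sighting, individual).  Mandatory columns:
        ``date`` (datetime64 day), ``group_id``, ``individual_id``, ``sex``
        (F/M/UN), ``age_class`` (A/J/C), ``group_size_observed``,
        ``n_identified``, ``trammel_net`` (bool).  An optional ``time`` column
        orders groups within a day.
    deduped : bool
        Whether :func:`daily_dedup` has been applied.
    """

    data: pd.DataFrame
    deduped: bool = False

    def __post_init__(self) -> None:
        validate_table(self.data)

    # -- convenience accessors -------------------------------------------
    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())

    @property
    def dates(self) -> list:
        return sorted(self.data["date"].unique())

    @property
    def n_groups(self) -> int:
        return self.data.groupby(["date", "group_id"]).ngroups

    def sighting_counts(self) -> pd.Series:
        """Number of group memberships per individual."""
        return self.data["individual_id"].value_counts().sort_index()

    def attributes(self) -> pd.DataFrame:
        """Per-individual (sex, age_class), one row per individual."""
        return (
            self.data.groupby("individual_id")[["sex", "age_class"]]
            .first()
            .sort_index()
        )

    def with_data(self, data: pd.DataFrame, **kw) -> "SightingTable":
        kw.setdefault("deduped", self.deduped)
        return SightingTable(data.reset_index(drop=True), **kw)


def validate_table(df: pd.DataFrame) -> None:
    """Check structural invariants; raise :class:`ValidationError` naming offenders."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory columns: {missing}")

    bad_sex = sorted(set(df["sex"].unique()) - set(SEX_VALUES))
    if bad_sex:
        raise ValidationError(f"invalid sex values {bad_sex}; expected {SEX_VALUES}")
    bad_age = sorted(set(df["age_class"].unique()) - set(AGE_VALUES))
    if bad_age:
        raise ValidationError(
            f"invalid age_class values {bad_age}; expected {AGE_VALUES}"
        )

    if (df["n_identified"] > df["group_size_observed"]).any():
        rows = df.index[df["n_identified"] > df["group_size_observed"]].tolist()
        raise ValidationError(f"n_identified > group_size_observed at rows {rows}")
    if (df["group_size_observed"] < 1).any():
        raise ValidationError("group_size_observed must be >= 1")

    # each individual at most once per (date, group)
    dup = df.duplicated(subset=["date", "group_id", "individual_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate individual within a group at rows {df.index[dup].tolist()}"
        )

    # sex / age constant per individual
    for col in ("sex", "age_class"):
        nun = df.groupby("individual_id")[col].nunique()
        bad = nun.index[nun > 1].tolist()
        if bad:
            raise ValidationError(
                f"contradictory {col} for individual(s) {bad}: "
                f"attribute must be constant across the table"
            )

    # group covariates constant per (date, group)
    for col in ("group_size_observed", "n_identified", "trammel_net"):
        nun = df.groupby(["date", "group_id"])[col].nunique()
        bad = nun.index[nun > 1].tolist()
        if bad:
            raise ValidationError(f"inconsistent {col} within group(s) {bad}")

    # can't identify more members than claimed identified
    sizes = df.groupby(["date", "group_id"]).agg(
        n_rows=("individual_id", "size"), n_id=("n_identified", "first")
    )
    bad = sizes.index[sizes["n_rows"] > sizes["n_id"]].tolist()
    if bad:
        raise ValidationError(
            f"more member rows than n_identified for group(s) {bad}"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sightings(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    attribute_overrides: Mapping[str, Mapping[str, str]] | None = None,
) -> SightingTable:
    """Read a delimited sighting table.

    Parameters
    ----------
    path : str or file-like
        CSV (UTF-8, header row, ISO-8601 dates).
    dialect : mapping, optional
        Maps file column names to the canonical names in
        :data:`REQUIRED_COLUMNS` (e.g. ``{"ID": "individual_id"}``).
    attribute_overrides : mapping, optional
        ``{individual_id: {"sex": ..., "age_class": ...}}`` applied after the
        file is read.  This is the supported route for analysis-time edits
        such as reclassifying estimated-sex animals to unknown, keeping the
        raw file untouched.
    """
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"missing mandatory columns after mapping: {missing}; "
            f"file has {list(df.columns)}"
        )
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    df["group_id"] = df["group_id"].astype(str)
    df["individual_id"] = df["individual_id"].astype(str)
    df["trammel_net"] = df["trammel_net"].astype(bool)
    df["group_size_observed"] = df["group_size_observed"].astype(int)
    df["n_identified"] = df["n_identified"].astype(int)
    if attribute_overrides:
        for ind, attrs in attribute_overrides.items():
            mask = df["individual_id"] == ind
            for col, val in attrs.items():
                df.loc[mask, col] = val
    return SightingTable(df.reset_index(drop=True))


def write_sightings(table: SightingTable, path, sep: str = ",") -> None:
    """Write a sighting table as delimited text (ISO dates)."""
    df = table.data.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# daily de-duplication
# ---------------------------------------------------------------------------

def daily_dedup(table: SightingTable) -> SightingTable:
    """Keep only each individual's first group sighting per day.

    Repeated sightings of the same animal within a day are serially
    autocorrelated, so only the first is retained.  "First" is resolved by an
    explicit ``time`` column when present, else lexicographic ``group_id``.
    Other individuals' memberships in later groups are unaffected.
    Idempotent.
    """
    df = table.data
    order_cols = ["date"] + (["time"] if "time" in df.columns else []) + ["group_id"]
    ordered = df.sort_values(order_cols, kind="stable")
    keep = ~ordered.duplicated(subset=["date", "individual_id"], keep="first")
    out = ordered[keep].sort_index().reset_index(drop=True)
    return SightingTable(out, deduped=True)


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Record of every row/group/individual removed by the inclusion filters."""

    groups_low_identified: list = field(default_factory=list)
    calves: list = field(default_factory=list)
    below_min_sightings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for date, gid in self.groups_low_identified:
            rows.append(("group_low_identified_fraction", str(date), gid))
        for ind in self.calves:
            rows.append(("calf_excluded", "", ind))
        for ind in self.below_min_sightings:
            rows.append(("below_min_sightings", "", ind))
        return pd.DataFrame(rows, columns=["reason", "date", "excluded"])


def apply_inclusion_filters(
    table: SightingTable,
    min_sightings: int = 6,
    exclude_calves: bool = True,
    large_group_size: int = 8,
    min_identified_frac: float = 0.8,
) -> tuple[SightingTable, ExclusionReport]:
    """Apply the analysis inclusion rules, in a fixed single pass.

    Order: (1) drop large groups (> ``large_group_size`` animals) in which
    fewer than ``min_identified_frac`` of members were photo-identified,
    (2) drop calves (dependent on their mothers), (3) drop individuals with
    fewer than ``min_sightings`` remaining group sightings.  The pass is not
    iterated: per-individual totals are fixed after one sweep.

    Requires a de-duplicated table (one sighting per individual per day).
    """
    if not table.deduped:
        raise ValidationError(
            "apply daily_dedup before the inclusion filters "
            "(per-day duplicate sightings bias the association index)"
        )
    df = table.data
    report = ExclusionReport()

    # 1. group photographic-quality rule
    frac = df["n_identified"] / df["group_size_observed"]
    bad_group = (df["group_size_observed"] > large_group_size) & (
        frac < min_identified_frac
    )
    bad_keys = set(
        map(tuple, df.loc[bad_group, ["date", "group_id"]].drop_duplicates().values)
    )
    report.groups_low_identified = sorted(bad_keys)
    keys = list(map(tuple, df[["date", "group_id"]].values))
    df = df[[k not in bad_keys for k in keys]]

    # 2. calves
    if exclude_calves:
        calves = sorted(df.loc[df["age_class"] == "C", "individual_id"].unique())
        report.calves = calves
        df = df[df["age_class"] != "C"]

    # 3. minimum sighting count
    counts = df["individual_id"].value_counts()
    low = sorted(counts.index[counts < min_sightings])
    report.below_min_sightings = low
    df = df[~df["individual_id"].isin(low)]

    if df.empty:
        raise ValidationError("no analysable individuals remain after filtering")
    return table.with_data(df), report


# ---------------------------------------------------------------------------
# group-by-individual matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupByIndividual:
    """Binary occurrence matrix: rows = group sightings, columns = individuals.

    ``periods`` maps each row to its daily sampling period (the date);
    permutation nulls swap individuals only between groups of the same
    period.  ``row_covariates`` carries per-group covariates and
    ``column_attributes`` per-individual sex / age class.
    """

    matrix: np.ndarray                      # (n_groups, n_individuals) of 0/1
    individuals: tuple[str, ...]
    periods: np.ndarray                     # (n_groups,) datetime64[D]
    row_covariates: pd.DataFrame            # group_size_observed, n_identified, trammel_net
    column_attributes: pd.DataFrame         # sex, age_class indexed by individual

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or not np.isin(m, (0, 1)).all():
            raise ValidationError("GBI matrix must be 2-D with entries in {0,1}")
        if m.shape[1] != len(self.individuals):
            raise ValidationError("column count does not match individual labels")
        if m.shape[0] != len(self.periods):
            raise ValidationError("row count does not match period labels")

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    def sighting_counts(self) -> np.ndarray:
        """Per-individual number of group sightings (column sums)."""
        return self.matrix.sum(axis=0)

    def period_indices(self) -> np.ndarray:
        """Integer period id per row, in chronological order."""
        uniq = np.unique(self.periods)
        return np.searchsorted(uniq, self.periods)

    def subset_rows(self, mask: np.ndarray) -> "GroupByIndividual":
        """GBI restricted to the selected group rows (columns unchanged)."""
        mask = np.asarray(mask)
        return GroupByIndividual(
            self.matrix[mask],
            self.individuals,
            self.periods[mask],
            self.row_covariates.iloc[np.flatnonzero(mask)
                                     if mask.dtype == bool else mask].reset_index(drop=True),
            self.column_attributes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, columns=list(self.individuals),
            index=pd.Index(self.periods, name="date"),
        )


def build_gbi(table: SightingTable) -> GroupByIndividual:
    """Build the binary group-by-individual matrix from a (filtered) table.

    Rows are ordered by (date, time-if-present, group_id); columns by sorted
    individual id, so identical inputs give identical matrices.
    """
    df = table.data
    inds = sorted(df["individual_id"].unique())
    col = {ind: j for j, ind in enumerate(inds)}
    order_cols = ["date"] + (["time"] if "time" in df.columns else []) + ["group_id"]
    groups = df.sort_values(order_cols, kind="stable").groupby(
        ["date", "group_id"], sort=True
    )
    n = groups.ngroups
    mat = np.zeros((n, len(inds)), dtype=np.int8)
    periods = np.empty(n, dtype="datetime64[D]")
    cov_rows = []
    for r, ((date, gid), sub) in enumerate(groups):
        for ind in sub["individual_id"]:
            mat[r, col[ind]] = 1
        periods[r] = np.datetime64(pd.Timestamp(date).date(), "D")
        cov_rows.append(
            {
                "date": date,
                "group_id": gid,
                "group_size_observed": int(sub["group_size_observed"].iloc[0]),
                "n_identified": int(sub["n_identified"].iloc[0]),
                "trammel_net": bool(sub["trammel_net"].iloc[0]),
            }
        )
    covs = pd.DataFrame(cov_rows)
    attrs = table.attributes().loc[inds]
    return GroupByIndividual(mat, tuple(inds), periods, covs, attrs)


def write_gbi(gbi: GroupByIndividual, path, sep: str = ",") -> None:
    """Dense labelled 0/1 matrix as delimited text."""
    gbi.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# residence profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidenceProfile:
    individual_id: str
    n_sightings: int
    residence_class: str
    annual_residence: Mapping[int, float]
    pct_with_trammel: float
    pct_large_groups: float


def residence_class(n_sightings: int) -> str:
    for label, lo, hi in RESIDENCE_BINS:
        if n_sightings >= lo and (hi is None or n_sightings <= hi):
            return label
    raise ValueError(f"no residence class for {n_sightings} sightings")


def residence_profiles(
    table: SightingTable, pooled_mean_group_size: float | None = None
) -> list[ResidenceProfile]:
    """Per-individual residency summaries.

    ``annual_residence`` is the individual's share of that year's sightings:
    (individual's sightings in year y) / (total sighting rows in year y).
    ``pct_large_groups`` uses the pooled mean group size as cut-off; by
    default it is computed from this table (one size per group sighting),
    never hard-coded.
    """
    df = table.data
    if pooled_mean_group_size is None:
        pooled_mean_group_size = float(
            df.groupby(["date", "group_id"])["group_size_observed"].first().mean()
        )
    years = pd.to_datetime(df["date"]).dt.year
    total_by_year = years.value_counts()
    profiles = []
    for ind, sub in df.assign(year=years).groupby("individual_id"):
        n = len(sub)
        annual = {
            int(y): float(c / total_by_year[y])
            for y, c in sub["year"].value_counts().items()
        }
        profiles.append(
            ResidenceProfile(
                individual_id=str(ind),
                n_sightings=n,
                residence_class=residence_class(n),
                annual_residence=annual,
                pct_with_trammel=float(sub["trammel_net"].mean()),
                pct_large_groups=float(
                    (sub["group_size_observed"] > pooled_mean_group_size).mean()
                ),
            )
        )
    return profiles
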