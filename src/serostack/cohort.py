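"""Cohort data model and delimited-table I/O.

A cohort is one row per serum sample: subject/sample identifiers, case/control
status, time-to-diagnosis at draw (months, cases only), clinical covariates
(age at draw, BMI, HRT use, OCP use, diabetes, sex) and a panel of biomarker
concentrations.  Concentrations below the assay limit of detection arrive as a
LOW token; they are kept as flags until explicitly imputed.

Time-to-diagnosis is discretised into single year groups 0-1, 1-2, 2-3, 3-4,
4+ (half-open intervals [a, b) in years) and joined groups 0-1 .. 0-4+, the
union of the first g single groups.  Controls have no diagnosis date and are
eligible for every group.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortError",
    "TableDialect",
    "TimeGroupScheme",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "impute_low",
    "assign_time_groups",
    "stratified_split",
    "build_design",
]

#: canonical covariate column names (all optional except status)
COVARIATES = ("age", "bmi", "hrt", "ocp", "diabetes", "sex")
BINARY_COVARIATES = ("hrt", "ocp", "diabetes")

SINGLE_GROUPS = ("0-1", "1-2", "2-3", "3-4", "4+")
JOINED_GROUPS = ("0-1", "0-2", "0-3", "0-4", "0-4+")


class CohortError(ValueError):
    """Schema, parse or validation failure on cohort data."""


@dataclass(frozen=True)
class TableDialect:
    """Column roles of a delimited cohort table.

    ``marker_cols`` may be an explicit list; if None, every column that is not
    an identifier, the status/ytd column or a covariate is taken as a marker.
    """

    status_col: str = "status"
    ytd_col: str = "ytd_months"
    subject_col: str = "subject_id"
    sample_col: str = "sample_id"
    marker_cols: tuple[str, ...] | None = None
    marker_prefix: str | None = None
    covariate_cols: tuple[str, ...] = COVARIATES
    low_token: str = "low"
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path) -> "TableDialect":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        for key in ("marker_cols", "covariate_cols"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


@dataclass(frozen=True)
class TimeGroupScheme:
    """Single [a, b) year intervals and their cumulative joined groups."""

    single_edges: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, np.inf)
    single_names: tuple[str, ...] = SINGLE_GROUPS
    joined_names: tuple[str, ...] = JOINED_GROUPS

    def single_group(self, ytd_months: float) -> str:
        if ytd_months < 0:
            raise CohortError(f"negative time-to-diagnosis: {ytd_months}")
        years = ytd_months / 12.0
        idx = int(np.searchsorted(self.single_edges, years, side="right")) - 1
        return self.single_names[min(idx, len(self.single_names) - 1)]

    def singles_in_joined(self, joined: str) -> tuple[str, ...]:
        g = self.joined_names.index(joined)
        return self.single_names[: g + 1]


@dataclass
class Cohort:
    """A validated cohort table.

    ``df`` holds numeric marker columns (LOW cells as NaN) and covariates;
    ``low_mask`` marks which NaNs are LOW flags rather than true missing.
    """

    df: pd.DataFrame
    marker_cols: list[str]
    low_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.low_mask is None:
            self.low_mask = pd.DataFrame(
                False, index=self.df.index, columns=self.marker_cols
            )

    # -- basic accessors -------------------------------------------------
    @property
    def status(self) -> pd.Series:
        return self.df["status"]

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == 0).sum())

    def subset(self, mask) -> "Cohort":
        return Cohort(
            self.df.loc[mask].copy(),
            list(self.marker_cols),
            self.low_mask.loc[mask].copy(),
        )

    def time_group_subset(self, joined: str, scheme: TimeGroupScheme | None = None) -> "Cohort":
        """Cases of the joined group plus all controls (controls are shared)."""
        scheme = scheme or TimeGroupScheme()
        if "time_group" not in self.df.columns:
            raise CohortError("assign_time_groups must be called first")
        singles = set(scheme.singles_in_joined(joined))
        mask = (self.df["status"] == 0) | self.df["time_group"].isin(singles)
        return self.subset(mask)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.marker_cols == other.marker_cols
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
            and self.low_mask.reset_index(drop=True).equals(
                other.low_mask.reset_index(drop=True)
            )
        )


def _validate(df: pd.DataFrame, markers: list[str]) -> None:
    if not df["status"].isin([0, 1]).all():
        raise CohortError("status column must be binary 0/1")
    if "age" in df.columns:
        ages = df["age"].dropna()
        if ((ages < 18) | (ages > 120)).any():
            raise CohortError("age_at_draw outside plausibility window [18, 120]")
    if "ytd_months" in df.columns:
        ytd = df["ytd_months"].dropna()
        if (ytd < 0).any():
            raise CohortError("negative ytd_months")


def read_cohort(path_or_buf, dialect: TableDialect = TableDialect()) -> Cohort:
    """Read a delimited cohort table, preserving LOW flags and row order."""
    df = pd.read_csv(path_or_buf, sep=dialect.delimiter, dtype=str)
    for col in (dialect.status_col, dialect.sample_col):
        if col not in df.columns:
            raise CohortError(f"missing mandatory column: {col!r}")
    rename = {
        dialect.status_col: "status",
        dialect.ytd_col: "ytd_months",
        dialect.subject_col: "subject_id",
        dialect.sample_col: "sample_id",
    }
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})

    reserved = {"status", "ytd_months", "subject_id", "sample_id", "time_group"}
    reserved |= set(dialect.covariate_cols)
    if dialect.marker_cols is not None:
        markers = list(dialect.marker_cols)
    elif dialect.marker_prefix is not None:
        markers = [c for c in df.columns if c.startswith(dialect.marker_prefix)]
    else:
        markers = [c for c in df.columns if c not in reserved]

    low_mask = pd.DataFrame(False, index=df.index, columns=markers)
    for m in markers:
        cells = df[m].astype(str).str.strip()
        is_low = cells.str.lower() == dialect.low_token.lower()
        low_mask[m] = is_low
        numeric = pd.to_numeric(cells.where(~is_low), errors="coerce")
        bad = numeric.isna() & ~is_low & ~cells.isin(["", "nan", "None"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"non-numeric marker cell in column {m!r} at row {row}: "
                f"{cells.iloc[row]!r}"
            )
        if (numeric.dropna() < 0).any():
            raise CohortError(f"negative concentration in marker {m!r}")
        df[m] = numeric

    df["status"] = pd.to_numeric(df["status"], errors="raise").astype(int)
    for col in ("ytd_months", "age", "bmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("hrt", "ocp", "diabetes", "sex"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip().str.lower().replace(
                {"nan": np.nan, "": np.nan, "none": np.nan}
            )
    if "time_group" in df.columns:
        df["time_group"] = df["time_group"].replace({"nan": np.nan, "": np.nan})
    _validate(df, markers)
    return Cohort(df.reset_index(drop=True), markers, low_mask.reset_index(drop=True))


def write_cohort(cohort: Cohort, path_or_buf, dialect: TableDialect = TableDialect()) -> None:
    """Write a cohort back to delimited text, re-emitting LOW tokens."""
    out = cohort.df.copy()
    for m in cohort.marker_cols:
        col = out[m].astype(object)
        col[cohort.low_mask[m].to_numpy()] = dialect.low_token
        out[m] = col
    out.to_csv(path_or_buf, sep=dialect.delimiter, index=False)


def impute_low(cohort: Cohort, rule: str = "half_min", floor: float | None = None) -> Cohort:
    """Replace LOW flags: half the observed per-marker minimum, or a fixed floor.

    ``rule`` is ``"half_min"`` or ``"fixed_floor"`` (with ``floor`` given).
    """
    df = cohort.df.copy()
    for m in cohort.marker_cols:
        low = cohort.low_mask[m].to_numpy()
        if not low.any():
            continue
        if rule == "half_min":
            observed = df[m].to_numpy(dtype=float)[~low]
            observed = observed[~np.isnan(observed)]
            if observed.size == 0:
                raise CohortError(
                    f"marker {m!r}: all values below LOD, no observed minimum"
                )
            value = float(observed.min()) / 2.0
        elif rule == "fixed_floor":
            if floor is None:
                raise CohortError("fixed_floor rule requires a floor value")
            value = float(floor)
        else:
            raise CohortError(f"unknown imputation rule {rule!r}")
        col = df[m].to_numpy(dtype=float)
        col[low] = value
        df[m] = col
    low_mask = pd.DataFrame(False, index=df.index, columns=cohort.marker_cols)
    return Cohort(df, list(cohort.marker_cols), low_mask)


def assign_time_groups(cohort: Cohort, scheme: TimeGroupScheme = TimeGroupScheme()) -> Cohort:
    """Label each case sample with its single time-group; controls get NaN."""
    df = cohort.df.copy()
    cases = df["status"] == 1
    if "ytd_months" not in df.columns or df.loc[cases, "ytd_months"].isna().any():
        raise CohortError("every case sample needs ytd_months to assign time-groups")
    groups = np.full(len(df), np.nan, dtype=object)
    for i in np.flatnonzero(cases.to_numpy()):
        groups[i] = scheme.single_group(float(df["ytd_months"].iloc[i]))
    df["time_group"] = groups
    return Cohort(df, list(cohort.marker_cols), cohort.low_mask.copy())


def _quartile(values: pd.Series) -> np.ndarray:
    """Quartile index 0..3 on the combined table; ties go to the lower quartile."""
    v = values.to_numpy(dtype=float)
    out = np.zeros(len(v), dtype=int)
    ok = ~np.isnan(v)
    if ok.sum() >= 4:
        qs = np.nanquantile(v, [0.25, 0.5, 0.75])
        out[ok] = np.searchsorted(qs, v[ok], side="left")
    return out


def stratified_split(
    cohort: Cohort,
    frac_train: float = 2.0 / 3.0,
    keys: tuple[str, ...] = ("status", "time_group", "age", "bmi", "hrt", "ocp", "diabetes"),
    seed: int = 0,
    min_stratum: int = 3,
) -> pd.Series:
    """Assign each sample to 'train' or 'test', stratified on ``keys``.

    Continuous keys (age, bmi) are stratified by combined-table quartile.
    Fully crossed strata smaller than ``min_stratum`` are coarsened to the
    primary keys (status, time-group) so that rare covariate combinations do
    not drain one partition of cases.  Per stratum, round(frac_train * size)
    samples go to train; remaining singleton strata go to train.  Returns a
    Series indexed like the cohort with values 'train'/'test'.
    """
    if not 0 < frac_train < 1:
        raise CohortError("frac_train must be in (0, 1)")
    df = cohort.df
    if len(df) == 0:
        raise CohortError("cannot split an empty cohort")
    parts = []
    for key in keys:
        if key not in df.columns:
            continue
        if key in ("age", "bmi"):
            parts.append(pd.Series(_quartile(df[key]), index=df.index).astype(str))
        else:
            parts.append(df[key].astype(str).fillna("NA"))
    stratum = parts[0]
    for p in parts[1:]:
        stratum = stratum + "|" + p
    coarse_keys = [k for k in ("status", "time_group") if k in keys]
    if coarse_keys and len(parts) > len(coarse_keys):
        coarse = df[coarse_keys[0]].astype(str).fillna("NA")
        for k in coarse_keys[1:]:
            coarse = coarse + "|" + df[k].astype(str).fillna("NA")
        sizes = stratum.map(stratum.value_counts())
        stratum = stratum.where(sizes >= min_stratum, "small|" + coarse)

    rng = np.random.default_rng(seed)
    assignment = pd.Series("test", index=df.index)
    for _, idx in sorted(stratum.groupby(stratum).groups.items()):
        idx = np.asarray(idx)
        n = len(idx)
        n_train = max(1, int(np.floor(frac_train * n + 0.5))) if n > 1 else 1
        chosen = rng.choice(idx, size=min(n_train, n), replace=False)
        assignment.loc[chosen] = "train"
    return assignment


def build_design(
    cohort: Cohort, panel: list[str], require_complete: bool = True
) -> pd.DataFrame:
    """Numeric design matrix for a feature panel (markers + covariates).

    Binary covariates are encoded yes=1/no=0; sex male=1/female=0.  LOW flags
    must have been imputed for any marker in the panel.  Missing values raise
    unless ``require_complete`` is False.
    """
    cols = {}
    for f in panel:
        if f in cohort.marker_cols:
            if cohort.low_mask[f].any():
                raise CohortError(f"marker {f!r} still has LOW flags; impute first")
            cols[f] = cohort.df[f].astype(float)
        elif f in ("age", "bmi"):
            if f not in cohort.df.columns:
                raise CohortError(f"missing panel feature: {f!r}")
            cols[f] = cohort.df[f].astype(float)
        elif f in BINARY_COVARIATES:
            if f not in cohort.df.columns:
                raise CohortError(f"missing panel feature: {f!r}")
            cols[f] = cohort.df[f].map({"yes": 1.0, "no": 0.0})
        elif f == "sex":
            cols[f] = cohort.df[f].map({"male": 1.0, "female": 0.0})
        else:
            raise CohortError(f"missing panel feature: {f!r}")
    X = pd.DataFrame(cols, index=cohort.df.index)[panel]
    if require_complete and X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise CohortError(f"panel features with missing values: {bad}")
    return X
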