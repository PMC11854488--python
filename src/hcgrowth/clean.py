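"""Data selection for growth-reference construction.

Implements the cleaning rules typical of national anthropometric extracts:
keep healthy children only, drop exact duplicate rows, compute exact
calendar ages, restrict to the chart's age window, and exclude gross
outliers whose z-score against an *external* reference chart exceeds +5 or
falls below -5 (strict inequalities: boundary values are retained).
Cleaning against an external reference rather than the data being fitted
avoids circularity.

The cleaned data are binned into 120-day age intervals by sex with per-bin
counts and mean HC, and a Mann-Whitney rank-sum test compares HC between
the sexes (exact by enumeration for combined n <= 10, tie-corrected normal
approximation otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CleanConfig",
    "CleanReport",
    "compute_age_days",
    "standardize_units",
    "filter_health",
    "deduplicate",
    "flag_outliers",
    "bin_and_summarize",
    "ranksum_sex_test",
    "clean_pipeline",
]


@dataclass(frozen=True)
class CleanConfig:
    z_limit: float = 5.0
    bin_width_days: int = 120
    max_age_days: int = 1800

    def __post_init__(self) -> None:
        if self.z_limit <= 0:
            raise ValueError("z_limit must be positive")
        if self.bin_width_days < 1:
            raise ValueError("bin_width_days must be >= 1")


@dataclass
class CleanReport:
    """Dispositions partition the input: counts always sum to the input size."""

    retained: int
    removed_duplicate: int
    removed_outlier: int
    removed_unhealthy: int
    removed_age_range: int
    bin_summary: pd.DataFrame = field(repr=False)

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.removed_duplicate
            + self.removed_outlier
            + self.removed_unhealthy
            + self.removed_age_range
        )

    def counts(self) -> dict[str, int]:
        return {
            "retained": self.retained,
            "removed_duplicate": self.removed_duplicate,
            "removed_outlier": self.removed_outlier,
            "removed_unhealthy": self.removed_unhealthy,
            "removed_age_range": self.removed_age_range,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"counts": self.counts()}, fh, sort_keys=False)


def compute_age_days(birth_date, measurement_date):
    """Exact calendar-day difference; vectorized over pandas Series."""
    b = pd.to_datetime(birth_date)
    m = pd.to_datetime(measurement_date)
    age = (m - b).days if not isinstance(b, pd.Series) else (m - b).dt.days
    if isinstance(age, pd.Series):
        if (age < 0).any():
            bad = age.index[age < 0].tolist()
            raise ValueError(f"measurement before birth at rows {bad}")
        return age.astype(int)
    if age < 0:
        raise ValueError(
            f"measurement {measurement_date} precedes birth {birth_date}"
        )
    return int(age)


def standardize_units(raw_value, unit: str) -> float:
    """Express a head-circumference reading in cm (accepts cm or mm)."""
    try:
        v = float(raw_value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric measurement {raw_value!r}") from exc
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"measurement must be positive, got {raw_value!r}")
    if unit == "cm":
        return v
    if unit == "mm":
        return v / 10.0
    raise ValueError(f"unknown unit {unit!r}")


def filter_health(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows flagged healthy; missing flags are conservatively excluded."""
    flag = df["health_flag"]
    kept_mask = flag.eq("healthy").fillna(False)
    return df[kept_mask], df[~kept_mask]


def deduplicate(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop exact-duplicate rows (all fields equal), keeping first occurrence.

    Rows agreeing on child and date but differing in HC are *not* duplicates
    and are both kept.
    """
    dup_mask = df.duplicated(keep="first")
    return df[~dup_mask], df[dup_mask]


def flag_outliers(
    df: pd.DataFrame, reference, config: CleanConfig = CleanConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows by reference z-score: removed iff z > +z_limit or z < -z_limit.

    ``reference`` is a :class:`hcgrowth.charts.ReferenceChart`; L, M, S are
    linearly interpolated at each record's exact age.  Boundary values
    (z exactly +/- z_limit) are retained.  Ages outside the reference's
    coverage raise a ValueError listing the offending rows.
    """
    if df.empty:
        return df, df
    z = np.empty(len(df))
    ages = df["age_days"].to_numpy(dtype=float)
    for sex in df["sex"].unique():
        m = (df["sex"] == sex).to_numpy()
        lo, hi = reference.age_range(sex)
        bad = m & ((ages < lo) | (ages > hi))
        if bad.any():
            raise ValueError(
                f"ages outside reference coverage [{lo}, {hi}] for sex "
                f"{sex!r} at rows {df.index[bad].tolist()}"
            )
        z[m] = reference.zscore(
            df.loc[m, "hc_cm"].to_numpy(dtype=float), ages[m], sex
        )
    removed_mask = (z > config.z_limit) | (z < -config.z_limit)
    return df[~removed_mask], df[removed_mask]


def bin_and_summarize(df: pd.DataFrame, config: CleanConfig = CleanConfig()) -> pd.DataFrame:
    """Per-sex record counts and mean HC over half-open age bins.

    Bin k covers [k*w, (k+1)*w) days; the final bin additionally includes
    the closing day ``max_age_days`` itself.
    """
    if df.empty:
        return pd.DataFrame(columns=["sex", "bin", "age_lo", "age_hi", "n", "mean_hc_cm"])
    w = config.bin_width_days
    n_bins = int(np.ceil(config.max_age_days / w))
    binned = np.minimum(df["age_days"] // w, n_bins - 1).astype(int)
    out = (
        df.assign(bin=binned)
        .groupby(["sex", "bin"], as_index=False)
        .agg(n=("hc_cm", "size"), mean_hc_cm=("hc_cm", "mean"))
        .sort_values(["sex", "bin"], ignore_index=True)
    )
    out.insert(2, "age_lo", out["bin"] * w)
    out.insert(3, "age_hi", (out["bin"] + 1) * w)
    return out


def _exact_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    n = pooled.size
    center = n1 * (y.size) / 2.0

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        gt = (a[:, None] > b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        return float(gt) + 0.5 * float(ties)

    u_obs = u_stat(x, y)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def ranksum_sex_test(df: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing HC between sexes.

    Returns (U, p) with U the count of (male, female) pairs where the male
    value is larger (ties count 1/2).  Exact by full enumeration when the
    combined sample size is <= 10, otherwise the tie-corrected normal
    approximation.
    """
    male = df.loc[df["sex"] == "male", "hc_cm"].to_numpy(dtype=float)
    female = df.loc[df["sex"] == "female", "hc_cm"].to_numpy(dtype=float)
    if male.size == 0 or female.size == 0:
        raise ValueError("both sexes must be present for the rank-sum test")
    if male.size + female.size <= 10:
        return _exact_ranksum(male, female)
    res = stats.mannwhitneyu(male, female, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def clean_pipeline(
    df: pd.DataFrame, reference, config: CleanConfig = CleanConfig()
) -> tuple[pd.DataFrame, CleanReport]:
    """Full selection sequence: health -> duplicates -> age window -> outliers.

    Adds an ``age_days`` column, returns the retained rows and a report
    whose dispositions partition the input.
    """
    n_in = len(df)
    healthy, unhealthy = filter_health(df)
    unique, dups = deduplicate(healthy)
    unique = unique.assign(
        age_days=compute_age_days(unique["birth_date"], unique["measurement_date"])
    )
    in_window = (unique["age_days"] >= 0) & (unique["age_days"] <= config.max_age_days)
    windowed, out_of_window = unique[in_window], unique[~in_window]
    kept, outliers = flag_outliers(windowed, reference, config)
    report = CleanReport(
        retained=len(kept),
        removed_duplicate=len(dups),
        removed_outlier=len(outliers),
        removed_unhealthy=len(unhealthy),
        removed_age_range=len(out_of_window),
        bin_summary=bin_and_summarize(kept, config),
    )
    assert report.total == n_in
    return kept.reset_index(drop=True), report
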