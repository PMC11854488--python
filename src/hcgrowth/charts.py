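"""Percentile tables, reference charts, z-scoring and chart comparison.

A fitted model becomes a :class:`PercentileTable` (age grid x centile
levels, the printable chart), external LMS coefficient tables in the
WHO-published layout become :class:`ReferenceChart` objects usable for
z-scoring and cleaning, and :func:`overlay_compare` locates the onset of
sustained divergence between a fitted chart and a reference — the
operational version of reading "the 97th centile departs after day d" off a
superimposed plot.

Reference file dialects (tab-delimited, header row required):

* ``LMS_table``:  columns ``sex  age_days  L  M  S``
* ``BCPE_table``: columns ``sex  age_days  mu  sigma  nu  tau``

Ages must be strictly increasing within each sex; M (or mu) and S (or
sigma) strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bcpe import BCPEParams, bcpe_quantile, box_cox_z

__all__ = [
    "ReferenceChart",
    "PercentileTable",
    "DivergenceReport",
    "load_reference",
    "reference_zscore",
    "reference_from_truth",
    "build_percentile_table",
    "classify_head_size",
    "overlay_compare",
    "plot_chart",
    "CHART_LEVELS",
]

#: the chart levels conventional for national HC references
CHART_LEVELS = (0.03, 0.15, 0.50, 0.85, 0.97)

_DIALECTS = {
    "LMS_table": ["sex", "age_days", "L", "M", "S"],
    "BCPE_table": ["sex", "age_days", "mu", "sigma", "nu", "tau"],
}


@dataclass(frozen=True)
class ReferenceChart:
    """External coefficient table keyed by sex and age in days."""

    data: pd.DataFrame = field(repr=False)
    dialect: str = "LMS_table"
    provenance: str = ""

    def _sex_table(self, sex: str) -> pd.DataFrame:
        t = self.data[self.data["sex"] == sex]
        if t.empty:
            raise ValueError(f"reference has no rows for sex {sex!r}")
        return t

    def age_range(self, sex: str) -> tuple[float, float]:
        t = self._sex_table(sex)
        return float(t["age_days"].iloc[0]), float(t["age_days"].iloc[-1])

    def params_at(self, age_days, sex: str) -> BCPEParams:
        """L/M/S (or mu/sigma/nu/tau) linearly interpolated in age."""
        t = self._sex_table(sex)
        age = np.asarray(age_days, dtype=float)
        lo, hi = self.age_range(sex)
        if np.any(age < lo) or np.any(age > hi):
            raise ValueError(f"age outside reference coverage [{lo}, {hi}]")
        x = t["age_days"].to_numpy(dtype=float)
        if self.dialect == "LMS_table":
            nu = np.interp(age, x, t["L"].to_numpy(dtype=float))
            mu = np.interp(age, x, t["M"].to_numpy(dtype=float))
            sg = np.interp(age, x, t["S"].to_numpy(dtype=float))
            tau = np.broadcast_to(np.float64(2.0), age.shape).copy()
        else:
            mu = np.interp(age, x, t["mu"].to_numpy(dtype=float))
            sg = np.interp(age, x, t["sigma"].to_numpy(dtype=float))
            nu = np.interp(age, x, t["nu"].to_numpy(dtype=float))
            tau = np.interp(age, x, t["tau"].to_numpy(dtype=float))
        return BCPEParams(mu=mu, sigma=sg, nu=nu, tau=tau)

    def zscore(self, y, age_days, sex: str):
        return reference_zscore(y, age_days, sex, self)

    def centile(self, alpha, age_days, sex: str):
        """Reference centile value(s) at the given age(s)."""
        return bcpe_quantile(alpha, self.params_at(age_days, sex))


def load_reference(path, dialect: str = "LMS_table") -> ReferenceChart:
    """Parse and validate a tab-delimited reference coefficient table."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"reference file {path} is empty") from None
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"reference file {path} lacks columns {missing}")
    df = df[cols]
    errors: list[str] = []
    for col in cols[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"line {i + 2}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[cols[1:]].isna().any().any():
        rows = df.index[df[cols[1:]].isna().any(axis=1)]
        errors.extend(f"line {i + 2}: missing value" for i in rows)
    m_col = "M" if dialect == "LMS_table" else "mu"
    s_col = "S" if dialect == "LMS_table" else "sigma"
    if not errors:
        for sex, t in df.groupby("sex"):
            ages = t["age_days"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                errors.append(f"ages not strictly increasing for sex {sex!r}")
            if np.any(t[m_col] <= 0) or np.any(t[s_col] <= 0):
                errors.append(f"non-positive {m_col} or {s_col} for sex {sex!r}")
    if errors:
        raise ValueError("malformed reference file: " + "; ".join(errors))
    return ReferenceChart(data=df.reset_index(drop=True), dialect=dialect, provenance=str(path))


def reference_zscore(y, age_days, sex: str, ref: ReferenceChart):
    """LMS/Box-Cox z-score of measurement(s) against the reference."""
    return box_cox_z(y, ref.params_at(age_days, sex))


def reference_from_truth(curves_by_sex, ages) -> ReferenceChart:
    """Tabulate truth (or fitted) parameter curves into a ReferenceChart.

    Accepts any mapping sex -> object with a ``params_at(age)`` method.
    Emits a BCPE-dialect chart (exact for any tau), which behaves as an LMS
    chart when tau = 2.
    """
    ages = np.asarray(ages, dtype=float)
    rows = []
    for sex in sorted(curves_by_sex):
        p = curves_by_sex[sex].params_at(ages)
        mu, sg, nu, tau = p.broadcast()
        rows.append(
            pd.DataFrame(
                {"sex": sex, "age_days": ages, "mu": mu, "sigma": sg, "nu": nu, "tau": tau}
            )
        )
    return ReferenceChart(
        data=pd.concat(rows, ignore_index=True),
        dialect="BCPE_table",
        provenance="synthetic truth tabulation",
    )


# ---------------------------------------------------------------------------
# percentile tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PercentileTable:
    """Age grid x centile levels matrix of HC values from one fitted model."""

    sex: str
    ages: np.ndarray
    levels: tuple[float, ...]
    values: np.ndarray = field(repr=False)  # shape (n_ages, n_levels)

    def column(self, level: float) -> np.ndarray:
        return self.values[:, self.levels.index(level)]

    def at(self, age_days: float, level: float) -> float:
        """Linear interpolation of one centile curve at an arbitrary age."""
        return float(np.interp(age_days, self.ages, self.column(level)))

    def to_frame(self) -> pd.DataFrame:
        def name(a: float) -> str:
            pct = 100.0 * a
            return f"p{pct:g}"

        df = pd.DataFrame({"age_days": self.ages})
        for j, lv in enumerate(self.levels):
            df[name(lv)] = self.values[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def build_percentile_table(curves, levels=CHART_LEVELS, age_grid=None) -> PercentileTable:
    """Evaluate fitted centile curves on an age grid.

    ``curves`` is any object with ``params_at``, ``sex`` and an
    ``age_range`` attribute pair (fitted :class:`~hcgrowth.fit.ParameterCurves`
    or synthetic :class:`~hcgrowth.synth.TruthCurves`).  Rows are checked to
    be strictly increasing across levels (non-crossing centiles).
    """
    levels = tuple(float(a) for a in levels)
    if sorted(levels) != list(levels):
        raise ValueError("levels must be strictly increasing")
    lo, hi = getattr(curves, "age_range", (0.0, getattr(curves, "age_max", 1800.0)))
    if age_grid is None:
        age_grid = np.arange(float(lo), float(hi) + 1.0)
    age_grid = np.asarray(age_grid, dtype=float)
    if np.any(age_grid < lo) or np.any(age_grid > hi):
        raise ValueError(f"age grid outside fitted range [{lo}, {hi}]")
    p = curves.params_at(age_grid)
    values = np.column_stack([np.atleast_1d(bcpe_quantile(a, p)) for a in levels])
    if np.any(np.diff(values, axis=1) <= 0):
        raise ValueError("centile curves cross on the evaluation grid")
    return PercentileTable(sex=curves.sex, ages=age_grid, levels=levels, values=values)


def classify_head_size(y: float, age_days: float, sex: str, chart) -> str:
    """Micro/macrocephaly screen against a chart.

    Strictly above the 97th-centile value -> ``macrocephalic``; strictly
    below the 3rd -> ``microcephalic``; boundary values are ``typical``.
    ``chart`` is a PercentileTable (its sex must match) or a ReferenceChart.
    """
    if isinstance(chart, ReferenceChart):
        p3 = float(chart.centile(0.03, age_days, sex))
        p97 = float(chart.centile(0.97, age_days, sex))
    else:
        if chart.sex != sex:
            raise ValueError(f"chart is for {chart.sex!r}, record is {sex!r}")
        if not (chart.ages[0] <= age_days <= chart.ages[-1]):
            raise ValueError("age outside chart coverage")
        p3 = chart.at(age_days, 0.03)
        p97 = chart.at(age_days, 0.97)
    if y > p97:
        return "macrocephalic"
    if y < p3:
        return "microcephalic"
    return "typical"


# ---------------------------------------------------------------------------
# overlay comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceEntry:
    level: float
    onset_day: float
    direction: int  # +1 fitted above reference, -1 below
    max_abs_gap_cm: float


@dataclass(frozen=True)
class DivergenceReport:
    threshold_cm: float
    persistence_days: float
    entries: dict[float, DivergenceEntry]

    def to_yaml(self, path) -> None:
        doc = {
            "threshold_cm": self.threshold_cm,
            "persistence_days": self.persistence_days,
            "divergences": [
                {
                    "level": e.level,
                    "onset_day": e.onset_day,
                    "direction": "above" if e.direction > 0 else "below",
                    "max_abs_gap_cm": round(e.max_abs_gap_cm, 4),
                }
                for e in self.entries.values()
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def overlay_compare(
    fitted: PercentileTable,
    ref: ReferenceChart,
    levels=None,
    threshold_cm: float = 0.2,
    persistence_days: float = 120.0,
) -> DivergenceReport:
    """Locate sustained divergence of fitted centiles from a reference.

    On a daily grid over the common age range, a level diverges at the
    earliest day from which |fitted - reference| > threshold_cm holds
    continuously for at least ``persistence_days``.  The default threshold
    is the 0.2 cm tape-reading agreement tolerance and the default
    persistence one 120-day age bin, making "the curves part ways after day
    d" reproducible rather than a visual judgment.
    """
    levels = tuple(fitted.levels if levels is None else (float(a) for a in levels))
    rlo, rhi = ref.age_range(fitted.sex)
    lo = max(float(fitted.ages[0]), rlo)
    hi = min(float(fitted.ages[-1]), rhi)
    if lo >= hi:
        raise ValueError("fitted table and reference share no age range")
    grid = np.arange(lo, hi + 1.0)
    entries: dict[float, DivergenceEntry] = {}
    for lv in levels:
        f = np.interp(grid, fitted.ages, fitted.column(lv))
        r = np.atleast_1d(ref.centile(lv, grid, fitted.sex))
        gap = f - r
        over = np.abs(gap) > threshold_cm
        onset = _first_sustained_run(grid, over, persistence_days)
        if onset is not None:
            i = int(np.searchsorted(grid, onset))
            entries[lv] = DivergenceEntry(
                level=lv,
                onset_day=float(onset),
                direction=1 if gap[i] > 0 else -1,
                max_abs_gap_cm=float(np.max(np.abs(gap))),
            )
    return DivergenceReport(
        threshold_cm=threshold_cm, persistence_days=persistence_days, entries=entries
    )


def _first_sustained_run(grid: np.ndarray, mask: np.ndarray, min_days: float):
    """Start of the first True-run spanning at least ``min_days`` of age."""
    if not mask.any():
        return None
    idx = np.nonzero(mask)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        if grid[e] - grid[s] + 1.0 >= min_days:
            return grid[s]
    return None


def plot_chart(table: PercentileTable, path, reference: ReferenceChart | None = None) -> None:
    """Render centile curves (and optionally a reference overlay) to a file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for j, lv in enumerate(table.levels):
        ax.plot(table.ages, table.values[:, j], label=f"p{100 * lv:g}")
    if reference is not None:
        for lv in table.levels:
            r = np.atleast_1d(reference.centile(lv, table.ages, table.sex))
            ax.plot(table.ages, r, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("head circumference (cm)")
    ax.set_title(f"HC-for-age centiles ({table.sex})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
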