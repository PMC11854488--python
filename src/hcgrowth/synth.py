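"""Synthetic child-visit cohorts with the statistical structure of a
national head-circumference (HC) screening extract.

The generator emulates a mixed longitudinal/cross-sectional cohort of
children aged 0-1800 days: each child contributes one visit
(cross-sectional) or several (longitudinal), the HC at each visit is drawn
from a BCPE distribution whose four parameters vary smoothly with age and
differ by sex, and the recorded value is the average of two simulated tape
readings agreeing within 0.2 cm.  Exact duplicate rows and gross outliers
(reference z-score beyond +/-5) can be injected on top, with a ground-truth
manifest, so the downstream cleaning stage has known work to do.

Truth curves
------------
The default median curve is a saturating log form

    mu(t) = m0 + m1 * log(1 + t / m2)        (cm, t in days)

rising from about 34 cm at birth to about 50 cm at 1800 days, with boys
offset above girls by a configurable amount (default 0.5 cm).  The
coefficient of variation sigma(t) decreases linearly with age; skewness nu
and kurtosis tau are constant (defaults 1 and 2: the Box-Cox normal / LMS
case).  Any smooth family satisfying the invariants (mu positive and
non-decreasing, sigma > 0, tau > 0) would do; the coefficients are fixture
material, not a contract.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bcpe import BCPEParams, bcpe_quantile, box_cox_y, pe_sample

__all__ = [
    "MeasurementRecord",
    "TruthCurves",
    "CohortConfig",
    "make_truth_curves",
    "simulate_cohort",
    "inject_artifacts",
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "write_manifest_csv",
]

COLUMNS = ["child_id", "sex", "birth_date", "measurement_date", "hc_cm", "health_flag"]

#: default visit-count distribution: half the cohort cross-sectional,
#: the rest longitudinal with 2-5 visits.
DEFAULT_VISIT_DIST = {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}

_BIRTH_EPOCH = dt.date(2018, 1, 1)
_BIRTH_SPAN_DAYS = 4 * 365


@dataclass(frozen=True)
class MeasurementRecord:
    """One child-visit row of the cohort extract."""

    child_id: str
    sex: str  # "male" | "female"
    birth_date: dt.date
    measurement_date: dt.date
    hc_cm: float
    health_flag: str  # "healthy" | "excluded_condition"

    def __post_init__(self) -> None:
        if self.measurement_date < self.birth_date:
            raise ValueError(f"measurement before birth for child {self.child_id}")
        if not self.hc_cm > 0:
            raise ValueError(f"non-positive HC for child {self.child_id}")


@dataclass(frozen=True)
class TruthCurves:
    """Smooth age -> (mu, sigma, nu, tau) functions for one sex.

    mu(t) = m0 + m1*log(1 + t/m2), strictly increasing for m1 > 0;
    sigma(t) = s0 + s1 * t/1800 (s1 <= 0 gives the decreasing CV typical of
    head circumference); nu and tau constant.
    """

    sex: str
    m0: float
    m1: float
    m2: float
    s0: float
    s1: float
    nu: float = 1.0
    tau: float = 2.0
    age_max: float = 1800.0

    def __post_init__(self) -> None:
        if self.m0 <= 0 or self.m1 < 0 or self.m2 <= 0:
            raise ValueError("median curve must be positive and non-decreasing")
        if self.sigma(0.0) <= 0 or self.sigma(self.age_max) <= 0:
            raise ValueError("sigma must stay positive over the age range")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def mu(self, age_days):
        t = np.asarray(age_days, dtype=float)
        out = self.m0 + self.m1 * np.log1p(t / self.m2)
        return out if out.ndim else float(out)

    def sigma(self, age_days):
        t = np.asarray(age_days, dtype=float)
        out = self.s0 + self.s1 * t / 1800.0
        return out if out.ndim else float(out)

    def params_at(self, age_days) -> BCPEParams:
        t = np.asarray(age_days, dtype=float)
        shape = t.shape
        return BCPEParams(
            mu=self.mu(t),
            sigma=self.sigma(t),
            nu=np.broadcast_to(np.float64(self.nu), shape).copy(),
            tau=np.broadcast_to(np.float64(self.tau), shape).copy(),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the simulated cohort.

    Defaults encode the emulated screening-program conditions: 51.6% boys,
    ages 0-1800 days with mild front-loading toward infancy (screening
    visits concentrate in the first years), mixed visit counts, two tape
    readings of SD 0.1 cm agreeing within 0.2 cm, and no artifacts unless
    rates are set.
    """

    n_children: int = 1000
    male_fraction: float = 0.516
    visit_count_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_DIST)
    )
    age_range_days: tuple[int, int] = (0, 1800)
    outlier_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0
    # plumbing beyond the core design:
    unhealthy_rate: float = 0.0
    front_loading: float = 1.6  # ages drawn as lo + span*u**front_loading
    reading_sd_cm: float = 0.1
    reading_agreement_cm: float = 0.2
    max_abs_z: float | None = None  # rejection-sample truth |z| within bound
    outlier_z: float = 8.0  # |reference z| of injected outliers (> 5)

    def validate(self) -> None:
        if self.n_children < 0:
            raise ValueError("n_children must be non-negative")
        for name in ("male_fraction", "outlier_rate", "duplicate_rate", "unhealthy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.visit_count_distribution:
            raise ValueError("visit_count_distribution must be non-empty")
        if any(k < 1 for k in self.visit_count_distribution):
            raise ValueError("visit counts must be >= 1")
        probs = np.array(list(self.visit_count_distribution.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("visit probabilities must be non-negative and sum to 1")
        lo, hi = self.age_range_days
        if not (0 <= lo < hi):
            raise ValueError("age_range_days must satisfy 0 <= lo < hi")
        if self.outlier_z <= 5.0:
            raise ValueError("outlier_z must exceed the +/-5 cleaning flag")


def make_truth_curves(
    sex: str,
    seed: int,
    *,
    sex_offset_cm: float = 0.5,
    nu: float = 1.0,
    tau: float = 2.0,
) -> TruthCurves:
    """Seeded truth curves for one sex.

    The seed jitters the base coefficients by a few percent so distinct
    fixtures exist, while the construction guarantees the invariants and a
    male median >= female median at every age (males carry ``sex_offset_cm``
    added to the intercept; both sexes share the seed-drawn shape).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    rng = np.random.default_rng(seed)
    # shared shape draw (same for both sexes under the same seed)
    m0 = 34.0 * (1.0 + 0.01 * rng.uniform(-1, 1))
    m2 = 30.0 * (1.0 + 0.10 * rng.uniform(-1, 1))
    # anchor mu(1800) ~ 50 cm
    target_gain = 16.0 * (1.0 + 0.02 * rng.uniform(-1, 1))
    m1 = target_gain / np.log1p(1800.0 / m2)
    s0 = 0.036 * (1.0 + 0.05 * rng.uniform(-1, 1))
    s1 = -0.012 * (1.0 + 0.05 * rng.uniform(-1, 1))
    if sex == "male":
        m0 += sex_offset_cm
    return TruthCurves(sex=sex, m0=m0, m1=m1, m2=m2, s0=s0, s1=s1, nu=nu, tau=tau)


def _sample_visit_counts(dist: dict[int, float], n: int, rng) -> np.ndarray:
    ks = np.array(sorted(dist), dtype=int)
    ps = np.array([dist[int(k)] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(ks, size=n, p=ps)


def _recorded_hc(true_hc: np.ndarray, cfg: CohortConfig, rng) -> np.ndarray:
    """Average of two tape readings within ``reading_agreement_cm``.

    Each reading is the true value plus N(0, reading_sd^2) error rounded to
    the 0.1 cm tape resolution; pairs disagreeing by more than the protocol
    tolerance are re-measured.
    """
    n = true_hc.size
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        r1 = true_hc[pending] + rng.normal(0.0, cfg.reading_sd_cm, pending.size)
        r2 = true_hc[pending] + rng.normal(0.0, cfg.reading_sd_cm, pending.size)
        r1 = np.round(r1, 1)
        r2 = np.round(r2, 1)
        ok = np.abs(r1 - r2) <= cfg.reading_agreement_cm + 1e-12
        out[pending[ok]] = (r1[ok] + r2[ok]) / 2.0
        pending = pending[~ok]
    return out


def simulate_cohort(
    curves: dict[str, TruthCurves] | tuple[TruthCurves, TruthCurves],
    config: CohortConfig,
) -> list[MeasurementRecord]:
    """Simulate the clean (artifact-free) cohort.

    Each child draws a sex, a birth date, a visit count, visit ages, and an
    HC per visit from the BCPE truth model at that age, recorded through the
    two-reading measurement protocol.  Children with one visit are
    cross-sectional, the rest longitudinal.  Output order and values are
    fully reproducible under ``config.seed``.
    """
    config.validate()
    if not isinstance(curves, dict):
        curves = {c.sex: c for c in curves}
    if set(curves) != {"male", "female"}:
        raise ValueError("curves must cover both sexes")
    if config.n_children == 0:
        return []

    rng = np.random.default_rng(config.seed)
    n = config.n_children
    is_male = rng.random(n) < config.male_fraction
    visits = _sample_visit_counts(config.visit_count_distribution, n, rng)
    birth_offsets = rng.integers(0, _BIRTH_SPAN_DAYS, size=n)
    unhealthy = rng.random(n) < config.unhealthy_rate

    lo, hi = config.age_range_days
    records: list[MeasurementRecord] = []
    for i in range(n):
        sex = "male" if is_male[i] else "female"
        c = curves[sex]
        child_id = f"C{i:06d}"
        birth = _BIRTH_EPOCH + dt.timedelta(days=int(birth_offsets[i]))
        k = int(visits[i])
        u = rng.random(k)
        ages = np.sort(lo + (hi - lo) * u**config.front_loading).astype(int)
        p = c.params_at(ages.astype(float))
        z = pe_sample(c.tau, k, rng)
        if config.max_abs_z is not None:
            while np.any(np.abs(z) > config.max_abs_z):
                bad = np.abs(z) > config.max_abs_z
                z[bad] = pe_sample(c.tau, int(bad.sum()), rng)
        true_hc = np.atleast_1d(box_cox_y(z, p))
        hc = _recorded_hc(true_hc, config, rng)
        flag = "excluded_condition" if unhealthy[i] else "healthy"
        for j in range(k):
            records.append(
                MeasurementRecord(
                    child_id=child_id,
                    sex=sex,
                    birth_date=birth,
                    measurement_date=birth + dt.timedelta(days=int(ages[j])),
                    hc_cm=float(hc[j]),
                    health_flag=flag,
                )
            )
    return records


def inject_artifacts(
    records: list[MeasurementRecord],
    config: CohortConfig,
    curves: dict[str, TruthCurves] | tuple[TruthCurves, TruthCurves] | None = None,
) -> tuple[list[MeasurementRecord], dict[int, str]]:
    """Append exact duplicates and displace gross outliers; return manifest.

    * duplicates: ``round(duplicate_rate * len(records))`` exact row copies
      appended at the end;
    * outliers: ``round(outlier_rate * len(records))`` distinct original
      rows get their HC moved to the truth-model value at standardized
      residual ``+/- config.outlier_z`` (default |z| = 8, safely beyond the
      +/-5 cleaning flag).  ``curves`` supplies the truth model; it is
      required when ``outlier_rate > 0``.

    The manifest maps output record index -> artifact kind ("duplicate" or
    "outlier"); every index not in the manifest is an untouched truth draw.
    The two index sets are disjoint so cleaning dispositions are
    unambiguous.
    """
    config.validate()
    n = len(records)
    n_dup = int(round(config.duplicate_rate * n))
    n_out = int(round(config.outlier_rate * n))
    if (n_dup or n_out) and n == 0:
        raise ValueError("cannot inject artifacts into an empty cohort")
    if n_dup == 0 and n_out == 0:
        return list(records), {}

    rng = np.random.default_rng(config.seed + 1)
    out = list(records)
    manifest: dict[int, str] = {}

    chosen = rng.choice(n, size=n_dup + n_out, replace=False) if n_dup + n_out else []
    dup_idx = np.asarray(chosen[:n_dup], dtype=int)
    out_idx = np.asarray(chosen[n_dup : n_dup + n_out], dtype=int)

    if n_out:
        if curves is None:
            raise ValueError("truth curves are required to place outliers")
        if not isinstance(curves, dict):
            curves = {c.sex: c for c in curves}
        signs = rng.choice((-1.0, 1.0), size=n_out)
        for s, i in zip(signs, out_idx):
            r = out[i]
            age = float((r.measurement_date - r.birth_date).days)
            p = curves[r.sex].params_at(age)
            hc = float(box_cox_y(s * config.outlier_z, p))
            out[i] = replace(r, hc_cm=hc)
            manifest[int(i)] = "outlier"

    for i in dup_idx:
        manifest[len(out)] = "duplicate"
        out.append(out[int(i)])

    return out, manifest


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical column order."""
    if not records:
        return pd.DataFrame(columns=COLUMNS)
    return pd.DataFrame(
        {
            "child_id": [r.child_id for r in records],
            "sex": [r.sex for r in records],
            "birth_date": [r.birth_date.isoformat() for r in records],
            "measurement_date": [r.measurement_date.isoformat() for r in records],
            "hc_cm": [r.hc_cm for r in records],
            "health_flag": [r.health_flag for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    return [
        MeasurementRecord(
            child_id=str(row.child_id),
            sex=str(row.sex),
            birth_date=dt.date.fromisoformat(str(row.birth_date)),
            measurement_date=dt.date.fromisoformat(str(row.measurement_date)),
            hc_cm=float(row.hc_cm),
            health_flag=str(row.health_flag),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort_csv(records: list[MeasurementRecord] | pd.DataFrame, path) -> None:
    """CSV with ISO-8601 dates; byte-identical across runs for a fixed seed."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


def write_manifest_csv(manifest: dict[int, str], path) -> None:
    pd.DataFrame(
        sorted(manifest.items()), columns=["record_index", "artifact_kind"]
    ).to_csv(path, index=False, lineterminator="\n")
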