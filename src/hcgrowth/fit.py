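"""Penalized-likelihood estimation of age-varying BCPE parameters.

The model for a single sex is a distributional regression: at age ``t`` the
head circumference is BCPE(mu(t), sigma(t), nu(t), tau(t)), where each
parameter curve is a penalized B-spline (P-spline) in a power-transformed
age ``x = (t / t_max)^xi``, with a log link for mu, sigma and tau (enforcing
positivity) and an identity link for nu.  The power transform stretches
infancy, where growth is steepest, so modest spline complexity suffices.

Estimation follows the classic cyclic (backfitting) algorithm for
distributional regression: each parameter curve is updated in turn by a
penalized weighted least-squares step on the local-scoring working
response, holding the others fixed, until the global deviance
GD = -2 * log-likelihood stops improving.  Scores and curvatures with
respect to each predictor are obtained by central finite differences of the
exact BCPE log-density, and every coefficient update is step-halved if it
fails to decrease GD, which makes the deviance trajectory monotone.

Smoothness is controlled by a per-curve target for the effective degrees
of freedom (edf): the ridge penalty lambda on squared second differences of
the B-spline coefficients is bisected until the trace of the smoother
matrix matches the target.  A target of 0 requests a constant (for tau:
a value fixed at 2, the Box-Cox-normal case), 1 a fitted constant, 2 a
straight line in x, and >= 3 a genuinely smooth curve.  Model complexity is
chosen by AIC = GD + 2 * total edf over a configured grid of targets and
age-transform exponents, ties broken toward fewer degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.interpolate import BSpline

from .bcpe import BCPEParams, bcpe_logpdf, box_cox_z, pe_logpdf, bcpe_quantile

__all__ = [
    "FitConfig",
    "ParameterCurves",
    "FitDiagnostics",
    "FitError",
    "global_deviance",
    "fit_lms",
    "select_model",
    "empirical_coverage",
]

PARAMS = ("mu", "sigma", "nu", "tau")
_LINKS = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}
_SPLINE_DEGREE = 3


class FitError(RuntimeError):
    """Raised when estimation cannot proceed or does not converge."""


@dataclass(frozen=True)
class FitConfig:
    """Search grids and convergence settings for model estimation.

    Each ``*_df_grid`` lists candidate effective-df targets for that
    parameter curve (see module docstring for the 0/1/2/>=3 semantics);
    ``xi_grid`` lists candidate age-transform exponents.  ``fit_lms`` uses
    the first entry of each grid unless explicit targets are passed;
    ``select_model`` sweeps the full product.
    """

    mu_df_grid: tuple[float, ...] = (6, 8, 10, 12)
    sigma_df_grid: tuple[float, ...] = (3, 4, 5, 6)
    nu_df_grid: tuple[float, ...] = (0, 2)
    tau_df_grid: tuple[float, ...] = (0, 2)
    xi_grid: tuple[float, ...] = (0.35, 1.0)
    tau_fixed_value: float = 2.0
    gd_tol: float = 0.01
    max_cycles: int = 50
    inner_iters: int = 2
    n_inner_knots: int = 16
    age_range: tuple[float, float] = (0.0, 1800.0)

    def __post_init__(self) -> None:
        for g in (self.mu_df_grid, self.sigma_df_grid, self.nu_df_grid, self.tau_df_grid, self.xi_grid):
            if not g:
                raise ValueError("search grids must be non-empty")
        if self.gd_tol <= 0:
            raise ValueError("gd_tol must be positive")


@dataclass
class _Term:
    """One parameter curve: kind, link and coefficients on the shared basis."""

    kind: str  # fixed | constant | linear | pspline
    link: str
    coef: np.ndarray  # empty for fixed
    fixed_value: float = np.nan
    lam: float = np.nan
    edf: float = 0.0

    def eta(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(X.shape[0], _link_fn(self.link)(self.fixed_value))
        return X @ self.coef


def _link_fn(link: str):
    return np.log if link == "log" else (lambda v: v)


def _inv_link(link: str):
    return np.exp if link == "log" else (lambda v: v)


@dataclass
class ParameterCurves:
    """Fitted sex-specific parameter curves, evaluable at any in-range age."""

    sex: str
    xi: float
    age_range: tuple[float, float]
    knots: np.ndarray = field(repr=False)
    terms: dict[str, _Term] = field(repr=False, default_factory=dict)

    # -- evaluation ---------------------------------------------------------

    def _x(self, age_days) -> np.ndarray:
        t = np.atleast_1d(np.asarray(age_days, dtype=float))
        lo, hi = self.age_range
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"age outside fitted range [{lo}, {hi}]; no extrapolation")
        return ((t - lo) / (hi - lo)) ** self.xi

    def _design(self, x: np.ndarray, kind: str) -> np.ndarray:
        return _design_matrix(x, self.knots, kind)

    def params_at(self, age_days) -> BCPEParams:
        x = self._x(age_days)
        vals = {}
        for name in PARAMS:
            term = self.terms[name]
            if term.kind == "fixed":
                vals[name] = np.full(x.shape, term.fixed_value)
            else:
                eta = self._design(x, term.kind) @ term.coef
                vals[name] = _inv_link(term.link)(eta)
        p = BCPEParams(**vals)
        if np.isscalar(age_days) or np.ndim(age_days) == 0:
            return BCPEParams(*(float(np.asarray(v)[0]) for v in p.broadcast()))
        return p

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "xi": self.xi,
            "age_range": list(self.age_range),
            "knots": self.knots.tolist(),
            "terms": {
                name: {
                    "kind": t.kind,
                    "link": t.link,
                    "coef": np.asarray(t.coef).tolist(),
                    "fixed_value": None if np.isnan(t.fixed_value) else t.fixed_value,
                    "edf": t.edf,
                }
                for name, t in self.terms.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterCurves":
        terms = {
            name: _Term(
                kind=td["kind"],
                link=td["link"],
                coef=np.asarray(td["coef"], dtype=float),
                fixed_value=np.nan if td.get("fixed_value") is None else float(td["fixed_value"]),
                edf=float(td.get("edf", 0.0)),
            )
            for name, td in d["terms"].items()
        }
        return cls(
            sex=d["sex"],
            xi=float(d["xi"]),
            age_range=tuple(d["age_range"]),
            knots=np.asarray(d["knots"], dtype=float),
            terms=terms,
        )

    def to_yaml(self, path, diagnostics: "FitDiagnostics | None" = None) -> None:
        doc = {"model": self.to_dict()}
        if diagnostics is not None:
            doc["diagnostics"] = diagnostics.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterCurves":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["model"])


@dataclass(frozen=True)
class FitDiagnostics:
    """Deviance, effective df and the AIC identity AIC = GD + 2*df."""

    gd: float
    edf: dict[str, float]
    converged: bool
    n_cycles: int
    df_spec: dict[str, float]
    xi: float

    @property
    def total_df(self) -> float:
        return float(sum(self.edf.values()))

    @property
    def aic(self) -> float:
        return self.gd + 2.0 * self.total_df

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_df"] = self.total_df
        d["aic"] = self.aic
        return d


# ---------------------------------------------------------------------------
# basis and penalized weighted least squares
# ---------------------------------------------------------------------------


def _make_knots(n_inner: int) -> np.ndarray:
    inner = np.linspace(0.0, 1.0, n_inner + 2)
    k = _SPLINE_DEGREE
    return np.concatenate([np.zeros(k), inner, np.ones(k)])


def _design_matrix(x: np.ndarray, knots: np.ndarray, kind: str) -> np.ndarray:
    if kind == "constant":
        return np.ones((x.size, 1))
    if kind == "linear":
        return np.column_stack([np.ones(x.size), x])
    xc = np.clip(x, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(xc, knots, _SPLINE_DEGREE).toarray()


def _second_diff_penalty(n_coef: int) -> np.ndarray:
    D = np.diff(np.eye(n_coef), n=2, axis=0)
    return D.T @ D


def _pwls(X, w, zw, lam, P):
    """Penalized weighted LS solve; returns (coef, edf)."""
    XtW = X.T * w
    A = XtW @ X
    M = A + lam * P if P is not None and lam > 0 else A.copy()
    M.flat[:: M.shape[0] + 1] += 1e-10  # numerical ridge
    coef = np.linalg.solve(M, XtW @ zw)
    edf = float(np.trace(np.linalg.solve(M, A)))
    return coef, edf


def _fit_term_pwls(X, w, zw, target_df: float, P):
    """Choose lambda by bisection so the smoother trace hits target_df."""
    if P is None:  # constant or linear: unpenalized
        return _pwls(X, w, zw, 0.0, None)
    lo, hi = -8.0, 16.0  # log10 lambda bracket
    _, edf_lo = _pwls(X, w, zw, 10.0**lo, P)
    if target_df >= edf_lo:  # effectively unpenalized
        return _pwls(X, w, zw, 10.0**lo, P)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        coef, edf = _pwls(X, w, zw, 10.0**mid, P)
        if abs(edf - target_df) < 1e-4:
            return coef, edf
        if edf > target_df:
            lo = mid
        else:
            hi = mid
    return coef, edf


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _loglik(y, mu, sigma, nu, tau) -> np.ndarray:
    """Per-record BCPE log-density without the truncation-mass guard
    (iterates may wander; the final model is validated separately)."""
    z = box_cox_z(y, BCPEParams(mu, sigma, nu, tau))
    log_jac = (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma)
    return pe_logpdf(z, tau) + log_jac


def _extract_xy(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    if "sex" in data.columns:
        sexes = data["sex"].unique()
        if len(sexes) > 1:
            raise FitError(f"fit expects a single sex, got {sorted(sexes)}")
        sex = str(sexes[0])
    else:
        sex = "unspecified"
    ages = data["age_days"].to_numpy(dtype=float)
    y = data["hc_cm"].to_numpy(dtype=float)
    return ages, y, sex


def global_deviance(data: pd.DataFrame, curves: ParameterCurves) -> float:
    """GD = -2 * sum of log BCPE densities under the fitted curves."""
    ages, y, _ = _extract_xy(data)
    p = curves.params_at(ages)
    ll = bcpe_logpdf(y, p)
    ll = np.atleast_1d(ll)
    if not np.all(np.isfinite(ll)):
        bad = np.nonzero(~np.isfinite(ll))[0]
        raise FitError(f"zero density at record rows {bad.tolist()[:10]}")
    return float(-2.0 * ll.sum())


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _term_kind(target_df: float, name: str) -> str:
    if target_df == 0:
        return "fixed" if name == "tau" else "constant"
    if target_df == 1:
        return "constant"
    if target_df == 2:
        return "linear"
    return "pspline"


def fit_lms(
    data: pd.DataFrame,
    config: FitConfig = FitConfig(),
    *,
    dfs: dict[str, float] | None = None,
    xi: float | None = None,
) -> tuple[ParameterCurves, FitDiagnostics]:
    """Fit the four BCPE parameter curves to one sex's cleaned records.

    ``data`` needs ``age_days`` and ``hc_cm`` columns (and at most one sex).
    ``dfs`` gives the per-parameter effective-df targets (defaults: first
    entry of each grid in ``config``); ``xi`` the age-transform exponent.
    Returns the curves at a local deviance optimum plus diagnostics.
    Deterministic: no randomness enters the algorithm.
    """
    ages, y, sex = _extract_xy(data)
    if len(y) < 50:
        raise FitError("need at least 50 records to fit parameter curves")
    if len(np.unique(ages // 120)) < 2:
        raise FitError("records must span at least two 120-day age bins")
    if np.ptp(y) == 0.0:
        raise FitError("degenerate data: all HC values identical (sigma -> 0)")
    lo, hi = config.age_range
    if np.any(ages < lo) or np.any(ages > hi):
        raise FitError(f"record ages outside configured range [{lo}, {hi}]")

    if dfs is None:
        dfs = {
            "mu": config.mu_df_grid[0],
            "sigma": config.sigma_df_grid[0],
            "nu": config.nu_df_grid[0],
            "tau": config.tau_df_grid[0],
        }
    xi = float(config.xi_grid[0] if xi is None else xi)

    knots = _make_knots(config.n_inner_knots)
    x = ((ages - lo) / (hi - lo)) ** xi

    # designs and penalties per term kind
    terms: dict[str, _Term] = {}
    X: dict[str, np.ndarray] = {}
    P: dict[str, np.ndarray | None] = {}
    for name in PARAMS:
        kind = _term_kind(float(dfs[name]), name)
        link = _LINKS[name]
        if kind == "fixed":
            terms[name] = _Term(kind, link, np.empty(0), fixed_value=config.tau_fixed_value, edf=0.0)
            X[name] = np.empty((len(y), 0))
            P[name] = None
            continue
        Xk = _design_matrix(x, knots, kind)
        X[name] = Xk
        P[name] = _second_diff_penalty(Xk.shape[1]) if kind == "pspline" else None
        terms[name] = _Term(kind, link, np.zeros(Xk.shape[1]), edf=float(min(dfs[name], Xk.shape[1])))

    # --- initialization: smooth median, constant CV, nu=1, tau=2 ----------
    log_y = np.log(y)
    t_mu = terms["mu"]
    if t_mu.kind == "pspline":
        t_mu.coef, _ = _fit_term_pwls(X["mu"], np.ones(len(y)), log_y, max(float(dfs["mu"]), 3.0), P["mu"])
    else:
        t_mu.coef, _ = _pwls(X["mu"], np.ones(len(y)), log_y, 0.0, None)
    mu0 = np.exp(X["mu"] @ t_mu.coef)
    cv = float(np.std(y / mu0 - 1.0))
    cv = max(cv, 1e-4)
    _init_flat(terms["sigma"], np.log(cv))
    _init_flat(terms["nu"], 1.0)
    if terms["tau"].kind != "fixed":
        _init_flat(terms["tau"], np.log(2.0))

    etas = {name: terms[name].eta(X[name]) if terms[name].kind != "fixed"
            else np.full(len(y), _link_fn(_LINKS[name])(terms[name].fixed_value))
            for name in PARAMS}

    def current_gd() -> float:
        vals = [_inv_link(_LINKS[n])(etas[n]) for n in PARAMS]
        ll = _loglik(y, *vals)
        return float(-2.0 * np.sum(ll)) if np.all(np.isfinite(ll)) else np.inf

    gd = current_gd()
    if not np.isfinite(gd):
        raise FitError("initialization gives non-finite deviance")

    h = 1e-4
    converged = False
    n_cycles = 0
    for cycle in range(config.max_cycles):
        n_cycles = cycle + 1
        gd_cycle_start = gd
        for name in PARAMS:
            term = terms[name]
            if term.kind == "fixed":
                continue
            for _ in range(config.inner_iters):
                u, w = _score_weights(y, etas, name, h)
                zw = etas[name] + u / w
                target = float(dfs[name])
                new_coef, edf = _fit_term_pwls(X[name], w, zw, target, P[name])
                # step-halving: accept only GD-non-increasing updates
                old_coef = term.coef
                old_eta = etas[name]
                trial = new_coef
                accepted = False
                for _half in range(8):
                    etas[name] = X[name] @ trial
                    gd_trial = current_gd()
                    if gd_trial <= gd + 1e-9:
                        term.coef = trial
                        term.edf = edf
                        gd = gd_trial
                        accepted = True
                        break
                    trial = 0.5 * (trial + old_coef)
                if not accepted:
                    etas[name] = old_eta
        if gd_cycle_start - gd < config.gd_tol:
            converged = True
            break

    if not converged:
        raise FitError(
            f"no convergence in {config.max_cycles} cycles (last GD {gd:.4f})"
        )

    curves = ParameterCurves(sex=sex, xi=xi, age_range=(float(lo), float(hi)), knots=knots, terms=terms)
    diag = FitDiagnostics(
        gd=gd,
        edf={n: float(terms[n].edf) for n in PARAMS},
        converged=converged,
        n_cycles=n_cycles,
        df_spec={n: float(dfs[n]) for n in PARAMS},
        xi=xi,
    )
    return curves, diag


def _init_flat(term: _Term, eta_value: float) -> None:
    """Set coefficients so the term evaluates to a constant predictor.

    Works for every kind because B-spline bases sum to one pointwise."""
    if term.kind == "linear":
        term.coef = np.array([eta_value, 0.0])
    else:
        term.coef = np.full(term.coef.shape if term.coef.size else 1, eta_value, dtype=float)


def _score_weights(y, etas, which: str, h: float):
    """Central-difference score and curvature of the log-likelihood with
    respect to the predictor of one parameter, per record."""

    def ll(eta_k):
        vals = []
        for n in PARAMS:
            e = eta_k if n == which else etas[n]
            vals.append(_inv_link(_LINKS[n])(e))
        out = _loglik(y, *vals)
        return np.where(np.isfinite(out), out, -1e10)

    e0 = etas[which]
    l0 = ll(e0)
    lp = ll(e0 + h)
    lm = ll(e0 - h)
    u = (lp - lm) / (2.0 * h)
    w = -(lp - 2.0 * l0 + lm) / h**2
    pos = w > 1e-8
    if not np.all(pos):
        fallback = float(np.median(w[pos])) if np.any(pos) else 1.0
        w = np.where(pos, w, fallback)
    return u, w


def select_model(
    data: pd.DataFrame, config: FitConfig = FitConfig()
) -> tuple[ParameterCurves, list[FitDiagnostics]]:
    """Fit every df-grid x age-transform candidate; return the AIC minimizer.

    The full candidate ranking (ascending AIC, ties toward fewer df) is
    returned for reporting.  Candidates that fail to converge are dropped;
    if all fail, the errors are aggregated into one :class:`FitError`.
    """
    combos = list(
        itertools.product(
            config.mu_df_grid,
            config.sigma_df_grid,
            config.nu_df_grid,
            config.tau_df_grid,
            config.xi_grid,
        )
    )
    results: list[tuple[ParameterCurves, FitDiagnostics]] = []
    failures: list[str] = []
    for mu_df, sg_df, nu_df, tau_df, xi in combos:
        dfs = {"mu": mu_df, "sigma": sg_df, "nu": nu_df, "tau": tau_df}
        try:
            results.append(fit_lms(data, config, dfs=dfs, xi=xi))
        except FitError as exc:
            failures.append(f"dfs={dfs}, xi={xi}: {exc}")
    if not results:
        raise FitError("all candidates failed:\n" + "\n".join(failures))
    results.sort(key=lambda cd: (cd[1].aic, cd[1].total_df))
    best_curves = results[0][0]
    return best_curves, [d for _, d in results]


def empirical_coverage(
    data: pd.DataFrame,
    curves: ParameterCurves,
    levels=(0.03, 0.15, 0.50, 0.85, 0.97),
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Observed fraction of records below each fitted centile curve.

    Returns one row per level with the observed proportion and its exact
    (Clopper-Pearson) confidence interval; for a well-calibrated model the
    observed proportion at level alpha should be near alpha.
    """
    levels = tuple(float(a) for a in levels)
    if not levels:
        return pd.DataFrame(columns=["level", "n", "n_below", "observed", "ci_low", "ci_high"])
    ages, y, _ = _extract_xy(data)
    p = curves.params_at(ages)
    rows = []
    n = len(y)
    a2 = (1.0 - ci_level) / 2.0
    for lv in levels:
        q = np.atleast_1d(bcpe_quantile(lv, p))
        k = int(np.sum(y < q))
        lo = 0.0 if k == 0 else float(stats.beta.ppf(a2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a2, k + 1, n - k))
        rows.append({"level": lv, "n": n, "n_below": k, "observed": k / n, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
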