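"""Single-day reliability of walking outcomes and monitoring-day projections.

The reliability of one day of monitoring is the intraclass correlation from a
random-intercept linear model of the (optionally transformed) day-level
outcome:

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e)

    ICC_single = s2_b / (s2_b + s2_e)

i.e. the between-subject share of the variance left after adjusting for fixed
covariates (care level, weekday/weekend, facility). Variance components are
estimated by REML; because the model always carries exactly one random
intercept, REML is profiled down to a one-dimensional optimisation over the
variance ratio lambda = s2_b / s2_e, which is solved to high precision and is
fast enough for resampling-based confidence intervals.

The number of days N whose average attains a target reliability ICC_t follows
from the Spearman-Brown prophecy formula,

    N = ICC_t / (1 - ICC_t) * (1 - ICC_s) / ICC_s,

rounded up to an integer (minimum 1): the average of ceil(N) days is the
cheapest design whose composite reliability reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import WEEKDAYS

__all__ = [
    "DEFAULT_TRANSFORMS",
    "VarianceComponents",
    "DayEffectResult",
    "fit_random_intercept",
    "icc_single_day",
    "icc_with_ci",
    "days_needed",
    "spearman_brown",
    "reliability_table",
    "day_of_week_effects",
    "STRATA",
]

#: square-root transform for the right-skewed volume/bout-length outcomes;
#: alpha and variability are analysed on their original scale
DEFAULT_TRANSFORMS = {
    "total_walk_time_s": "sqrt",
    "total_steps": "sqrt",
    "total_bouts": "sqrt",
    "mean_bout_length_s": "sqrt",
    "alpha": "identity",
    "variability_s": "identity",
}

STRATA = ("whole_group", "dementia", "high", "intermediate")

_OUTCOME_ORDER = [
    "total_walk_time_s",
    "total_steps",
    "total_bouts",
    "mean_bout_length_s",
    "alpha",
    "variability_s",
]


@dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_residual: float
    fixed_effects: dict[str, dict[str, float]]
    n_subjects: int
    n_days_total: int
    boundary: bool  # True when the between-subject variance hit zero
    reml_neg2loglik: float


@dataclass
class DayEffectResult:
    pairwise: pd.DataFrame  # day_a, day_b, estimate, se, p_value, significant, available
    weekend_beta: dict[str, float]  # estimate, ci_low, ci_high, p_value
    p_threshold: float = 0.01


# ---------------------------------------------------------------------------
# profiled REML for the single-random-intercept model


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    if X.shape[1] <= 1:
        return X, names
    s = np.linalg.svd(X, compute_uv=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank == X.shape[1]:
        return X, names
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        if len(keep) == rank:
            break
    return X[:, keep], [names[j] for j in keep]


def _reml_neg2(lam: float, stats_: dict) -> float:
    n, p = stats_["n"], stats_["p"]
    c = lam / (1.0 + lam * stats_["n_i"])
    XtViX = stats_["XtX"] - (stats_["SX"].T * c) @ stats_["SX"]
    XtViy = stats_["Xty"] - stats_["SX"].T @ (c * stats_["Sy"])
    ytViy = stats_["yty"] - float(c @ (stats_["Sy"] ** 2))
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = ytViy - float(XtViy @ beta)
    if rss <= 0:
        return np.inf
    sigma2_e = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    return (
        (n - p) * math.log(sigma2_e)
        + float(np.log1p(lam * stats_["n_i"]).sum())
        + logdet
    )


def _profile_reml(y: np.ndarray, X: np.ndarray, codes: np.ndarray) -> dict:
    """REML fit of ``y = X beta + b[code] + e`` via the profiled ratio."""
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    _, start = np.unique(codes, return_index=True)
    n_i = np.diff(np.append(start, len(y))).astype(float)
    SX = np.add.reduceat(X, start, axis=0)
    Sy = np.add.reduceat(y, start)
    st = {
        "n": len(y),
        "p": X.shape[1],
        "n_i": n_i,
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "SX": SX,
        "Sy": Sy,
    }

    def f(theta: float) -> float:
        return _reml_neg2(math.exp(theta), st)

    res = optimize.minimize_scalar(
        f, bounds=(-25.0, 25.0), method="bounded", options={"xatol": 1e-12}
    )
    f0 = _reml_neg2(0.0, st)
    if f0 <= res.fun or res.x <= -24.0:
        lam, neg2, boundary = 0.0, f0, True
    else:
        lam, neg2, boundary = math.exp(res.x), float(res.fun), False

    c = lam / (1.0 + lam * n_i)
    XtViX = st["XtX"] - (SX.T * c) @ SX
    XtViy = st["Xty"] - SX.T @ (c * Sy)
    ytViy = st["yty"] - float(c @ (Sy**2))
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - float(XtViy @ beta)
    sigma2_e = rss / (len(y) - X.shape[1])
    return {
        "lambda": lam,
        "sigma2_between": lam * sigma2_e,
        "sigma2_residual": sigma2_e,
        "beta": beta,
        "cov_beta": sigma2_e * np.linalg.inv(XtViX),
        "n_subjects": len(n_i),
        "n": len(y),
        "boundary": boundary,
        "neg2": neg2,
    }


def _design(
    df: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for cov in covariates:
        s = df[cov]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    X = np.column_stack(cols)
    return _drop_collinear(X, names)


def _apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative outcome values")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r} (expected 'sqrt' or 'identity')")


def fit_random_intercept(
    day_table: pd.DataFrame,
    outcome: str,
    transform: str = "identity",
    fixed_covariates: Sequence[str] = (),
    group_col: str = "participant_id",
) -> VarianceComponents:
    """REML variance components of a day-level outcome.

    Rows with a missing outcome are dropped listwise. Covariates with a single
    observed level contribute nothing and are removed automatically; the fit
    is deterministic (no stochastic optimisation).
    """
    df = day_table.dropna(subset=[outcome])
    counts = df[group_col].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            f"need at least 2 subjects with at least 2 non-missing days of "
            f"{outcome!r}; got {dict(counts)}"
        )
    y = _apply_transform(df[outcome].to_numpy(dtype=float), transform)
    X, names = _design(df, fixed_covariates)
    codes = pd.factorize(df[group_col])[0]
    fit = _profile_reml(y, X, codes)

    fe: dict[str, dict[str, float]] = {}
    se = np.sqrt(np.diag(fit["cov_beta"]))
    for j, name in enumerate(names):
        b = float(fit["beta"][j])
        z = b / se[j] if se[j] > 0 else math.nan
        fe[name] = {
            "estimate": b,
            "se": float(se[j]),
            "ci_low": b - 1.959963984540054 * float(se[j]),
            "ci_high": b + 1.959963984540054 * float(se[j]),
            "p_value": float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else math.nan,
        }
    return VarianceComponents(
        sigma2_between=float(fit["sigma2_between"]),
        sigma2_residual=float(fit["sigma2_residual"]),
        fixed_effects=fe,
        n_subjects=int(fit["n_subjects"]),
        n_days_total=int(fit["n"]),
        boundary=bool(fit["boundary"]),
        reml_neg2loglik=float(fit["neg2"]),
    )


def icc_single_day(vc: VarianceComponents) -> float:
    """Between-subject share of total (between + residual) variance."""
    total = vc.sigma2_between + vc.sigma2_residual
    if total <= 0:
        return math.nan  # degenerate: no variance at all
    return vc.sigma2_between / total


def icc_with_ci(
    day_table: pd.DataFrame,
    outcome: str,
    transform: str = "identity",
    fixed_covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
    group_col: str = "participant_id",
) -> tuple[float, float, float]:
    """Point ICC with a percentile cluster-bootstrap 95% CI.

    Participants (clusters) are resampled with replacement; each resample is
    refit and its ICC recorded. Resamples where the fit degenerates are
    skipped.
    """
    point = icc_single_day(
        fit_random_intercept(day_table, outcome, transform, fixed_covariates, group_col)
    )
    rng = np.random.default_rng(seed)
    ids = day_table[group_col].unique()
    by_id = {pid: grp for pid, grp in day_table.groupby(group_col)}
    boots = []
    for _ in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for k, pid in enumerate(chosen):
            g = by_id[pid].copy()
            g[group_col] = f"bs{k}"
            frames.append(g)
        sample = pd.concat(frames, ignore_index=True)
        try:
            vc = fit_random_intercept(sample, outcome, transform, fixed_covariates, group_col)
        except (ValueError, np.linalg.LinAlgError):
            continue
        icc = icc_single_day(vc)
        if math.isfinite(icc):
            boots.append(icc)
    if len(boots) < max(10, n_boot // 10):
        return point, math.nan, math.nan
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


def spearman_brown(icc_single: float, n: float) -> float:
    """Composite reliability of the average of ``n`` days."""
    return n * icc_single / (1.0 + (n - 1.0) * icc_single)


def days_needed(icc_s: float, icc_t: float = 0.8) -> int:
    """Days of monitoring whose average reaches the target reliability.

    Inverts the Spearman-Brown prophecy formula and rounds up (minimum one
    day). A tiny epsilon guards against binary floating point pushing exact
    integer solutions (e.g. ICC_s = ICC_t) over the next ceiling.
    """
    if not 0 < icc_t < 1:
        raise ValueError(f"target ICC must lie in (0, 1), got {icc_t}")
    if icc_s <= 0:
        raise ValueError(f"single-day ICC must be positive, got {icc_s}")
    if icc_s >= 1:
        return 1
    n = icc_t / (1.0 - icc_t) * (1.0 - icc_s) / icc_s
    return max(1, math.ceil(n - 1e-9))


def _covariates_for(stratum: str, df: pd.DataFrame) -> list[str]:
    covs = ["care_level", "is_weekend", "facility_id"] if stratum == "whole_group" else [
        "is_weekend",
        "facility_id",
    ]
    return [c for c in covs if c in df.columns and df[c].nunique() > 1]


def reliability_table(
    day_table: pd.DataFrame,
    transforms: dict[str, str] | None = None,
    strata: Sequence[str] = STRATA,
    target_icc: float = 0.8,
    n_boot: int = 1000,
    seed: int = 0,
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One reliability row per outcome x stratum, Table-style ordering.

    Whole-group fits adjust for care level, weekday/weekend and facility;
    stratified fits adjust for weekday/weekend and facility. Strata with
    fewer than two participants are flagged unavailable rather than fitted.
    """
    transforms = dict(DEFAULT_TRANSFORMS, **(transforms or {}))
    outcomes = list(outcomes) if outcomes is not None else _OUTCOME_ORDER
    rows = []
    for outcome in outcomes:
        for stratum in strata:
            sub = (
                day_table
                if stratum == "whole_group"
                else day_table[day_table["care_level"] == stratum]
            )
            n_participants = sub["participant_id"].nunique()
            row = {
                "outcome": outcome,
                "stratum": stratum,
                "n_participants": int(n_participants),
                "icc": math.nan,
                "ci_low": math.nan,
                "ci_high": math.nan,
                "days_needed": pd.NA,
                "sigma2_between": math.nan,
                "sigma2_residual": math.nan,
                "boundary": False,
                "available": False,
            }
            if n_participants >= 2:
                try:
                    covs = _covariates_for(stratum, sub)
                    icc, lo, hi = icc_with_ci(
                        sub,
                        outcome,
                        transforms.get(outcome, "identity"),
                        covs,
                        n_boot=n_boot,
                        seed=seed,
                    )
                    vc = fit_random_intercept(
                        sub, outcome, transforms.get(outcome, "identity"), covs
                    )
                    row.update(
                        icc=icc,
                        ci_low=lo,
                        ci_high=hi,
                        sigma2_between=vc.sigma2_between,
                        sigma2_residual=vc.sigma2_residual,
                        boundary=vc.boundary,
                        available=True,
                    )
                    if math.isfinite(icc) and icc > 0:
                        row["days_needed"] = days_needed(icc, target_icc)
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


def day_of_week_effects(
    day_table: pd.DataFrame,
    outcome: str,
    transform: str = "identity",
    p_threshold: float = 0.01,
) -> DayEffectResult:
    """Week-structure tests for one outcome.

    Fits the random-intercept model with day-of-week as a 7-level fixed
    factor and reports all 21 pairwise Wald contrasts at the stated
    ``p_threshold`` (the threshold itself accounts for multiplicity; no
    further correction is layered on). A separate fit with a weekday/weekend
    dummy reports the weekend shift with 95% CI.
    """
    df = day_table.dropna(subset=[outcome])
    present = set(df["day_of_week"].unique())

    vc = fit_random_intercept(df, outcome, transform, ["day_of_week"])
    # effect of each day relative to the reference level absorbed in intercept
    names = [n for n in vc.fixed_effects if n.startswith("day_of_week_")]
    est = {n.removeprefix("day_of_week_"): vc.fixed_effects[n]["estimate"] for n in names}

    # rebuild the covariance over the day-effect coordinates for contrasts
    fit_df = df
    y = _apply_transform(fit_df[outcome].to_numpy(dtype=float), transform)
    X, xnames = _design(fit_df, ["day_of_week"])
    codes = pd.factorize(fit_df["participant_id"])[0]
    fit = _profile_reml(y, X, codes)
    idx = {n.removeprefix("day_of_week_"): j for j, n in enumerate(xnames) if n.startswith("day_of_week_")}

    rows = []
    for a_i in range(7):
        for b_i in range(a_i + 1, 7):
            a, b = WEEKDAYS[a_i], WEEKDAYS[b_i]
            row = {
                "day_a": a,
                "day_b": b,
                "estimate": math.nan,
                "se": math.nan,
                "p_value": math.nan,
                "significant": False,
                "available": a in present and b in present,
            }
            if row["available"]:
                L = np.zeros(X.shape[1])
                if a in idx:
                    L[idx[a]] += 1.0
                if b in idx:
                    L[idx[b]] -= 1.0
                e = float(L @ fit["beta"])
                se = float(np.sqrt(L @ fit["cov_beta"] @ L))
                z = e / se if se > 0 else 0.0
                p = float(2 * stats.norm.sf(abs(z)))
                row.update(estimate=e, se=se, p_value=p, significant=p < p_threshold)
            rows.append(row)

    wk = fit_random_intercept(df, outcome, transform, ["is_weekend"])
    wfe = wk.fixed_effects.get("is_weekend")
    weekend = (
        {
            "estimate": wfe["estimate"],
            "ci_low": wfe["ci_low"],
            "ci_high": wfe["ci_high"],
            "p_value": wfe["p_value"],
        }
        if wfe
        else {"estimate": math.nan, "ci_low": math.nan, "ci_high": math.nan, "p_value": math.nan}
    )
    return DayEffectResult(
        pairwise=pd.DataFrame(rows), weekend_beta=weekend, p_threshold=p_threshold
    )
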