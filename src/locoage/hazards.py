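"""Supervised risk models: ridge Cox on activity descriptors and the
parametric Cox–Gompertz likelihood.

The "LogMort"/"LogMorb" models are Cox proportional-hazards fits with 65
covariates (the 64 log-transition-matrix elements plus a gender label),
ridge-penalized with a small weight because the descriptor coordinates are
strongly collinear; chronological age is deliberately not a covariate, so
the linear predictor itself behaves as a log-scaled biological age.  The
Cox–Gompertz model checks that the cohort's mortality follows the Gompertz
law ``mu(t) = M0 * exp(Gamma * t)`` by maximizing, over (M0, Gamma), the
censored log-likelihood

    logL = sum_i (M0/Gamma) e^(Gamma t_i) (1 - e^(Gamma dt_i))
         + sum_i delta_i (ln M0 + Gamma t_i + Gamma dt_i)

with t_i the age at entry, dt_i the follow-up and delta_i the death
indicator.  Association tests and group comparisons quantify how a
detrended score relates to observed outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from lifelines import CoxPHFitter

__all__ = [
    "HazardModel",
    "CoxGompertzFit",
    "AssocResult",
    "fit_cox_ridge",
    "predict_log_hazard",
    "gompertz_loglik",
    "fit_cox_gompertz",
    "doubling_time",
    "assoc_test",
    "compare_groups",
]

DEFAULT_PENALTY = 0.01


# ---------------------------------------------------------------------------
# Ridge-penalized Cox proportional hazards (Efron ties)


@dataclass
class HazardModel:
    """Ridge Cox model over descriptor + gender covariates."""

    coef: np.ndarray          # on the original covariate scale
    center: np.ndarray
    scale: np.ndarray
    penalty: float
    endpoint: str = "mortality"
    loglik: float = np.nan

    @property
    def n_covariates(self) -> int:
        return self.coef.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coef": self.coef.tolist(),
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                    "penalty": self.penalty,
                    "endpoint": self.endpoint,
                    "loglik": self.loglik,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "HazardModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coef=np.asarray(d["coef"]),
            center=np.asarray(d["center"]),
            scale=np.asarray(d["scale"]),
            penalty=d["penalty"],
            endpoint=d["endpoint"],
            loglik=d["loglik"],
        )


def _efron_groups(times: np.ndarray, events: np.ndarray):
    """Sorted order plus, per distinct event time: (risk-set start, event idx)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(bool)
    groups = []
    event_times = np.unique(t[e])
    for et in event_times:
        i0 = int(np.searchsorted(t, et, side="left"))
        d_idx = np.flatnonzero((t == et) & e)
        groups.append((i0, d_idx))
    return order, groups


def _efron_negloglik_grad(
    beta: np.ndarray,
    X: np.ndarray,
    order: np.ndarray,
    groups,
    lam: float,
) -> tuple[float, np.ndarray]:
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    # suffix sums over the risk sets (times sorted ascending)
    cum_w = np.cumsum(w[::-1])[::-1]
    cum_wx = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros_like(beta)
    for i0, d_idx in groups:
        d = d_idx.size
        S_r = cum_w[i0]
        Z_r = cum_wx[i0]
        S_d = w[d_idx].sum()
        Z_d = (w[d_idx, None] * Xs[d_idx]).sum(axis=0)
        ll += eta[d_idx].sum()
        grad += Xs[d_idx].sum(axis=0)
        frac = np.arange(d) / d
        denom = S_r - frac * S_d
        ll -= np.log(denom).sum()
        grad -= ((Z_r[None, :] - frac[:, None] * Z_d[None, :])
                 / denom[:, None]).sum(axis=0)
    ll -= 0.5 * lam * beta @ beta
    grad -= lam * beta
    return -ll, -grad


def fit_cox_ridge(
    descriptors: np.ndarray,
    gender: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    penalty: float = DEFAULT_PENALTY,
    endpoint: str = "mortality",
    standardize: bool = True,
) -> HazardModel:
    """Maximize the Efron partial likelihood minus ``(penalty/2)*||beta||^2``.

    Covariates (descriptor columns and the gender label) are centred and,
    by default, scaled to unit variance before penalization — the penalty
    is otherwise scale-dependent — and the coefficients are mapped back to
    the original scale.  Age is deliberately excluded as a covariate.
    """
    X = np.column_stack([np.asarray(descriptors, float),
                         np.asarray(gender, float)])
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if events.sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    center = X.mean(axis=0)
    scale = X.std(axis=0) if standardize else np.ones(X.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale
    order, groups = _efron_groups(times, events)
    res = scipy.optimize.minimize(
        _efron_negloglik_grad,
        np.zeros(X.shape[1]),
        args=(Xs, order, groups, penalty),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"ridge Cox fit did not converge: {res.message}")
    beta_std = res.x
    return HazardModel(
        coef=beta_std / scale,
        center=center,
        scale=scale,
        penalty=penalty,
        endpoint=endpoint,
        loglik=float(-res.fun),
    )


def predict_log_hazard(
    model: HazardModel,
    descriptors: np.ndarray,
    gender: np.ndarray,
) -> np.ndarray:
    """Linear predictor ("logMort"/"logMorb" score) about the training centre.

    The training covariate mean scores 0; adding a constant to any
    covariate shifts all scores equally, leaving relative risks unchanged.
    """
    X = np.column_stack(
        [np.atleast_2d(np.asarray(descriptors, float)),
         np.asarray(gender, float).reshape(-1, 1)]
    )
    if X.shape[1] != model.n_covariates:
        raise ValueError(
            f"expected {model.n_covariates} covariates, got {X.shape[1]}"
        )
    return (X - model.center) @ model.coef


# ---------------------------------------------------------------------------
# Parametric Cox–Gompertz model


@dataclass
class CoxGompertzFit:
    M0: float
    Gamma: float
    loglik: float
    se_M0: float = np.nan
    se_Gamma: float = np.nan


def gompertz_loglik(
    M0: float,
    Gamma: float,
    ages: np.ndarray,
    followups: np.ndarray,
    events: np.ndarray,
) -> float:
    """Censored Gompertz log-likelihood at (M0, Gamma)."""
    if M0 <= 0 or Gamma <= 0:
        raise ValueError("M0 and Gamma must be positive")
    t = np.asarray(ages, dtype=float)
    dt = np.asarray(followups, dtype=float)
    if np.any(dt < 0):
        raise ValueError("follow-up durations must be non-negative")
    d = np.asarray(events, dtype=float)
    surv = (M0 / Gamma) * np.exp(Gamma * t) * (1.0 - np.exp(Gamma * dt))
    ev = d * (np.log(M0) + Gamma * t + Gamma * dt)
    return float(surv.sum() + ev.sum())


#: search box for (ln M0, ln Gamma): hazards up to 1/yr, doubling times >= ~8 months
GOMPERTZ_BOUNDS = ((-30.0, 0.0), (-7.0, 0.0))


def _gompertz_negll_grad(theta, t, dt, d):
    # theta = (ln M0, ln Gamma); analytic gradient in these coordinates
    M0, G = np.exp(theta)
    egt = np.exp(G * t)
    egdt = np.exp(G * dt)
    a = egt * (1.0 - egdt)
    ll = (M0 / G) * a.sum() + d.sum() * np.log(M0) + G * (d * (t + dt)).sum()
    dM0 = (1.0 / G) * a.sum() + d.sum() / M0
    da_dG = t * egt * (1.0 - egdt) - egt * dt * egdt
    dG = (
        -(M0 / G**2) * a.sum()
        + (M0 / G) * da_dG.sum()
        + (d * (t + dt)).sum()
    )
    grad = np.array([M0 * dM0, G * dG])
    return -ll, -grad


def fit_cox_gompertz(
    ages: np.ndarray,
    followups: np.ndarray,
    events: np.ndarray,
    starts: tuple = ((1e-5, 0.08), (1e-4, 0.05), (1e-3, 0.12)),
) -> CoxGompertzFit:
    """Maximum-likelihood Gompertz fit of the empirical mortality pattern.

    Optimizes over (ln M0, ln Gamma) for positivity, from several starts,
    with the analytic gradient; standard errors come from the numerical
    curvature at the optimum, mapped back from the log scale.
    """
    t = np.asarray(ages, dtype=float)
    dt = np.asarray(followups, dtype=float)
    d = np.asarray(events, dtype=float)
    if d.sum() == 0:
        raise ValueError(
            "no events observed; the likelihood is unbounded toward M0 -> 0"
        )
    best = None
    for m0, g in starts:
        res = scipy.optimize.minimize(
            _gompertz_negll_grad,
            np.log([m0, g]),
            args=(t, dt, d),
            jac=True,
            method="L-BFGS-B",
            bounds=GOMPERTZ_BOUNDS,
            options={"gtol": 1e-10, "ftol": 1e-14, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    # numerical Hessian from the analytic gradient
    h = 1e-5
    H = np.zeros((2, 2))
    for k in range(2):
        tp = theta.copy(); tp[k] += h
        tmm = theta.copy(); tmm[k] -= h
        _, gp = _gompertz_negll_grad(tp, t, dt, d)
        _, gm = _gompertz_negll_grad(tmm, t, dt, d)
        H[:, k] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov_log = np.linalg.inv(H)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.array([np.nan, np.nan])
    M0, G = np.exp(theta)
    return CoxGompertzFit(
        M0=float(M0),
        Gamma=float(G),
        loglik=float(-best.fun),
        se_M0=float(M0 * se_log[0]),
        se_Gamma=float(G * se_log[1]),
    )


def doubling_time(gamma: float) -> float:
    """Mortality-rate doubling time ln(2)/Gamma in years."""
    if gamma <= 0:
        raise ValueError("Gamma must be positive")
    return float(np.log(2.0) / gamma)


# ---------------------------------------------------------------------------
# Association tests and group comparisons


@dataclass
class AssocResult:
    """Hazard ratio per SD of a detrended score, with CI and p-value."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int

    def covers(self, hr: float = 1.0) -> bool:
        return self.ci_low <= hr <= self.ci_high


def assoc_test(
    score: np.ndarray,
    ages: np.ndarray,
    genders: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    detrend_first: bool = True,
) -> AssocResult:
    """Cox association of a score with outcomes, adjusted for age and gender.

    The score is linearly detrended by age and gender (so the test
    reflects only its age/gender-independent part), standardized, and
    entered into an unpenalized Cox model alongside chronological age and
    gender.  The hazard ratio is reported per standard deviation of the
    detrended score.
    """
    score = np.asarray(score, dtype=float)
    if score.std() == 0:
        raise ValueError("score has zero variance")
    if np.sum(events) < 1:
        raise ValueError("need at least one event")
    if detrend_first:
        from .bioage import detrend

        score = detrend(score, ages, genders).baa
    z = score / score.std(ddof=1)
    df = pd.DataFrame(
        {
            "age": np.asarray(ages, float),
            "gender": np.asarray(genders, float),
            "score": z,
            "T": np.asarray(times, float),
            "E": np.asarray(events, int),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    s = cph.summary.loc["score"]
    return AssocResult(
        hr=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n=len(df),
        events=int(df["E"].sum()),
    )


def compare_groups(values: np.ndarray, labels: np.ndarray) -> dict:
    """Per-group median ± S.E.M. and rank-based pairwise tests.

    Returns a per-group summary table and a table of two-sided
    Mann–Whitney p-values for every pair (e.g. current vs never vs former
    smokers).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    summary_rows = []
    by_group = {}
    for g in names:
        v = values[labels == g]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        by_group[g] = v
        summary_rows.append(
            {
                "group": g,
                "n": v.size,
                "median": float(np.median(v)),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
            }
        )
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stat, p = scipy.stats.mannwhitneyu(
                by_group[a], by_group[b], alternative="two-sided"
            )
            pairs.append({"group_a": a, "group_b": b, "u": float(stat),
                          "p": float(p)})
    return {
        "summary": pd.DataFrame(summary_rows),
        "pairwise": pd.DataFrame(pairs),
    }
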