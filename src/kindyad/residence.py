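"""Survival and tenure analyses of male group residence.

Implements the downstream fitness-correlate models: Kaplan-Meier curves of
continued residence, a Cox proportional-hazards fit of residence time on kin
presence (partial likelihood, Breslow or Efron ties, Newton-Raphson), a
logistic likelihood-ratio test of staying at least one year, a linear model
of high-rank tenure, and a cluster bootstrap over individuals as a surrogate
for individual-level random effects.

Time unit is months throughout; censoring is right-censoring only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MaleResidenceRecord",
    "SurvivalFit",
    "km_curve",
    "cox_fit",
    "stay_one_year_test",
    "tenure_model",
    "cluster_bootstrap",
    "records_to_frame",
    "records_from_frame",
]


@dataclass
class MaleResidenceRecord:
    """One residence spell of a male in a group.

    ``duration_months`` runs from group entry to departure, or to the end of
    observation if ``censored``. ``high_rank_tenure_months`` is present only
    for males who reached rank 1-3 during the spell.
    """

    male_id: str
    group_id: str
    entry_month: int
    duration_months: int
    censored: bool = False
    natal_disperser: bool = False
    kin_at_entry: bool = False
    kin_3mo: bool = False
    peer_at_entry: bool = False
    coresidence_fraction: float = 0.0
    high_rank_tenure_months: Optional[float] = None
    max_rank: Optional[int] = None
    group_n_nonnatal_males: Optional[int] = None
    natal_group: Optional[str] = None
    birth_year: Optional[int] = None

    def __post_init__(self):
        if self.duration_months < 1:
            raise ValueError("duration_months must be >= 1")
        if not (0.0 <= self.coresidence_fraction <= 1.0):
            raise ValueError("coresidence_fraction must lie in [0, 1]")

    @property
    def exit_month(self) -> int:
        return self.entry_month + self.duration_months


@dataclass
class SurvivalFit:
    """A fitted effect: coefficient, Wald and likelihood-ratio summaries."""

    beta: float
    se: float
    z: float
    chi2_lr: float
    p_lr: float
    n: int
    n_events: int
    converged: bool = True
    note: str = ""


def records_to_frame(records: Sequence[MaleResidenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def records_from_frame(df: pd.DataFrame) -> list:
    cols = {f for f in MaleResidenceRecord.__dataclass_fields__}
    out = []
    for _, row in df.iterrows():
        kw = {k: row[k] for k in df.columns if k in cols}
        for opt in ("high_rank_tenure_months", "max_rank", "group_n_nonnatal_males"):
            if opt in kw and pd.isna(kw[opt]):
                kw[opt] = None
        out.append(MaleResidenceRecord(**kw))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_curve(records: Sequence[MaleResidenceRecord], group_by: Optional[str] = None) -> dict:
    """Product-limit survival curves, optionally stratified by a flag field.

    Returns a dict mapping stratum value -> DataFrame with columns
    ``time``, ``n_at_risk``, ``n_events``, ``survival``. Survival starts at 1
    and is non-increasing.
    """
    if not records:
        raise ValueError("no records")
    strata: dict = {}
    for r in records:
        key = getattr(r, group_by) if group_by else "all"
        strata.setdefault(key, []).append(r)
    out = {}
    for key, recs in strata.items():
        times = np.array([r.duration_months for r in recs], dtype=float)
        events = np.array([not r.censored for r in recs], dtype=bool)
        order = np.argsort(times)
        times, events = times[order], events[order]
        rows = [(0.0, len(recs), 0, 1.0)]
        surv = 1.0
        for t in np.unique(times[events]):
            at_risk = int(np.sum(times >= t))
            d = int(np.sum((times == t) & events))
            surv *= 1.0 - d / at_risk
            rows.append((float(t), at_risk, d, surv))
        out[key] = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (partial likelihood)

def _cox_loglik(beta, times, events, X, ties):
    """Partial log-likelihood with gradient and Hessian (Breslow or Efron)."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times)  # decreasing time: accumulate risk sets
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1 = 0.0, np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    ts = times[order]
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        idx = order[i:j]
        for k in idx:  # everyone at this time joins the risk set
            S0 += w[k]
            S1 += w[k] * X[k]
            S2 += w[k] * np.outer(X[k], X[k])
        dead = idx[events[idx]]
        d = len(dead)
        if d > 0:
            xsum = X[dead].sum(axis=0)
            ll += eta[dead].sum()
            if ties == "breslow":
                ll -= d * np.log(S0)
                grad += xsum - d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1 / S0, S1 / S0))
            else:  # efron
                w_d = w[dead].sum()
                S1_d = (w[dead, None] * X[dead]).sum(axis=0)
                S2_d = sum(w[k] * np.outer(X[k], X[k]) for k in dead)
                for m in range(d):
                    f = m / d
                    s0 = S0 - f * w_d
                    s1 = S1 - f * S1_d
                    s2 = S2 - f * S2_d
                    ll -= np.log(s0)
                    grad -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1 / s0, s1 / s0)
                grad += xsum
        i = j
    return ll, grad, hess


def _newton_cox(times, events, X, ties, tol=1e-8, max_iter=60):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, times, events, X, ties)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = _cox_loglik(cand, times, events, X, ties)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.linalg.norm(beta) > 50:
            break  # monotone likelihood / separation
    converged = bool(np.linalg.norm(grad) < tol)
    return beta, ll, hess, converged


def cox_fit(records: Sequence[MaleResidenceRecord], covariates: Sequence[str],
            interaction: Optional[tuple] = None, ties: str = "breslow") -> dict:
    """Cox proportional-hazards fit of residence duration on record flags.

    ``covariates`` are field names of :class:`MaleResidenceRecord` (binary
    flags or numeric); ``interaction=(a, b)`` adds a product term ``"a:b"``.
    Returns a dict mapping term name -> :class:`SurvivalFit`; each term's
    likelihood-ratio statistic compares the full model against the model
    with that term dropped. Complete separation is flagged via
    ``converged=False`` rather than raising.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    times = np.array([r.duration_months for r in records], dtype=float)
    events = np.array([not r.censored for r in records], dtype=bool)
    if events.sum() == 0:
        raise ValueError("no events (all records censored)")
    names = list(covariates)
    cols = [np.array([float(getattr(r, c)) for r in records]) for c in names]
    if interaction is not None:
        a, b = interaction
        cols.append(np.array([float(getattr(r, a)) * float(getattr(r, b))
                              for r in records]))
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    # centring improves conditioning; leaves partial likelihood shape intact
    X = X - X.mean(axis=0)
    beta, ll_full, hess, converged = _newton_cox(times, events, X, ties)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(len(names), np.nan)
        converged = False
    out = {}
    for j, name in enumerate(names):
        if X.shape[1] > 1:
            Xr = np.delete(X, j, axis=1)
            _, ll_red, _, _ = _newton_cox(times, events, Xr, ties)
        else:
            ll_red, _, _ = _cox_loglik(np.zeros(1), times, events, X, ties)
        chi2 = max(0.0, 2.0 * (ll_full - ll_red))
        se = ses[j]
        z = beta[j] / se if se > 0 else np.nan
        # a vanishing gradient on a likelihood plateau still "converges":
        # flag runaway coefficients / exploded SEs as monotone likelihood
        ok = converged and abs(beta[j]) <= 15 and (0 < se <= 100)
        out[name] = SurvivalFit(
            beta=float(beta[j]), se=float(se), z=float(z),
            chi2_lr=float(chi2), p_lr=float(stats.chi2.sf(chi2, df=1)),
            n=len(records), n_events=int(events.sum()),
            converged=bool(ok),
            note="" if ok else "monotone likelihood or separation suspected",
        )
    return out


# ---------------------------------------------------------------------------
# One-year-stay logistic LR test

def stay_one_year_test(records: Sequence[MaleResidenceRecord],
                       predictor: str = "kin_at_entry") -> SurvivalFit:
    """Logistic likelihood-ratio test of staying >= 12 months on a kin flag.

    Records censored before month 12 carry no information on the one-year
    outcome and are excluded (count reported in the ``note``).
    """
    import statsmodels.api as sm

    usable = [r for r in records if not (r.censored and r.duration_months < 12)]
    n_excluded = len(records) - len(usable)
    if not usable:
        raise ValueError("no usable records after censoring exclusion")
    y = np.array([r.duration_months >= 12 for r in usable], dtype=float)
    x = np.array([float(getattr(r, predictor)) for r in usable])
    if y.min() == y.max():
        raise ValueError("one-year outcome is constant; test undefined")
    X = sm.add_constant(x)
    note = f"{n_excluded} records censored before month 12 excluded"
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones_like(y)).fit(disp=0, maxiter=200)
            beta, se = full.params[1], full.bse[1]
            ll_full, ll_null = full.llf, null.llf
        except Exception:
            separated = True
    if not separated and (not np.isfinite(se) or abs(beta) > 15):
        separated = True
    if separated:
        # perfect separation: LR is still well-defined from the saturated
        # two-binomial likelihoods; Wald quantities are not
        ll_full = _two_binomial_loglik(y, x)
        ll_null = _binomial_loglik(y)
        beta, se = np.inf, np.nan
        note += "; perfect separation: infinite beta, median-unbiased estimate advised"
    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    return SurvivalFit(
        beta=float(beta), se=float(se),
        z=float(beta / se) if np.isfinite(se) and se > 0 else np.nan,
        chi2_lr=float(chi2), p_lr=float(stats.chi2.sf(chi2, df=1)),
        n=len(usable), n_events=int(y.sum()),
        converged=not separated, note=note,
    )


def _binomial_loglik(y):
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    k, n = y.sum(), len(y)
    return k * np.log(p) + (n - k) * np.log(1 - p)


def _two_binomial_loglik(y, x):
    ll = 0.0
    for v in np.unique(x):
        ll += _binomial_loglik(y[x == v])
    return ll


# ---------------------------------------------------------------------------
# High-rank tenure linear model

def tenure_model(records: Sequence[MaleResidenceRecord],
                 predictor: str = "kin_at_entry",
                 min_males_rule: bool = True) -> SurvivalFit:
    """OLS of high-rank tenure (months) on a kin flag, with eligibility filter.

    Eligible records held rank 1-3; when fewer than five non-natal males were
    resident in the group, only ranks 1-2 qualify (``min_males_rule``).
    The likelihood-ratio statistic compares Gaussian likelihoods of the full
    and intercept-only models.
    """
    import statsmodels.api as sm

    eligible = []
    for r in records:
        if r.high_rank_tenure_months is None or r.max_rank is None:
            continue
        if r.max_rank > 3:
            continue
        if (min_males_rule and r.group_n_nonnatal_males is not None
                and r.group_n_nonnatal_males < 5 and r.max_rank > 2):
            continue
        eligible.append(r)
    if len(eligible) < 3:
        raise ValueError(
            "fewer than 3 records eligible after the high-rank filter "
            "(rank <= 3, or <= 2 in groups with < 5 non-natal males)")
    y = np.array([r.high_rank_tenure_months for r in eligible], dtype=float)
    x = np.array([float(getattr(r, predictor)) for r in eligible])
    X = sm.add_constant(x) if x.min() != x.max() else np.ones((len(y), 1))
    fit = sm.OLS(y, X).fit()
    n = len(y)
    rss_full = float(np.sum(fit.resid ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    if x.min() == x.max():
        beta, se, t = 0.0, np.nan, np.nan
        chi2 = 0.0
    else:
        beta, se, t = fit.params[1], fit.bse[1], fit.tvalues[1]
        chi2 = n * np.log(rss_null / rss_full) if rss_full > 0 else np.inf
    return SurvivalFit(
        beta=float(beta), se=float(se), z=float(t),
        chi2_lr=float(chi2), p_lr=float(stats.chi2.sf(chi2, df=1)),
        n=n, n_events=n,
    )


# ---------------------------------------------------------------------------
# Cluster bootstrap

def cluster_bootstrap(records: Sequence[MaleResidenceRecord],
                      fit_fn: Callable[[Sequence[MaleResidenceRecord]], float],
                      n_boot: int = 500, seed: int = 0,
                      ci_level: float = 0.95) -> dict:
    """Percentile bootstrap resampling whole males (clusters of spells).

    ``fit_fn`` maps a record list to a scalar effect estimate. Surrogate for
    individual-level random effects: resampling clusters propagates
    within-male dependence into the interval. Returns point estimate,
    bootstrap SE, percentile CI, and the refit-failure count (warns above
    10% failures).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    clusters: dict = {}
    for r in records:
        clusters.setdefault(r.male_id, []).append(r)
    keys = list(clusters)
    point = fit_fn(records)
    estimates = []
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.choice(len(keys), size=len(keys), replace=True)
        resampled = [rec for i in draw for rec in clusters[keys[i]]]
        try:
            est = fit_fn(resampled)
            if not np.isfinite(est):
                raise ValueError
            estimates.append(est)
        except Exception:
            n_failed += 1
    failure_rate = n_failed / n_boot
    if failure_rate > 0.10:
        warnings.warn(f"cluster bootstrap: {failure_rate:.0%} of refits failed")
    estimates = np.asarray(estimates)
    lo, hi = np.quantile(estimates, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return {
        "estimate": float(point),
        "boot_se": float(estimates.std(ddof=1)),
        "ci": (float(lo), float(hi)),
        "ci_level": ci_level,
        "n_boot": n_boot,
        "n_failed": n_failed,
    }
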