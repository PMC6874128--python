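"""Survival datasets and models for per-tumor and per-patient failure.

Two endpoints drive the analysis:

* ITFFR (individual tumor failure-free rate): one row per primary or nodal
  tumor, time from the start of RT to that tumor's progression, censored for
  all of a patient's tumors at the earliest of distant failure, death or
  last follow-up.
* DFFS (distant-failure-free survival): one row per patient, time to distant
  failure, censored at the first locoregional failure, death or last
  follow-up.

Cox proportional-hazards fitting is implemented here directly (Newton
iteration on the partial likelihood, Breslow ties by default, Efron as an
option) because the analysis contract needs per-SD covariate scaling,
covariate centering, interaction-derived group effects and an optional
cluster-robust sandwich variance for tumors nested in patients — with the
fit checkable against an exhaustive partial-likelihood search. Harrell's
concordance, Benjamini–Hochberg FDR control, the nonparametric rank tests
and the 18-month landmark classification round out the statistics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import inf, isnan, nan

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OutcomeRecord",
    "CoxSpec",
    "CoxFit",
    "build_itffr",
    "build_dffs",
    "cox_partial_loglik",
    "fit_cox",
    "concordance",
    "bh_fdr",
    "rank_test",
    "logrank_groups",
    "landmark_groups",
    "outcomes_to_frame",
]


# ---------------------------------------------------------------------------
# Outcome bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class OutcomeRecord:
    """Follow-up record for one tumor.

    ``prog_time`` is the tumor's own locoregional progression time (months;
    NaN if it never progressed); ``df_time`` and ``death_time`` are the
    patient-level distant-failure and death times (NaN if unobserved);
    ``last_followup`` is the administrative follow-up time. The derived
    ``event_type``/``event_time`` give the tumor's first recorded event.
    """

    patient_id: str
    tumor_id: str
    kind: str  # primary | nodal
    prog_time: float = nan
    df_time: float = nan
    death_time: float = nan
    last_followup: float = nan

    @property
    def event_time(self) -> float:
        cands = [t for t in (self.prog_time, self.df_time, self.death_time) if not isnan(t)]
        return min(cands) if cands else nan

    @property
    def event_type(self) -> str:
        t = self.event_time
        if isnan(t):
            return "none"
        if not isnan(self.prog_time) and self.prog_time == t:
            return "LF" if self.kind == "primary" else "RF"
        if not isnan(self.df_time) and self.df_time == t:
            return "DF"
        return "death"


def outcomes_to_frame(outcomes) -> pd.DataFrame:
    """Normalize a list of OutcomeRecords or a DataFrame into a DataFrame
    with the outcome columns."""
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "tumor_id": r.tumor_id,
                    "kind": r.kind,
                    "prog_time": r.prog_time,
                    "df_time": r.df_time,
                    "death_time": r.death_time,
                    "last_followup": r.last_followup,
                }
                for r in outcomes
            ]
        )
    required = {"patient_id", "tumor_id", "kind", "prog_time", "df_time", "death_time", "last_followup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    return df


def build_itffr(outcomes, metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tumor failure-free survival table.

    event = 1 iff the tumor itself progressed before the patient-level
    censoring time min(DF, death, last follow-up); otherwise the row is
    censored at that time. Tumors without follow-up are dropped with a
    warning. ``metrics`` (indexed or keyed by tumor_id) is joined on as
    covariates when given.
    """
    df = outcomes_to_frame(outcomes)
    no_fup = df["last_followup"].isna()
    if no_fup.any():
        warnings.warn(f"dropping {int(no_fup.sum())} tumors without follow-up", stacklevel=2)
        df = df[~no_fup].copy()
    censor = df[["df_time", "death_time", "last_followup"]].min(axis=1, skipna=True)
    event = df["prog_time"].notna() & (df["prog_time"] <= censor)
    out = pd.DataFrame(
        {
            "unit_id": df["tumor_id"],
            "patient_id": df["patient_id"],
            "kind": df["kind"],
            "time": np.where(event, df["prog_time"], censor),
            "event": event.astype(int),
        }
    )
    if metrics is not None:
        m = metrics.set_index("tumor_id") if "tumor_id" in metrics.columns else metrics
        out = out.join(m, on="unit_id")
    return out.reset_index(drop=True)


def build_dffs(outcomes) -> pd.DataFrame:
    """Per-patient distant-failure-free survival table.

    event = 1 iff distant failure occurs no later than the first
    locoregional failure (any tumor), death, or last follow-up; otherwise
    censored at the earliest of those.
    """
    df = outcomes_to_frame(outcomes)
    no_fup = df["last_followup"].isna()
    if no_fup.any():
        warnings.warn(f"dropping {int(no_fup.sum())} tumors without follow-up", stacklevel=2)
        df = df[~no_fup].copy()
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        lrf = grp["prog_time"].min(skipna=True)  # earliest locoregional failure
        dft = grp["df_time"].min(skipna=True)
        death = grp["death_time"].min(skipna=True)
        fup = grp["last_followup"].max(skipna=True)
        censor = np.nanmin([lrf, death, fup])
        if not isnan(dft) and dft <= censor:
            rows.append({"unit_id": pid, "patient_id": pid, "time": dft, "event": 1})
        else:
            rows.append({"unit_id": pid, "patient_id": pid, "time": censor, "event": 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxSpec:
    """Covariate plan for :func:`fit_cox`.

    ``per_sd`` covariates are divided by their sample SD over the analysis
    rows (hazard ratios are then per 1 SD); ``center`` covariates have the
    sample mean subtracted, so a main effect in an interaction model is the
    effect at the mean of the centered partner. ``interactions`` are pairs
    (a, b) adding a product term named "a:b"; for a binary b the fit also
    reports the derived effect of a in each b-group.
    """

    covariates: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    per_sd: frozenset = frozenset()
    center: frozenset = frozenset()
    ties: str = "breslow"  # breslow | efron
    cluster_col: str | None = None  # adds a sandwich SE over these clusters


@dataclass
class CoxFit:
    summary: pd.DataFrame  # coef, hr, se, ci95_lo, ci95_hi, z, wald_p per term
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    c_index: float
    group_effects: pd.DataFrame | None = None
    robust_summary: pd.DataFrame | None = None
    message: str = ""

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


def cox_partial_loglik(
    beta: np.ndarray,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox log partial likelihood at ``beta`` (used directly by the
    brute-force oracle tests; the fitter maximizes the same function)."""
    ll, _, _ = _loglik_grad_hess(np.asarray(beta, float), x, time, event, ties, want_derivs=False)
    return ll


def _loglik_grad_hess(beta, x, time, event, ties, want_derivs=True):
    n, p = x.shape
    order = np.argsort(time, kind="stable")
    x = x[order]
    time = time[order]
    event = event[order]
    eta = x @ beta
    # guard against overflow in degenerate searches
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # risk set at t: subjects with time >= t; iterate unique event times
    # from largest to smallest, accumulating suffix sums
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = n - 1
    unique_times = np.unique(time[event == 1])[::-1]
    for t in unique_times:
        while i >= 0 and time[i] >= t:
            s0 += w[i]
            s1 += w[i] * x[i]
            s2 += w[i] * np.outer(x[i], x[i])
            i -= 1
        d_idx = np.where((time == t) & (event == 1))[0]
        d = len(d_idx)
        xd = x[d_idx]
        ll += float(eta[d_idx].sum())
        if ties == "breslow":
            ll -= d * np.log(s0)
            if want_derivs:
                mu = s1 / s0
                grad += xd.sum(axis=0) - d * mu
                hess -= d * (s2 / s0 - np.outer(mu, mu))
        elif ties == "efron":
            wd = w[d_idx].sum()
            s1d = (w[d_idx, None] * xd).sum(axis=0)
            s2d = np.einsum("i,ij,ik->jk", w[d_idx], xd, xd)
            for l in range(d):
                f = l / d
                denom = s0 - f * wd
                ll -= np.log(denom)
                if want_derivs:
                    num1 = s1 - f * s1d
                    mu = num1 / denom
                    grad_term = mu
                    grad -= grad_term
                    hess -= (s2 - f * s2d) / denom - np.outer(mu, mu)
            if want_derivs:
                grad += xd.sum(axis=0)
        else:
            raise ValueError("ties must be 'breslow' or 'efron'")
    return ll, grad, hess


def _newton_cox(x, time, event, ties, max_iter=60, tol=1e-9):
    p = x.shape[1]
    beta = np.zeros(p)
    ll_old = -inf
    for _ in range(max_iter):
        ll, grad, hess = _loglik_grad_hess(beta, x, time, event, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, hess, False, "singular information matrix"
        # step-halving to keep the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik_grad_hess(cand, x, time, event, ties, want_derivs=False)[0]
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if np.abs(beta).max() > 50:
            return beta, ll, hess, False, "monotone likelihood (diverging coefficient)"
        if np.max(np.abs(grad)) < tol or abs(ll - ll_old) < tol * (abs(ll) + 1):
            ll, grad, hess = _loglik_grad_hess(beta, x, time, event, ties)
            return beta, ll, hess, True, ""
        ll_old = ll
    return beta, ll, hess, False, "max iterations reached"


def _score_residuals(beta, x, time, event, ties):
    """Per-subject score residuals (Breslow form), for the cluster sandwich."""
    n, p = x.shape
    eta = np.clip(x @ beta, -500, 500)
    w = np.exp(eta)
    # event times and risk-set moments at each event time
    ev_times = np.unique(time[event == 1])
    resid = np.zeros((n, p))
    for t in ev_times:
        at_risk = time >= t
        s0 = w[at_risk].sum()
        mu = (w[at_risk, None] * x[at_risk]).sum(axis=0) / s0
        d_idx = (time == t) & (event == 1)
        d = int(d_idx.sum())
        resid[d_idx] += x[d_idx] - mu
        contrib = d * (w[:, None] * (x - mu)) / s0
        resid[at_risk] -= contrib[at_risk]
    return resid


def _build_design(table: pd.DataFrame, spec: CoxSpec):
    cols = {}
    for name in spec.covariates:
        if name not in table.columns:
            raise ValueError(f"covariate {name!r} missing from table")
        v = table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {name!r} has non-finite values")
        scale = 1.0
        if name in spec.per_sd:
            scale = float(np.std(v, ddof=1))
            if scale == 0:
                raise ValueError(f"covariate {name!r} has zero SD")
            v = v / scale
        if name in spec.center:
            v = v - v.mean()
        cols[name] = v
    for a, b in spec.interactions:
        if a not in cols or b not in cols:
            raise ValueError(f"interaction ({a}, {b}) references unknown covariate")
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    names = list(cols)
    x = np.column_stack([cols[k] for k in names])
    return x, names


def fit_cox(table: pd.DataFrame, spec: CoxSpec) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton iteration on the
    partial likelihood.

    ``table`` needs ``time`` and ``event`` columns plus the covariates named
    in ``spec``. The naive (model-based) SE is the default, mirroring a
    tumor-level analysis without cluster correction; when
    ``spec.cluster_col`` is set a cluster-robust sandwich summary is added
    alongside. For each interaction (a, b) with binary b, the derived effect
    of a in the b=0 group (β_a) and in the b=1 group (β_a + β_{a:b}) is
    reported with its delta-method SE.
    """
    if "time" not in table.columns or "event" not in table.columns:
        raise ValueError("table must have 'time' and 'event' columns")
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    if int(event.sum()) < 2:
        raise ValueError("need at least 2 events to fit")
    x, names = _build_design(table, spec)

    # all-identical covariate: zero information
    zero_var = [nm for j, nm in enumerate(names) if np.ptp(x[:, j]) == 0]
    if zero_var:
        p = x.shape[1]
        summary = _summary_frame(np.zeros(p), np.full(p, nan), names)
        return CoxFit(summary, np.full((p, p), nan), nan, len(table), int(event.sum()),
                      False, nan, message=f"zero-variance covariate(s): {zero_var}")

    beta, ll, hess, converged, msg = _newton_cox(x, time, event, spec.ties)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), nan)
        se = np.full(len(beta), nan)
        converged = False
    if not converged:
        se = np.full(len(beta), nan)

    summary = _summary_frame(beta, se, names)
    risk = x @ beta
    cidx = concordance(time, event, risk) if converged else nan

    group_effects = None
    if converged and spec.interactions:
        rows = []
        for a, b in spec.interactions:
            ia, ib = names.index(a), names.index(f"{a}:{b}")
            for grp, coef, var in (
                (f"{a} | {b}=0", beta[ia], cov[ia, ia]),
                (f"{a} | {b}=1", beta[ia] + beta[ib], cov[ia, ia] + cov[ib, ib] + 2 * cov[ia, ib]),
            ):
                s = np.sqrt(max(var, 0.0))
                rows.append(_effect_row(grp, coef, s))
        group_effects = pd.DataFrame(rows).set_index("term")

    robust_summary = None
    if converged and spec.cluster_col is not None:
        clusters = table[spec.cluster_col].to_numpy()
        resid = _score_residuals(beta, x, time, event, spec.ties)
        cl = pd.DataFrame(resid).groupby(clusters).sum().to_numpy()
        meat = cl.T @ cl
        vrob = cov @ meat @ cov
        se_rob = np.sqrt(np.maximum(np.diag(vrob), 0.0))
        robust_summary = _summary_frame(beta, se_rob, names)

    return CoxFit(
        summary=summary,
        cov=cov,
        loglik=ll,
        n=len(table),
        n_events=int(event.sum()),
        converged=converged,
        c_index=cidx,
        group_effects=group_effects,
        robust_summary=robust_summary,
        message=msg,
    )


def _effect_row(name, coef, se):
    z = coef / se if se > 0 else nan
    p = 2 * stats.norm.sf(abs(z)) if not isnan(z) else nan
    return {
        "term": name,
        "coef": coef,
        "hr": np.exp(coef),
        "se": se,
        "ci95_lo": np.exp(coef - 1.959963984540054 * se),
        "ci95_hi": np.exp(coef + 1.959963984540054 * se),
        "z": z,
        "wald_p": p,
    }


def _summary_frame(beta, se, names) -> pd.DataFrame:
    rows = [_effect_row(nm, float(b), float(s)) if not isnan(s) else
            {**_effect_row(nm, float(b), 0.0), "se": nan, "ci95_lo": nan, "ci95_hi": nan,
             "z": nan, "wald_p": nan}
            for nm, b, s in zip(names, beta, se)]
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Concordance, FDR, rank tests, landmark
# ---------------------------------------------------------------------------

def concordance(time, event, risk) -> float:
    """Harrell's c-index over usable pairs.

    A pair (i, j) is usable when the earlier time belongs to an event;
    concordant when the earlier-failing subject has the higher risk score;
    ties in risk count 0.5. Returns NaN when no pair is usable.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    for i in np.where(event == 1)[0]:
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        later[i] = False
        den += later.sum()
        num += (risk[i] > risk[later]).sum() + 0.5 * (risk[i] == risk[later]).sum()
    if den == 0:
        return nan
    return float(num / den)


def bh_fdr(p_values, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and significance flags
    at level ``q`` (strict: adjusted p < q, as the analysis protocol
    prescribes)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted < q


def rank_test(samples: list, kind: str) -> tuple[float, float]:
    """Nonparametric group comparison: (statistic, two-sided p).

    ``mann_whitney`` and ``wilcoxon_rank`` are the two-sample rank-sum test
    (reported as the Mann-Whitney U statistic; exact enumeration when both
    groups have at most 8 observations and no ties, normal approximation
    with mid-rank tie correction otherwise). ``kruskal_wallis`` needs at
    least 3 groups and uses the chi-square approximation.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if kind in ("mann_whitney", "wilcoxon_rank"):
        if len(samples) != 2:
            raise ValueError(f"{kind} requires exactly 2 groups")
        x, y = samples
        method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "kruskal_wallis":
        if len(samples) < 3:
            raise ValueError("kruskal_wallis requires at least 3 groups")
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind: {kind!r}")


def logrank_groups(time, event, group) -> tuple[float, float]:
    """Two-group logrank comparison (e.g. the dose-arm effect check).
    Returns (statistic, p)."""
    from lifelines.statistics import logrank_test

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("logrank_groups expects exactly 2 groups")
    a = group == levels[0]
    res = logrank_test(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


def landmark_groups(outcomes, cutoff: float = 18.0) -> pd.DataFrame:
    """18-month landmark classification of tumors.

    Labels: ``LF``/``RF`` for locoregional progression at or before the
    cutoff (by tumor kind); ``DF`` for locoregionally controlled tumors
    whose patient failed distantly by the cutoff; ``NED`` for no progression
    with follow-up reaching the cutoff. Excluded: locoregional progression
    after the cutoff, or no progression with follow-up shorter than the
    cutoff.
    """
    df = outcomes_to_frame(outcomes)
    labels = []
    for _, r in df.iterrows():
        prog, dft, fup = r["prog_time"], r["df_time"], r["last_followup"]
        if not isnan(prog):
            if prog <= cutoff:
                labels.append("LF" if r["kind"] == "primary" else "RF")
            else:
                labels.append("excluded")
        elif not isnan(dft) and dft <= cutoff:
            labels.append("DF")
        elif not isnan(fup) and fup >= cutoff:
            labels.append("NED")
        else:
            labels.append("excluded")
    out = df[["patient_id", "tumor_id", "kind"]].copy()
    out["group"] = labels
    return out
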