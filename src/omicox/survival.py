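"""Cox model fitting and the evaluation statistics shared by all selectors.

The partial likelihood uses the Efron correction for tied event times and
is maximized by damped Newton iterations with a small ridge (1e-8) on the
Hessian so that collinear or separated covariates (typical of sparse binary
mutation data) degrade gracefully instead of diverging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .io import SurvivalData

RIDGE = 1e-8
MAX_ITER = 100
SCORE_TOL = 1e-7


class FitError(RuntimeError):
    pass


@dataclass
class CoxFit:
    feature_ids: list[str]
    beta: np.ndarray
    log_partial_likelihood: float
    null_log_likelihood: float
    converged: bool
    n_events: int
    se: np.ndarray
    n_iter: int = 0

    @property
    def wald_p(self) -> np.ndarray:
        """Two-sided Wald p-value per coefficient."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, 0.0)
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def lrt_p(self) -> float:
        """Likelihood-ratio p-value of the model against the null model."""
        chi2 = 2.0 * (self.log_partial_likelihood - self.null_log_likelihood)
        return float(stats.chi2.sf(max(chi2, 0.0), df=len(self.feature_ids)))


@dataclass
class EvalResult:
    c_index: float
    logrank_chi2: float
    logrank_p: float
    tier: str
    prognostic_index: pd.Series
    mode: str  # "blind_test" or "resubstitution"


@dataclass
class SurvivalModel:
    """A selected feature set with refit Cox coefficients."""

    feature_ids: list[str]
    sources: list[str]
    beta: np.ndarray
    selector: str
    fitness: float
    fit: CoxFit | None = None
    extras: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.feature_ids)


def _prepare(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Sort by ascending time and group tied event times for Efron sums."""
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _efron_quantities(beta, X, time, event, want_hessian=True):
    """Log partial likelihood, score, and (optionally) Hessian, Efron ties.

    Fully vectorized over deaths: for the ell-th of d tied deaths the risk
    sum is ``S - (ell/d) * S_D`` with ``S`` the suffix sum over the risk
    set and ``S_D`` the sum over the tied deaths.  The "- eta.max()" shift
    cancels exactly (every death contributes one eta term and one
    log(risk-sum) term).
    """
    n, k = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # overflow guard
    r = np.exp(eta)
    rx = r[:, None] * X

    # suffix sums over the risk set (times sorted ascending)
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]

    # tie groups of the sorted times
    _, starts, ginv = np.unique(time, return_index=True, return_inverse=True)
    n_groups = starts.size

    deaths = np.flatnonzero(event == 1)
    if deaths.size == 0:
        raise FitError("no events")
    g = ginv[deaths]
    d_per_group = np.bincount(g, minlength=n_groups).astype(float)
    D0 = np.bincount(g, weights=r[deaths], minlength=n_groups)
    D1 = np.zeros((n_groups, k))
    np.add.at(D1, g, rx[deaths])

    # within-group death rank ell = 0..d-1 (deaths are time-sorted)
    _, first = np.unique(g, return_index=True)
    offset = np.zeros(deaths.size, dtype=int)
    offset[first] = np.arange(deaths.size)[first]
    np.maximum.accumulate(offset, out=offset)
    ell = np.arange(deaths.size) - offset
    frac = ell / d_per_group[g]

    gi = starts[g]  # first sorted index of each death's risk set
    s0 = S0[gi] - frac * D0[g]
    s1 = S1[gi] - frac[:, None] * D1[g]

    loglik = float(eta[deaths].sum() - np.log(s0).sum())
    score = X[deaths].sum(axis=0) - (s1 / s0[:, None]).sum(axis=0)

    hess = None
    if want_hessian:
        rxx = np.einsum("i,ij,il->ijl", r, X, X)
        S2 = np.cumsum(rxx[::-1], axis=0)[::-1]
        D2 = np.zeros((n_groups, k, k))
        np.add.at(D2, g, rxx[deaths])
        s2 = S2[gi] - frac[:, None, None] * D2[g]
        # under complete separation s0 underflows to 0; the resulting
        # non-finite Hessian is caught by the Newton driver
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            hess = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum(
                "ij,il,i->jl", s1, s1, 1.0 / s0**2
            )
    return loglik, score, hess


def fit_cox(X, survival: SurvivalData, feature_ids=None) -> CoxFit:
    """Maximize the Efron partial likelihood by damped Newton iterations.

    Parameters
    ----------
    X:
        ``n_patients x n_features`` array or DataFrame (patients as rows).
    survival:
        Aligned outcome; must contain at least one event.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns) if feature_ids is None else feature_ids
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != survival.n:
        raise FitError("covariate rows must match patients")
    n, k = X.shape
    if feature_ids is None:
        feature_ids = [f"x{i}" for i in range(k)]
    n_events = survival.n_events
    if n_events == 0:
        raise FitError("cannot fit a Cox model with zero events")
    if k > n:
        warnings.warn(f"more features ({k}) than patients ({n})", stacklevel=2)

    Xs, ts, es = _prepare(X, survival.time, survival.event)
    beta = np.zeros(k)
    null_ll, _, _ = _efron_quantities(beta, Xs, ts, es, want_hessian=False)
    ll, g, H = _efron_quantities(beta, Xs, ts, es)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(g)) / n < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(H + RIDGE * np.eye(k), g)
        except np.linalg.LinAlgError:
            break
        # damping: halve the step until the likelihood does not decrease
        scale = 1.0
        for _ in range(15):
            cand = beta + scale * step
            new_ll, new_g, new_H = _efron_quantities(cand, Xs, ts, es)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        progress = new_ll - ll
        beta, ll, g, H = cand, new_ll, new_g, new_H
        if progress < 1e-10:
            # flat likelihood (separation or plateau); the score criterion
            # decides whether this counts as convergence
            converged = bool(np.max(np.abs(g)) / n < SCORE_TOL)
            break
    if not np.all(np.isfinite(beta)):
        converged = False
        beta = np.zeros(k)

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(H + RIDGE * np.eye(k))
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.inf)
            converged = False
    return CoxFit(
        feature_ids=list(feature_ids),
        beta=beta,
        log_partial_likelihood=float(ll),
        null_log_likelihood=float(null_ll),
        converged=converged,
        n_events=n_events,
        se=se,
        n_iter=it,
    )


def prognostic_index(fit: CoxFit, X) -> pd.Series:
    """Linear predictor beta·x per patient."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in fit.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from matrix: {missing[:5]}")
        values = X[fit.feature_ids].to_numpy(dtype=float)
        index = X.index
    else:
        values = np.atleast_2d(np.asarray(X, dtype=float))
        index = pd.RangeIndex(values.shape[0])
    return pd.Series(values @ fit.beta, index=index, name="prognostic_index")


def concordance_index(pi, survival: SurvivalData) -> float:
    """Harrell's c-index.

    A pair is usable when its times differ and the earlier time is an
    event.  Concordant = higher index on the earlier death (1), tied index
    = 0.5.  Raises if censoring leaves no usable pair.
    """
    pi = np.asarray(pi, dtype=float)
    t, e = survival.time, survival.event
    n = t.size
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (e[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise FitError("no usable pairs (all censored or all tied)")
    pii, pij = pi[:, None], pi[None, :]
    concordant = (usable & (pii > pij)).sum()
    tied = (usable & (pii == pij)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


TIER_CUTS = ((0.001, "c"), (0.01, "b"), (0.05, "a"))


def significance_tier(p: float) -> str:
    for cut, tier in TIER_CUTS:
        if p < cut:
            return tier
    return "none"


def logrank_median_split(pi, survival: SurvivalData):
    """Two-group log-rank test after splitting the index at its median.

    Low risk = index <= median; high risk = index > median.  Returns
    (chi2, p, tier).
    """
    pi = np.asarray(pi, dtype=float)
    med = np.median(pi)
    high = pi > med
    if high.all() or not high.any():
        raise FitError("median split left an empty group")
    res = logrank_test(
        survival.time[~high],
        survival.time[high],
        event_observed_A=survival.event[~high],
        event_observed_B=survival.event[high],
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return chi2, p, significance_tier(p)


def evaluate_model(model_fit: CoxFit, X, survival: SurvivalData, mode: str) -> EvalResult:
    pi = prognostic_index(model_fit, X)
    c = concordance_index(pi.to_numpy(), survival)
    chi2, p, tier = logrank_median_split(pi.to_numpy(), survival)
    return EvalResult(c, chi2, p, tier, pi, mode)


def cohen_kappa(a, b) -> float:
    """Chance-corrected agreement of two binary vectors.

    Returns NaN when both raters are constant (chance agreement = 1).
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# resampling protocol


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(survival: SurvivalData, train_fraction: float = 2 / 3, seed=0):
    """Event-stratified train/test split of patient ids.

    Within each event stratum, ``round(train_fraction * stratum size)``
    patients go to training; the split is disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(survival.patient_ids)
    train: list = []
    test: list = []
    for value in (0, 1):
        stratum = ids[survival.event == value]
        if stratum.size < 2:
            raise FitError(f"event stratum {value} has fewer than 2 patients")
        perm = rng.permutation(stratum)
        n_train = _round_half_up(train_fraction * stratum.size)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return sorted(train), sorted(test)


def stratified_bootstrap(survival: SurvivalData, seed=0) -> list:
    """Resample patient ids with replacement within each event stratum."""
    rng = np.random.default_rng(seed)
    ids = np.array(survival.patient_ids)
    out: list = []
    for value in (0, 1):
        stratum = ids[survival.event == value]
        if stratum.size:
            out.extend(rng.choice(stratum, size=stratum.size, replace=True))
    return out


def bootstrap_cindex(X, survival: SurvivalData, B: int = 10, seed=0, resamples=None) -> float:
    """Mean c-index over B stratified bootstrap refits.

    Each replicate refits the model on the resampled patients and scores it
    on the same resample.  Fit failures are dropped; at least B/2 replicates
    must succeed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    idx = pd.Index(survival.patient_ids)
    if resamples is None:
        seeds = np.random.SeedSequence(seed).spawn(B)
        resamples = [stratified_bootstrap(survival, s) for s in seeds]
    values = []
    for ids in resamples:
        pos = idx.get_indexer(ids)
        sub = SurvivalData([f"r{i}" for i in range(len(ids))], survival.time[pos], survival.event[pos])
        try:
            fit = fit_cox(X[pos], sub)
            pi = X[pos] @ fit.beta
            values.append(concordance_index(pi, sub))
        except FitError:
            continue
    if len(values) < B / 2:
        raise FitError(f"only {len(values)}/{B} bootstrap fits succeeded")
    if len(values) < B:
        warnings.warn(f"{B - len(values)} bootstrap replicates failed", stacklevel=2)
    return float(np.mean(values))
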