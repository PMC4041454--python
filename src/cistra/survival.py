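"""Clinical survival statistics.

Implements immunostaining H-scores, median-unbiased quantile grouping,
the Kaplan–Meier product-limit estimator with Greenwood/log–log confidence
intervals, the two-group log-rank test, a maximally selected log-rank
cutpoint scan (single split), and Cox proportional-hazards regression with
Efron tie handling fitted by Newton iteration.

Conventions locked by tests:

* quantiles follow the median-unbiased definition ``h = (n + 1/3) p + 1/3``
  with linear interpolation, clamped to the data range;
* first-quartile dichotomisation labels scores ``<= cut`` as "low";
* the Cox score test for a single binary covariate equals the log-rank
  chi-square when event times are untied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HScore",
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "CutpointResult",
    "ConvergenceError",
    "compute_hscore",
    "hf_quantile",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "cox_ph",
    "dichotomize_first_quartile",
    "read_clinical_tsv",
    "write_km_tsv",
]


class ConvergenceError(RuntimeError):
    """Raised when the Cox Newton iteration fails to converge."""


@dataclass(frozen=True)
class HScore:
    intensity: int
    pct_positive: float
    h: float

    def __post_init__(self) -> None:
        if abs(self.h - self.intensity * self.pct_positive) > 1e-9:
            raise ValueError("h must equal intensity * pct_positive")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # months
    event: bool
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(
                f"subject {self.subject_id}: time must be > 0, got {self.time}"
            )


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    covariates: list[str]
    coef: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    score_chi2: float
    score_p: float
    log_likelihood: float
    n_iter: int
    warnings: list[str] = field(default_factory=list)

    def ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])


@dataclass
class CutpointResult:
    cut: float
    chi2: float
    p_naive: float
    p_adjusted: float | None = None
    n_perm: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Scores and quantiles


def compute_hscore(intensity: int, pct_positive: float) -> HScore:
    """Staining H-score: intensity (0-3) times percent positive nuclei."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be in {{0,1,2,3}}, got {intensity}")
    if not 0 <= pct_positive <= 100:
        raise ValueError(f"pct_positive must be in [0,100], got {pct_positive}")
    return HScore(intensity, float(pct_positive), float(intensity * pct_positive))


def hf_quantile(values: Sequence[float], p: float) -> float:
    """Median-unbiased sample quantile (Hyndman–Fan definition 8).

    ``h = (n + 1/3) p + 1/3``; linear interpolation between order
    statistics, clamped to [min, max].
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        raise ValueError("empty input")
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0,1], got {p}")
    n = x.size
    h = (n + 1.0 / 3.0) * p + 1.0 / 3.0
    h = min(max(h, 1.0), float(n))
    lo = int(math.floor(h))
    frac = h - lo
    if lo >= n:
        return float(x[-1])
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def dichotomize_first_quartile(
    scores: Sequence[float],
) -> tuple[float, list[str]]:
    """Split at the first quartile: label "low" iff score <= cut."""
    vals = list(scores)
    if len(vals) < 4:
        raise ValueError("need >= 4 values to form quartiles")
    cut = hf_quantile(vals, 0.25)
    labels = ["low" if v <= cut else "high" for v in vals]
    if len(set(labels)) == 1:
        logger.warning("degenerate dichotomisation: all scores in one group")
    return cut, labels


# ---------------------------------------------------------------------------
# Kaplan–Meier


def _event_table(records: Sequence[SurvivalRecord]):
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events]) if events.any() else np.empty(0)
    n = times.size
    n_risk = np.asarray([(times >= t).sum() for t in uniq], dtype=np.int64)
    n_event = np.asarray(
        [((times == t) & events).sum() for t in uniq], dtype=np.int64
    )
    return uniq, n_risk, n_event, n


def km_estimate(records: Sequence[SurvivalRecord], level: float = 0.95) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance and log–log
    (complementary-log) pointwise confidence intervals."""
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    uniq, n_risk, n_event, _ = _event_table(records)
    if uniq.size == 0:
        # all censored: S = 1 everywhere
        return KMCurve(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0),
            np.empty(0, np.int64), np.empty(0, np.int64),
        )
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(
            np.where(n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.inf)
        )
    z = stats.norm.ppf(0.5 + level / 2)
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    for i, s in enumerate(surv):
        if s <= 0.0 or s >= 1.0 or not np.isfinite(gw[i]):
            lo[i] = hi[i] = s
            continue
        se_theta = math.sqrt(gw[i]) / abs(math.log(s))
        theta = math.log(-math.log(s))
        lo[i] = math.exp(-math.exp(theta + z * se_theta))
        hi[i] = math.exp(-math.exp(theta - z * se_theta))
    return KMCurve(uniq, surv, lo, hi, n_risk, n_event)


# ---------------------------------------------------------------------------
# Log-rank


def _logrank_from_arrays(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) for a boolean group indicator."""
    uniq = np.unique(times[events])
    U = 0.0
    V = 0.0
    for t in uniq:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int((events & (times == t)).sum())
        n1_j = int((at_risk & group).sum())
        d1_j = int((events & (times == t) & group).sum())
        U += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            V += (
                d_j
                * (n1_j / n_j)
                * (1 - n1_j / n_j)
                * (n_j - d_j)
                / (n_j - 1)
            )
    if V <= 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    records = list(group_a) + list(group_b)
    if not any(r.event for r in records):
        raise ValueError("need >= 1 event overall")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    group = np.asarray([False] * len(group_a) + [True] * len(group_b))
    return _logrank_from_arrays(times, events, group)


# ---------------------------------------------------------------------------
# Maximally selected cutpoint


def _logrank_scan(
    times: np.ndarray,
    events: np.ndarray,
    scores: np.ndarray,
    candidates: np.ndarray,
) -> np.ndarray:
    """Vectorised log-rank chi-square for every split ``score > c``."""
    uniq = np.unique(times[events])
    J, C = uniq.size, candidates.size
    risk = times[None, :] >= uniq[:, None]  # J x n
    ev_at = (times[None, :] == uniq[:, None]) & events[None, :]
    g = scores[:, None] > candidates[None, :]  # n x C
    n_j = risk.sum(axis=1).astype(float)  # J
    d_j = ev_at.sum(axis=1).astype(float)
    n1 = risk.astype(float) @ g  # J x C
    d1 = ev_at.astype(float) @ g
    frac = n1 / n_j[:, None]
    U = (d1 - d_j[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = (
            d_j[:, None]
            * frac
            * (1 - frac)
            * ((n_j - d_j) / np.maximum(n_j - 1, 1))[:, None]
        )
    V = v_terms.sum(axis=0)
    chi2 = np.zeros(C)
    ok = V > 0
    chi2[ok] = U[ok] ** 2 / V[ok]
    return chi2


def optimal_cutpoint(
    scores: Mapping[str, float],
    records: Sequence[SurvivalRecord],
    qrange: tuple[float, float] = (0.10, 0.90),
    n_perm: int | None = None,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank split of a continuous score (depth-1
    recursive partitioning).

    Scans every candidate split ``score > c`` for observed score values
    whose quantile lies inside ``qrange`` and returns the split maximising
    the log-rank chi-square.  The naive p-value is NOT corrected for the
    scan; pass ``n_perm`` for a seeded permutation-adjusted p over
    relabelled scores (always >= the naive p in expectation).
    """
    lo_q, hi_q = qrange
    if not (0 < lo_q < hi_q < 1):
        raise ValueError("quantile range must satisfy 0 < lo < hi < 1")
    subj = [r.subject_id for r in records]
    missing = [s for s in subj if s not in scores]
    if missing:
        raise ValueError(f"missing scores for subjects: {missing[:5]}")
    s_arr = np.asarray([scores[s] for s in subj], dtype=float)
    if np.unique(s_arr).size < 2:
        raise ValueError("scores are constant; no candidate split")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    if not events.any():
        raise ValueError("need >= 1 event")
    lo_v = hf_quantile(s_arr, lo_q)
    hi_v = hf_quantile(s_arr, hi_q)
    cand = np.unique(s_arr[(s_arr >= lo_v) & (s_arr <= hi_v)])
    cand = cand[cand < s_arr.max()]  # 'score > c' must leave both groups non-empty
    if cand.size == 0:
        raise ValueError("quantile range excludes all candidate splits")
    chi2s = _logrank_scan(times, events, s_arr, cand)
    best = int(np.argmax(chi2s))
    chi2 = float(chi2s[best])
    p_naive = float(stats.chi2.sf(chi2, 1))
    result = CutpointResult(float(cand[best]), chi2, p_naive)
    if n_perm is not None:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(s_arr)
            c2 = _logrank_scan(times, events, perm, cand)
            if c2.max() >= chi2:
                exceed += 1
        result.p_adjusted = (1 + exceed) / (1 + n_perm)
        result.n_perm = n_perm
        result.seed = seed
    return result


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton iteration)


def _cox_loglik(beta, times, events, X):
    """Efron partial log-likelihood with gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    # clip to avoid overflow in pathological separation cases
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-times, kind="stable")  # descending time
    ll = 0.0
    U = np.zeros(p)
    H = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    idx = order
    while i < n:
        t = times[idx[i]]
        j = i
        # add all subjects entering the risk set at this time
        while j < n and times[idx[j]] == t:
            k = idx[j]
            S0 += w[k]
            S1 += w[k] * X[k]
            S2 += w[k] * np.outer(X[k], X[k])
            j += 1
        dead = [k for k in idx[i:j] if events[k]]
        d = len(dead)
        if d > 0:
            wd = np.array([w[k] for k in dead])
            Xd = X[dead]
            D0 = wd.sum()
            D1 = wd @ Xd
            D2 = (wd[:, None] * Xd).T @ Xd
            ll += float(np.sum(np.log(wd)))
            U += Xd.sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = S0 - f * D0
                phi1 = S1 - f * D1
                phi2 = S2 - f * D2
                ll -= math.log(phi0)
                U -= phi1 / phi0
                H += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
        i = j
    return ll, U, H


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str],
    max_iter: int = 25,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton iteration with Efron ties.

    Converges when the largest absolute score component falls below ``tol``
    (default 1e-8) within ``max_iter`` iterations; otherwise raises
    :class:`ConvergenceError`.  Monotone-likelihood (separation) cases are
    flagged with a warning and estimates are still reported.
    """
    if not any(r.event for r in records):
        raise ValueError("need >= 1 event")
    names = list(covariate_names)
    X = np.empty((len(records), len(names)))
    for i, r in enumerate(records):
        for j, nm in enumerate(names):
            if nm not in r.covariates:
                raise ValueError(f"subject {r.subject_id} lacks covariate {nm!r}")
            X[i, j] = r.covariates[nm]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    const = [nm for j, nm in enumerate(names) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)

    p = len(names)
    beta = np.zeros(p)
    _, U0, H0 = _cox_loglik(beta, times, events, X)
    score_chi2 = float(U0 @ np.linalg.solve(H0, U0)) if np.linalg.det(H0) else 0.0
    score_p = float(stats.chi2.sf(score_chi2, p))

    warnings_: list[str] = []
    ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, U, H = _cox_loglik(beta, times, events, X)
        if np.max(np.abs(U)) < tol:
            break
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            warnings_.append("singular information matrix")
            break
        # step-halving to keep the likelihood increasing (relative slack:
        # near the optimum the loglik comparison is float-noise limited)
        for _ in range(20):
            new_ll, _, _ = _cox_loglik(beta + step, times, events, X)
            if new_ll >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(beta)) > 15:
            warnings_.append(
                "possible monotone likelihood (perfect separation): "
                "coefficient path diverging"
            )
            logger.warning(warnings_[-1])
            break
    else:
        raise ConvergenceError(
            f"Cox Newton iteration did not converge in {max_iter} iterations"
        )
    ll, U, H = _cox_loglik(beta, times, events, X)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(
        covariates=names,
        coef=beta,
        hazard_ratios=np.exp(beta),
        se=se,
        wald_p=wald_p,
        score_chi2=score_chi2,
        score_p=score_p,
        log_likelihood=float(ll),
        n_iter=n_iter,
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# I/O


def read_clinical_tsv(path: str | Path) -> list[SurvivalRecord]:
    """Clinical table: subject_id, time_months, event, plus covariates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["subject_id", "time_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file missing column(s): {missing}")
    cov_cols = [c for c in df.columns if c not in required]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SurvivalRecord(
                subject_id=str(d["subject_id"]),
                time=float(d["time_months"]),
                event=bool(int(d["event"])),
                covariates={c: float(d[c]) for c in cov_cols},
            )
        )
    return records


def write_km_tsv(curve: KMCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time": curve.times,
            "n_risk": curve.n_risk,
            "n_event": curve.n_event,
            "survival": curve.survival,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
        }
    ).to_csv(path, sep="\t", index=False)
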