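"""Statistical layer: t-tests, OLS with adjusted R-squared, leave-one-out
predictive scoring, exhaustive best-subset model selection, and the
regional-pattern delta comparison.

The OLS and leave-one-out machinery is implemented directly (normal
equations; PRESS via the leverage identity ``e_i / (1 - h_ii)``) so that its
behavior is fully specified; statsmodels serves as an independent
cross-check in the test suite, not as the implementation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OLSFit",
    "ModelSelectionResult",
    "TTestResult",
    "RegionalDeltaTest",
    "CollinearDesignError",
    "DegenerateDataError",
    "two_sample_t",
    "fit_ols",
    "loo_score",
    "select_model",
    "regional_delta_test",
    "design_from_cohort",
    "PREDICTOR_POOL",
    "WITHIN_GROUP_POOL",
]

#: Candidate predictors for whole-population models.
PREDICTOR_POOL = ("group", "sex", "age", "weight", "height", "bmi",
                  "tendon_length", "csa")
#: Candidate pool for within-group models (group indicator dropped).
WITHIN_GROUP_POOL = tuple(p for p in PREDICTOR_POOL if p != "group")


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateDataError(ValueError):
    """Input unfit for the requested test (too few points, zero variance,
    or a leave-one-out leverage of one)."""


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    mean_diff: float
    variant: str


@dataclass(frozen=True)
class OLSFit:
    """Ordinary-least-squares fit summary.

    ``names`` includes the intercept first; coefficients are on the scale of
    the response per unit predictor (m/s for 0/1 indicators, m/s per year for
    age, etc.).
    """

    names: tuple
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2: float
    adj_r2: float
    df_resid: int
    n: int

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.names,
            "estimate": self.params,
            "std_error": self.se,
            "t": self.tvalues,
            "p_value": self.pvalues,
        })


@dataclass(frozen=True)
class ModelSelectionResult:
    pool: tuple
    scores: dict
    selected: tuple
    fit: OLSFit
    criterion: str


@dataclass(frozen=True)
class RegionalDeltaTest:
    """Between-group comparison of a per-subject regional SWV delta."""

    delta_name: str
    mean_control: float
    mean_skier: float
    test: TTestResult
    n_control: int
    n_skier: int
    n_dropped: int


def two_sample_t(a, b, variant: str = "welch") -> TTestResult:
    """Independent-samples t test, two-sided.

    ``variant='welch'`` (default) uses the Welch-Satterthwaite df; 'student'
    pools the variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateDataError("non-finite values in input")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if variant == "welch":
        if va == 0.0 and vb == 0.0:
            raise DegenerateDataError("zero variance in both groups")
        sa, sb = va / na, vb / nb
        se = math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    elif variant == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0.0:
            raise DegenerateDataError("zero pooled variance")
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(statistic=float(t), df=float(df), pvalue=float(p),
                       mean_diff=float(diff), variant=variant)


def _design_matrix(X: pd.DataFrame) -> tuple[tuple, np.ndarray]:
    names = ("intercept", *X.columns)
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return names, M


def _check_rank(names: tuple, M: np.ndarray) -> None:
    if np.linalg.matrix_rank(M) == M.shape[1]:
        return
    # find the first column that breaks the rank
    for j in range(1, M.shape[1]):
        if np.linalg.matrix_rank(M[:, :j + 1]) < j + 1:
            raise CollinearDesignError(
                f"collinear design: column {names[j]!r} is linearly dependent "
                "on the preceding columns")
    raise CollinearDesignError("collinear design")


def fit_ols(y, X: pd.DataFrame) -> OLSFit:
    """OLS of a response on named predictors, intercept always included.

    Normal-equation estimates; standard errors from the residual variance
    and the inverse Gram matrix; adjusted R^2 = 1 - (1-R^2)(n-1)/(n-k-1).
    """
    y = np.asarray(y, dtype=float)
    names, M = _design_matrix(X)
    n, p = M.shape
    if n <= p:
        raise DegenerateDataError(f"need n > {p} observations for {p} parameters")
    _check_rank(names, M)
    G = M.T @ M
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (M.T @ y)
    resid = y - M @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - p
    sigma2 = rss / df_resid
    se = np.sqrt(np.clip(sigma2 * np.diag(Ginv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    k = p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return OLSFit(names=names, params=beta, se=se, tvalues=tvals,
                  pvalues=pvals, r2=r2, adj_r2=adj, df_resid=df_resid, n=n)


def loo_score(y, X: pd.DataFrame) -> float:
    """Leave-one-out predictive R^2: ``1 - PRESS / SStot``.

    PRESS is computed with the closed-form leverage identity
    ``e_i / (1 - h_ii)``, which equals the literal refit-per-left-out-point
    prediction error exactly.
    """
    y = np.asarray(y, dtype=float)
    names, M = _design_matrix(X)
    n, p = M.shape
    if n <= p + 1:
        raise DegenerateDataError("need n > k + 2 for leave-one-out scoring")
    _check_rank(names, M)
    Ginv = np.linalg.inv(M.T @ M)
    beta = Ginv @ (M.T @ y)
    resid = y - M @ beta
    h = np.einsum("ij,jk,ik->i", M, Ginv, M)
    if np.any(h >= 1.0 - 1e-10):
        raise DegenerateDataError("leave-one-out undefined: a leverage equals 1")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def _subsets(pool: tuple):
    """All predictor subsets (including empty) ordered by size, then
    lexicographically in pool order — the tie-break order."""
    for k in range(len(pool) + 1):
        yield from itertools.combinations(pool, k)


def select_model(y, candidates: pd.DataFrame,
                 criterion: str = "adjusted_r2") -> ModelSelectionResult:
    """Exhaustive best-subset selection over <= 12 candidate predictors.

    Every subset (including intercept-only) is scored by the chosen
    criterion — full-data adjusted R^2 or leave-one-out predictive R^2
    (PRESS) — and the best subset is refit on the full data.  Ties break
    toward fewer predictors, then lexicographically.
    """
    pool = tuple(candidates.columns)
    if len(pool) > 12:
        raise ValueError("exhaustive search limited to 12 candidates")
    if criterion not in ("adjusted_r2", "loo_press"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = np.asarray(y, dtype=float)
    scores: dict = {}
    best: tuple | None = None
    best_score = -np.inf
    for subset in _subsets(pool):
        X = candidates[list(subset)]
        try:
            if criterion == "adjusted_r2":
                score = fit_ols(y, X).adj_r2 if subset else 0.0
            else:
                score = loo_score(y, X) if subset else _loo_intercept_only(y)
        except (CollinearDesignError, DegenerateDataError):
            continue
        scores[subset] = score
        if score > best_score:  # strict: earlier (smaller/lex-lower) wins ties
            best_score = score
            best = subset
    if best is None:
        raise DegenerateDataError("no scorable subset")
    fit = fit_ols(y, candidates[list(best)])
    return ModelSelectionResult(pool=pool, scores=scores, selected=best,
                                fit=fit, criterion=criterion)


def _loo_intercept_only(y: np.ndarray) -> float:
    n = y.size
    resid = y - y.mean()
    press = float(((resid / (1.0 - 1.0 / n)) ** 2).sum())
    tss = float((resid ** 2).sum())
    return 1.0 - press / tss if tss > 0 else 0.0


def design_from_cohort(cohort: pd.DataFrame, predictors) -> pd.DataFrame:
    """Named design columns from a cohort table.

    ``group`` -> skier indicator, ``sex`` -> male indicator; other predictors
    are taken as numeric columns.
    """
    cols = {}
    for name in predictors:
        if name == "group":
            cols[name] = (cohort["group"] == "skier").astype(float)
        elif name == "sex":
            cols[name] = (cohort["sex"] == "male").astype(float)
        else:
            cols[name] = cohort[name].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def regional_delta_test(cohort: pd.DataFrame, variant: str = "welch"
                        ) -> dict[str, RegionalDeltaTest]:
    """Between-group tests on per-subject regional SWV deltas.

    For each subject, ``distal - mid`` and ``proximal - mid`` are formed from
    the regional means; each delta is compared between skiers and controls
    with an independent-samples t test.  Subjects with an undefined region
    are dropped (count reported).
    """
    out = {}
    for name, (ra, rb) in {"distal_minus_mid": ("swv_distal", "swv_mid"),
                           "proximal_minus_mid": ("swv_proximal", "swv_mid")}.items():
        delta = cohort[ra] - cohort[rb]
        ok = delta.notna()
        dropped = int((~ok).sum())
        d = delta[ok]
        grp = cohort.loc[ok, "group"]
        a = d[grp == "skier"].to_numpy()
        b = d[grp == "control"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise DegenerateDataError(
                f"delta {name!r}: both groups need >= 2 subjects with "
                "defined regions")
        test = two_sample_t(a, b, variant=variant)
        out[name] = RegionalDeltaTest(
            delta_name=name, mean_control=float(b.mean()),
            mean_skier=float(a.mean()), test=test,
            n_control=int(b.size), n_skier=int(a.size), n_dropped=dropped)
    return out
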