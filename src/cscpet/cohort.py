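"""Cohort-level statistics: odds ratios, chi-square/Fisher tests, logistic fits.

Reproduces the univariable/multivariable analysis style of a neoadjuvant
breast-cancer cohort: 2x2 cross-product odds ratios with Woolf confidence
intervals, Pearson chi-square, Fisher's exact test by full enumeration for
small 2xc tables, and maximum-likelihood logistic regression via iteratively
reweighted least squares (IRLS) with Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "Chi2Result",
    "LogisticFit",
    "SeparationWarning",
    "odds_ratio",
    "pearson_chi2",
    "fisher_exact",
    "logistic_fit",
    "univariable_or_table",
    "multivariable_pcr_fit",
]


class SeparationWarning(UserWarning):
    """Quasi/complete separation detected in a logistic fit."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are exposure levels, columns the outcome (e.g. pCR / residual)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def odds_ratio(
    tab: ContingencyTable2x2, continuity_correction: bool = False
) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with a Woolf 95% CI.

    CI: exp(log OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell makes
    both the OR and the CI undefined; enabling ``continuity_correction`` adds
    0.5 to every cell (Haldane-Anscombe) and flags the result.
    """
    cells = np.array([tab.a, tab.b, tab.c, tab.d], dtype=float)
    corrected = False
    if np.any(cells == 0):
        if not continuity_correction:
            zero = "abcd"[int(np.argmin(cells))]
            raise ValueError(
                f"cell {zero!r} is zero; odds ratio undefined without "
                "continuity correction"
            )
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt((1 / cells).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), corrected)


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square on an r x c count table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins: every row and column needs counts")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


def _enumerate_tables(col_margins: np.ndarray, r0: int):
    """All first rows (x_1..x_c) with 0 <= x_j <= col_margin_j and sum r0."""
    ranges = [range(int(m) + 1) for m in col_margins]
    for row in product(*ranges):
        if sum(row) == r0:
            yield row


def _table_prob(row, col_margins, n, r0) -> float:
    """Multivariate hypergeometric probability of a 2xc table with fixed margins."""
    num = 1
    for x, m in zip(row, col_margins):
        num *= comb(int(m), int(x))
    return num / comb(n, r0)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test for a 2xc table by full enumeration.

    Sums the conditional (multivariate hypergeometric) probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  Enumeration is limited to c <= 5 columns.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("fisher_exact expects a 2xc table")
    if table.shape[1] > 5:
        raise ValueError(
            f"table with {table.shape[1]} columns too large for enumeration; "
            "use pearson_chi2 instead"
        )
    col_margins = table.sum(axis=0)
    r0 = int(table[0].sum())
    n = int(table.sum())
    p_obs = _table_prob(table[0], col_margins, n, r0)
    p = 0.0
    for row in _enumerate_tables(col_margins, r0):
        pr = _table_prob(row, col_margins, n, r0)
        if pr <= p_obs * (1 + 1e-12):
            p += pr
    return min(p, 1.0)


@dataclass(frozen=True)
class LogisticFit:
    coefficients: pd.Series  # log-odds scale, incl. intercept
    covariance: pd.DataFrame
    odds_ratios: pd.Series  # exp(coefficients)
    wald_ci: pd.DataFrame  # 95% interval on the OR scale
    p_values: pd.Series  # two-sided Wald
    converged: bool
    n_used: int
    loglik_trace: np.ndarray  # per-IRLS-iteration log-likelihood


def logistic_fit(
    design: pd.DataFrame,
    outcome,
    tol: float = 1e-8,
    maxiter: int = 100,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with Wald inference.

    Complete-case: rows with any missing covariate or outcome are dropped
    (``n_used`` reports the rows kept).  Continuous covariates enter per unit
    (e.g. per 1 cm^3 of MTVcsc).  Convergence when the log-likelihood changes
    by less than ``tol`` within ``maxiter`` iterations.  Quasi/complete
    separation (diverging coefficients) yields ``converged=False`` plus a
    :class:`SeparationWarning`; the last estimates are still returned.
    """
    design = pd.DataFrame(design).apply(pd.to_numeric)
    y = pd.Series(outcome).astype(float)
    keep = design.notna().all(axis=1) & y.notna()
    X = design.loc[keep]
    y = y.loc[keep].to_numpy()
    n_used = int(keep.sum())
    if X.shape[1] < 1:
        raise ValueError("at least one covariate is required")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if n_used < X.shape[1] + 1:
        raise ValueError(
            f"only {n_used} complete cases for {X.shape[1]} covariate(s)"
        )
    names = list(X.columns)
    Xmat = X.to_numpy(dtype=float)
    if add_intercept:
        Xmat = np.column_stack([np.ones(n_used), Xmat])
        names = ["intercept"] + names

    beta = np.zeros(Xmat.shape[1])
    trace = []
    converged = False
    separated = False
    for _ in range(maxiter):
        eta = Xmat @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = Xmat.T * w
        try:
            beta = np.linalg.solve(XtW @ Xmat, XtW @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        if np.abs(beta).max() > 50:  # log-odds this large => separation
            separated = True
            break

    # a fit that "converged" onto perfect prediction (every fitted probability
    # pinned to its outcome) is complete separation, not convergence
    if converged:
        mu_fit = 1.0 / (1.0 + np.exp(-np.clip(Xmat @ beta, -700, 700)))
        if np.all(np.abs(mu_fit - y) < 1e-6):
            separated = True

    if separated or not converged:
        converged = False
        warnings.warn(
            "possible quasi/complete separation: coefficients diverging or "
            "fit not converged; estimates are unreliable",
            SeparationWarning,
            stacklevel=2,
        )

    eta = Xmat @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = (Xmat.T * w) @ Xmat
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    ci = np.exp(np.clip(np.column_stack([beta - 1.96 * se, beta + 1.96 * se]), -700, 700))

    return LogisticFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        odds_ratios=pd.Series(np.exp(beta), index=names),
        wald_ci=pd.DataFrame(ci, index=names, columns=["ci_low", "ci_high"]),
        p_values=pd.Series(pvals, index=names),
        converged=converged,
        n_used=n_used,
        loglik_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Cohort-table encodings
#
# Reference levels chosen so ORs point the conventional direction:
# lower T stage vs 3-4, earlier anatomic stage vs IIIB-IIIC, grade 3 vs 1-2,
# Ki-67 >= 30% vs low, ER negative vs positive.  Missing grade/Ki-67 are
# dropped per analysis (complete-case), so each row keeps its own n.

_BINARY_ENCODINGS = {
    "t_stage_1_2": lambda df: (df["t_stage"] == "T1-2").where(df["t_stage"].notna()),
    "stage_IIA_IIIA": lambda df: (df["anatomic_stage"] == "IIA-IIIA").where(
        df["anatomic_stage"].notna()
    ),
    "grade_3": lambda df: (df["grade"] == "3").where(df["grade"].notna()),
    "ki67_high": lambda df: (df["ki67_pct"] >= 30).where(df["ki67_pct"].notna()),
    "er_negative": lambda df: (df["er_status"] == "negative").where(
        df["er_status"].notna()
    ),
}

_CONTINUOUS = [
    "mtv_csc", "tlg_csc", "csc_proportion", "suv_max",
    "mtv", "tlg", "mtv40", "tlg40",
]


def univariable_or_table(cohort: pd.DataFrame, outcome_col: str = "pcr") -> pd.DataFrame:
    """Univariable logistic ORs for each encoded covariate vs the outcome."""
    rows = []
    y = cohort[outcome_col].astype(float)
    covariates = {name: enc(cohort) for name, enc in _BINARY_ENCODINGS.items()}
    covariates.update({name: cohort[name] for name in _CONTINUOUS if name in cohort})
    for name, x in covariates.items():
        xv = pd.to_numeric(x.astype(float), errors="coerce")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SeparationWarning)
                fit = logistic_fit(pd.DataFrame({name: xv}), y)
        except ValueError:
            continue
        rows.append(
            {
                "covariate": name,
                "odds_ratio": fit.odds_ratios[name],
                "ci_low": fit.wald_ci.loc[name, "ci_low"],
                "ci_high": fit.wald_ci.loc[name, "ci_high"],
                "p_value": fit.p_values[name],
                "n": fit.n_used,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def multivariable_pcr_fit(cohort: pd.DataFrame, outcome_col: str = "pcr") -> LogisticFit:
    """Multivariable model: ER status + MTVcsc (per 1 cm^3)."""
    design = pd.DataFrame(
        {
            "er_negative": (cohort["er_status"] == "negative").astype(float),
            "mtv_csc": pd.to_numeric(cohort["mtv_csc"]),
        }
    )
    return logistic_fit(design, cohort[outcome_col].astype(float))
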