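"""Association statistics between morphology and ploidy status.

Group summaries, univariate logistic odds ratios, forward stepwise
multivariate logistic regression (likelihood-ratio entry/removal, the
SPSS "Forward: LR" analogue), two-sample t tests, Pearson chi-squared
and Pearson correlation.  All tests are two-tailed; odds ratios carry
Wald 95% confidence intervals (exp(beta +/- 1.96 SE)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthgen import FEATURE_COLUMNS

Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    """One odds-ratio association estimate."""

    feature: str
    estimate: float  # OR (or aOR) per unit of the feature
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    method: str
    selected: bool = True

    def __post_init__(self) -> None:
        if np.isfinite(self.estimate) and not (
            self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12
        ):
            raise ValueError("estimate outside its confidence interval")


def _fit_logit(X: np.ndarray, y: np.ndarray):
    import warnings

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        # separation is handled explicitly by the callers
        warnings.simplefilter("ignore")
        return model.fit(disp=0, maxiter=200)


def univariate_logistic(
    values: np.ndarray, outcome: np.ndarray, feature: str = "feature"
) -> AssocResult:
    """Single-predictor logistic regression OR with Wald CI and p."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    try:
        res = _fit_logit(x[:, None], y)
        beta = res.params[1]
        se = res.bse[1]
        if not np.isfinite(se) or se > 1e3:
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return AssocResult(
            feature=feature,
            estimate=np.inf,
            ci_low=0.0,
            ci_high=np.inf,
            p_value=np.nan,
            n=len(y),
            method="logistic-wald (perfect separation)",
        )
    return AssocResult(
        feature=feature,
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        n=len(y),
        method="logistic-wald",
    )


def forward_stepwise_logistic(
    table: pd.DataFrame,
    features: list[str],
    outcome_col: str = "euploid",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> list[AssocResult]:
    """Forward stepwise multivariate logistic regression (LR criterion).

    Iteratively adds the candidate with the smallest likelihood-ratio
    p-value if below ``alpha_enter``; after each addition, removes any
    included feature whose LR p-value exceeds ``alpha_remove``; stops at
    a fixpoint.  Adjusted ORs come from the final model; unselected
    features are echoed with the 1.000 sentinel, mirroring the common
    presentation of stepwise output tables.
    """
    if len(features) < 2:
        raise ValueError("need >= 2 candidate features")
    y = table[outcome_col].to_numpy(dtype=float)

    def loglik(cols: list[str]) -> float:
        X = table[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
        res = _fit_logit(X, y)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"logistic MLE did not converge for {cols}")
        return float(res.llf)

    selected: list[str] = []
    seen_states: set[tuple[str, ...]] = set()
    while True:
        state = tuple(sorted(selected))
        if state in seen_states:
            break  # entry/removal cycle: stop at the repeated state
        seen_states.add(state)
        changed = False
        # entry step
        ll0 = loglik(selected)
        best_p, best_f = 1.0, None
        for f in features:
            if f in selected:
                continue
            lr = 2.0 * (loglik(selected + [f]) - ll0)
            p = stats.chi2.sf(max(lr, 0.0), df=1)
            if p < best_p:
                best_p, best_f = p, f
        if best_f is not None and best_p < alpha_enter:
            selected.append(best_f)
            changed = True
        # removal step
        if len(selected) > 1:
            ll_full = loglik(selected)
            worst_p, worst_f = 0.0, None
            for f in selected:
                reduced = [g for g in selected if g != f]
                lr = 2.0 * (ll_full - loglik(reduced))
                p = stats.chi2.sf(max(lr, 0.0), df=1)
                if p > worst_p:
                    worst_p, worst_f = p, f
            if worst_f is not None and worst_p > alpha_remove:
                selected.remove(worst_f)
                changed = True
        if not changed:
            break

    results: list[AssocResult] = []
    if selected:
        res = _fit_logit(table[selected].to_numpy(dtype=float), y)
        for i, f in enumerate(selected):
            beta, se = res.params[i + 1], res.bse[i + 1]
            results.append(
                AssocResult(
                    feature=f,
                    estimate=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - Z95 * se)),
                    ci_high=float(np.exp(beta + Z95 * se)),
                    p_value=float(2 * stats.norm.sf(abs(beta / se))),
                    n=len(y),
                    method="stepwise-logistic-wald",
                )
            )
    for f in features:
        if f not in selected:
            results.append(
                AssocResult(
                    feature=f,
                    estimate=1.000,
                    ci_low=1.000,
                    ci_high=1.000,
                    p_value=np.nan,
                    n=len(y),
                    method="stepwise-logistic (not selected)",
                    selected=False,
                )
            )
    return results


def two_sample_t(x, y, welch: bool = True) -> dict:
    """Two-tailed two-sample t test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        return {"t": 0.0, "df": float(len(x) + len(y) - 2), "p": 1.0}
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def chi_square_trend(table) -> dict:
    """Pearson chi-squared without continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.min() < 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a non-negative table of at least 2x2")
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("degenerate margin: expected count of zero")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def pearson_corr(x, y) -> dict:
    """Product-moment correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def group_summary(
    table: pd.DataFrame,
    group_by: str,
    features: list[str] | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-group mean, SD (n-1) and n per feature, plus t-test p-values.

    With exactly two groups a two-sample t p-value per feature is
    appended; groups of n < 2 get a missing SD and a flag.
    """
    features = features or [c for c in FEATURE_COLUMNS if c in table.columns]
    if group_by not in table.columns:
        raise KeyError(f"grouping column {group_by!r} not present")
    rows = []
    groups = list(table.groupby(group_by, sort=True))
    for gname, g in groups:
        for f in features:
            v = g[f].to_numpy(dtype=float)
            rows.append(
                {
                    "group": gname,
                    "feature": f,
                    "n": len(v),
                    "mean": float(v.mean()) if len(v) else np.nan,
                    "sd": float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan,
                    "flag": None if len(v) >= 2 else "n < 2: SD undefined",
                }
            )
    out = pd.DataFrame(rows)
    if len(groups) == 2:
        (_, g1), (_, g2) = groups
        pvals = {
            f: two_sample_t(g1[f].to_numpy(float), g2[f].to_numpy(float), welch)["p"]
            for f in features
            if len(g1) >= 2 and len(g2) >= 2
        }
        out["t_p_value"] = out["feature"].map(pvals)
    return out
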