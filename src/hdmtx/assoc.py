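"""Genotype-phenotype association statistics.

This layer mirrors a candidate-SNP pharmacogenetic analysis: genotypes are
coded under additive / dominant / recessive models of the minor allele;
dichotomous toxicity outcomes are tested with Fisher's exact test reporting
the conditional-MLE odds ratio with its exact conditional confidence
interval; continuous PK endpoints (log10 end-of-infusion level, clearance)
are modeled with Gaussian linear models (optionally mixed models with a
patient random intercept for per-course endpoints) and compared by
likelihood-ratio tests; relapse is modeled with Cox proportional hazards
(Efron tie handling); course-level comparisons use Kruskal-Wallis with Dunn
pairwise post-hoc tests; and multiplicity is controlled with an explicit
method and family size.

Standard fitters are delegated: scipy for the exact test and rank tests,
statsmodels for OLS/MixedLM, lifelines for Cox.  Direction labels are always
explicit because a 2x2 table's printed OR depends on row orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .exceptions import (
    CollinearityError,
    InsufficientDataError,
    InvalidInputError,
    NoEventsError,
    ZeroMarginError,
)

GENETIC_MODELS = ("additive", "dominant", "recessive")


def genetic_coding(genotypes, model: str):
    """Code minor-allele counts (0/1/2) under a genetic model.

    additive -> the count itself; dominant -> carrier of >= 1 minor allele;
    recessive -> homozygous minor only.
    """
    g = np.asarray(genotypes)
    if not np.isin(g[~pd.isna(g)], [0, 1, 2]).all():
        raise InvalidInputError("genotypes must be minor-allele counts 0/1/2")
    if model == "additive":
        return g.astype(float)
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g == 2).astype(float)
    raise InvalidInputError(f"unknown genetic model {model!r}; use one of {GENETIC_MODELS}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``: rows are groups, columns event / no event."""

    a: int
    b: int
    c: int
    d: int
    group_labels: tuple = ("group1", "group2")
    event_label: str = "event"

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InvalidInputError("counts must be non-negative integers")

    @classmethod
    def from_groups(cls, group1_mask, event_mask, group_labels=("group1", "group2"),
                    event_label="event"):
        g = np.asarray(group1_mask, dtype=bool)
        e = np.asarray(event_mask, dtype=bool)
        return cls(
            a=int((g & e).sum()), b=int((g & ~e).sum()),
            c=int((~g & e).sum()), d=int((~g & ~e).sum()),
            group_labels=tuple(group_labels), event_label=event_label,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    """One tidy association estimate: effect, 95% CI, p, and its direction."""

    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    test: str
    n: int
    direction: str
    term: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise InvalidInputError(f"p-value out of [0,1]: {self.pvalue}")
        if np.isfinite(self.estimate) and np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise InvalidInputError("confidence interval does not bracket the estimate")


def fisher_pvalue(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding the observed table's)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def fisher_exact(table: ContingencyTable2x2) -> AssociationResult:
    """Fisher's exact test with the conditional-MLE odds ratio.

    The estimate maximizes the noncentral hypergeometric likelihood given
    both margins (the convention of R's ``fisher.test``); the CI is the exact
    conditional interval.  Raises :class:`ZeroMarginError` when a row or
    column margin is zero (the OR is undefined; use :func:`fisher_pvalue` if
    only the p-value is needed).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ZeroMarginError(
            f"zero margin in table {arr.tolist()}: odds ratio undefined"
        )
    res = _scipy_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    g1, g2 = table.group_labels
    return AssociationResult(
        estimate=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        pvalue=fisher_pvalue(table),
        test="fisher_exact_cmle",
        n=table.n,
        direction=f"odds of {table.event_label} in {g1} vs {g2}",
    )


def _lrt_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (llf_full - llf_reduced))
    return float(stats.chi2.sf(lr, df))


def pk_linear_model(
    data: pd.DataFrame,
    endpoint: str,
    covariates: list,
    multivariate: bool = False,
    log10_endpoint: bool = False,
    interactions: list | None = None,
) -> list:
    """Gaussian linear model of a PK endpoint with likelihood-ratio p-values.

    Parameters
    ----------
    data : per-patient table with the endpoint and numeric covariate columns
        (genetic codings already applied).
    endpoint : column name; end-of-infusion level endpoints are conventionally
        modeled on the log10 scale (set ``log10_endpoint=True``).
    covariates : column names.  With ``multivariate=False`` each covariate is
        screened alone; with True all enter one joint model and each term's
        LRT drops that term.
    interactions : optional list of (col1, col2) product terms, joint model
        only.

    Returns a list of :class:`AssociationResult`, one per term, with OLS
    coefficient, Wald 95% CI, and the LRT p-value in ``extra['p_lrt']``.
    """
    import statsmodels.api as sm

    if len(data) < max(10, len(covariates) + 2):
        raise InsufficientDataError(
            f"need at least {max(10, len(covariates) + 2)} patients, got {len(data)}"
        )
    y = data[endpoint].astype(float).to_numpy()
    if log10_endpoint:
        if (y <= 0).any():
            raise InvalidInputError("log10 endpoint requires positive values")
        y = np.log10(y)

    def _fit(cols, inter):
        X = data[cols].astype(float).copy()
        for c1, c2 in inter:
            X[f"{c1}:{c2}"] = data[c1].astype(float) * data[c2].astype(float)
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise CollinearityError(f"design with columns {list(X.columns)} is rank deficient")
        return sm.OLS(y, X).fit()

    interactions = interactions or []
    results = []
    if not multivariate:
        for cov in covariates:
            full = _fit([cov], [])
            reduced = _fit([], [])
            results.append(_ols_term_result(full, cov, len(data),
                                            _lrt_pvalue(full.llf, reduced.llf)))
        return results

    terms = list(covariates) + [f"{c1}:{c2}" for c1, c2 in interactions]
    full = _fit(covariates, interactions)
    for term in terms:
        if ":" in term:
            keep_inter = [iv for iv in interactions if f"{iv[0]}:{iv[1]}" != term]
            reduced = _fit(covariates, keep_inter)
        else:
            keep = [c for c in covariates if c != term]
            keep_inter = [iv for iv in interactions if term not in iv]
            reduced = _fit(keep, keep_inter)
        results.append(_ols_term_result(full, term, len(data),
                                        _lrt_pvalue(full.llf, reduced.llf)))
    return results


def _ols_term_result(fit, term, n, p_lrt):
    ci = fit.conf_int()
    return AssociationResult(
        estimate=float(fit.params[term]),
        ci_low=float(ci.loc[term, 0]),
        ci_high=float(ci.loc[term, 1]),
        pvalue=float(fit.pvalues[term]),
        test="ols",
        n=n,
        direction=f"change in endpoint per unit {term}",
        term=term,
        extra={"p_lrt": p_lrt, "se": float(fit.bse[term]), "llf": float(fit.llf)},
    )


def pk_mixed_model(
    data: pd.DataFrame,
    endpoint: str,
    covariates: list,
    group: str = "patient_id",
    log10_endpoint: bool = False,
) -> list:
    """Per-course endpoint with a patient random intercept (REML fit).

    Returns fixed-effect :class:`AssociationResult` objects; the random
    intercept variance (guaranteed >= 0) is in ``extra['re_var']``.
    """
    import statsmodels.api as sm

    y = data[endpoint].astype(float).to_numpy()
    if log10_endpoint:
        y = np.log10(y)
    X = sm.add_constant(data[covariates].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(y, X, groups=data[group]).fit(reml=True)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    re_var = max(re_var, 0.0)
    out = []
    ci = fit.conf_int()
    for term in covariates:
        out.append(
            AssociationResult(
                estimate=float(fit.params[term]),
                ci_low=float(ci.loc[term, 0]),
                ci_high=float(ci.loc[term, 1]),
                pvalue=float(fit.pvalues[term]),
                test="mixedlm",
                n=int(data[group].nunique()),
                direction=f"change in endpoint per unit {term}",
                term=term,
                extra={"re_var": re_var},
            )
        )
    return out


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal-Wallis omnibus result plus Dunn pairwise comparisons."""

    statistic: float
    pvalue: float
    n_groups: int
    dunn: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adj
    degenerate: bool = False


def _dunn_posthoc(groups: dict, adjust: str) -> pd.DataFrame:
    """Dunn's rank z-tests on the pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    sizes = {k: len(groups[k]) for k in labels}
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k in labels:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    for i, j in pairs:
        ki, kj = labels[i], labels[j]
        se = np.sqrt(base_var * (1.0 / sizes[ki] + 1.0 / sizes[kj]))
        z = (mean_ranks[ki] - mean_ranks[kj]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": ki, "group2": kj, "z": z, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, df["p_raw"].iloc[idx] * (m - rank_i))
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise InvalidInputError(f"unknown adjustment {adjust!r}")
    return df


def course_level_test(groups: dict, adjust: str = "bonferroni") -> RankTestResult:
    """Kruskal-Wallis across groups with Dunn pairwise post-hoc tests.

    ``groups`` maps labels (e.g., course index or toxicity status) to value
    arrays.  All-tied data yields a degenerate result with p = 1 and a
    warning; an empty group is an error.
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    for k, v in groups.items():
        if len(v) == 0:
            raise InvalidInputError(f"group {k!r} is empty")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; rank test degenerate",
                      stacklevel=2)
        dunn = _dunn_posthoc(groups, adjust)
        return RankTestResult(0.0, 1.0, len(groups), dunn, degenerate=True)
    values = list(groups.values())
    if len(values) == 2 and max(len(values[0]), len(values[1])) <= 10:
        # exact two-group rank test: the chi-square approximation is poor at
        # these sizes (complete separation of 3 vs 3 gives exact p = 0.1)
        mw = stats.mannwhitneyu(values[0], values[1], alternative="two-sided",
                                method="exact" if pooled.size == np.unique(pooled).size
                                else "asymptotic")
        h, _ = stats.kruskal(*values)
        return RankTestResult(float(h), float(mw.pvalue), 2, _dunn_posthoc(groups, adjust))
    h, p = stats.kruskal(*values)
    return RankTestResult(float(h), float(p), len(groups), _dunn_posthoc(groups, adjust))


def relapse_cox(
    data: pd.DataFrame,
    duration_col: str = "followup_years",
    event_col: str = "relapse",
    covariates: list | None = None,
) -> list:
    """Cox proportional-hazards fit of relapse (Efron tie handling).

    Returns one :class:`AssociationResult` per covariate with the hazard
    ratio, Wald 95% CI and p; the model likelihood-ratio test against the
    null model is in each result's ``extra['p_lrt_model']``.  Monotone
    likelihood (complete separation) is flagged as non-convergence in
    ``extra['converged']`` rather than silently reported.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates or [])
    if data[event_col].sum() == 0:
        raise NoEventsError("no relapse events; Cox model is undefined")
    if (data[duration_col] <= 0).any():
        raise InvalidInputError("follow-up times must be positive")
    df = data[[duration_col, event_col] + covariates].astype(float)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        # retry with ridge to return flagged estimates instead of crashing
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        _ = err
    p_lrt_model = float(cph.log_likelihood_ratio_test().p_value)
    out = []
    summary = cph.summary
    for term in covariates:
        row = summary.loc[term]
        out.append(
            AssociationResult(
                estimate=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                pvalue=float(row["p"]),
                test="cox_ph",
                n=len(df),
                direction=f"hazard of {event_col} per unit {term}",
                term=term,
                extra={
                    "coef": float(row["coef"]),
                    "se": float(row["se(coef)"]),
                    "events": int(df[event_col].sum()),
                    "p_lrt_model": p_lrt_model,
                    "converged": converged,
                },
            )
        )
    return out


def adjust_multiplicity(
    pvalues,
    method: str = "bonferroni",
    m: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multiple-testing adjustment with an explicit family size.

    ``m`` overrides the family size (useful when the tested family is larger
    than the p-values at hand); only Bonferroni supports an explicit ``m``.
    Returns a DataFrame with raw and adjusted p-values and the significance
    decision at ``alpha``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InvalidInputError("no p-values to adjust")
    if ((p < 0) | (p > 1)).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if m is not None:
        if method != "bonferroni":
            raise InvalidInputError("explicit family size m is only defined for bonferroni")
        if m < p.size:
            raise InvalidInputError(f"family size {m} smaller than number of p-values {p.size}")
        adjusted = np.minimum(p * m, 1.0)
    else:
        from statsmodels.stats.multitest import multipletests

        _, adjusted, _, _ = multipletests(p, alpha=alpha, method=method)
    return pd.DataFrame(
        {"p_raw": p, "p_adj": adjusted, "significant": adjusted < alpha}
    )


def shapiro_gate(values, alpha: float = 0.05):
    """Shapiro-Wilk normality screen.

    Emits a warning when normality is rejected; never switches the downstream
    test.  Returns the scipy result object.
    """
    res = stats.shapiro(np.asarray(values, dtype=float))
    if res.pvalue < alpha:
        warnings.warn(
            f"Shapiro-Wilk rejects normality (p={res.pvalue:.3g}); "
            "consider a transformed endpoint or rank test",
            stacklevel=2,
        )
    return res
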