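"""Group statistics for a two-group pre/post crossover physiology study.

Implements the analysis battery applied to the per-subject outcome measures
(basal CBF, venous oxygenation, flow-based CVR, BOLD-CVR): percent change
with the convention that a reduction is positive, Shapiro-Wilk normality
checks of paired differences, paired and independent t-tests (Welch by
default), and a linear mixed-effects model

    outcome ~ caffeine * group + sex + age + (1 | subject)

with caffeine coded pre = 0 / post = 1 and group coded naive = 0 /
habituated = 1, fitted by REML through statsmodels MixedLM. Inference on the
fixed effects uses Wald-z intervals by default (a residual-df t option is
available); coefficient estimates are the primary surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ShapeError

OUTCOMES = ("cbf", "yv", "cbf_cvr", "bold_cvr")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metadata and pre/post outcome measures."""

    subject_id: str
    group: str  # "naive" or "habituated"
    sex: str  # "F" or "M"
    age: float
    pre: dict = field(default_factory=dict)  # outcome name -> value
    post: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ParameterError("p-value outside [0, 1]")


@dataclass(frozen=True)
class LmeResult:
    """Fixed-effect table plus variance components of a mixed model."""

    fixed_effects: pd.DataFrame  # index: term; cols: coef, ci_low, ci_high, p_value
    random_intercept_var: float
    residual_var: float
    converged: bool
    singular: bool

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "coef"])


def percent_change(pre: float, post: float) -> float:
    """Percent change with reductions positive: ``(pre - post)/pre * 100``."""
    if pre == 0:
        raise ParameterError("pre value must be nonzero")
    return (pre - post) / pre * 100.0


def paired_test(pre, post, alpha: float = 0.05) -> TestResult:
    """Two-sided paired t-test on ``pre - post``.

    For identical vectors (zero differences throughout) the statistic is 0
    and the p-value is reported as 1 by convention.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ShapeError("pre and post must be 1-D with equal lengths")
    n = pre.size
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    d = pre - post
    dbar = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if dbar == 0:
            return TestResult(0.0, 1.0, df, 0.0, 0.0, 0.0)
        t = np.inf if dbar > 0 else -np.inf
        return TestResult(float(t), 0.0, df, float(dbar), float(dbar), float(dbar))
    se = sd / np.sqrt(n)
    t = dbar / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return TestResult(
        float(t), float(p), float(df), float(dbar),
        float(dbar - tcrit * se), float(dbar + tcrit * se),
    )


def normality_check(differences) -> TestResult:
    """Shapiro-Wilk test of the paired differences (3 <= n <= 5000)."""
    d = np.asarray(differences, float)
    if d.ndim != 1 or not 3 <= d.size <= 5000:
        raise ParameterError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(d)
    return TestResult(float(w), float(p), float(d.size), float(w), np.nan, np.nan)


def independent_test(
    group_a, group_b, equal_var: bool = False, alpha: float = 0.05
) -> TestResult:
    """Two-sided two-sample t-test (Welch by default, pooled on request)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, a.size + b.size - 2, 0.0, 0.0, 0.0)
        raise ParameterError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    est = a.mean() - b.mean()
    df = float(res.df)
    if equal_var:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    else:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return TestResult(
        float(res.statistic), float(res.pvalue), df, float(est),
        float(est - tcrit * se), float(est + tcrit * se),
    )


def records_to_long(
    records: list[SubjectRecord] | pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Long-format table (one row per subject x state) for mixed modeling.

    Codes caffeine pre = 0 / post = 1, group naive = 0 / habituated = 1 and
    sex F = 0 / M = 1.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"subject_id", "group", "sex", "age", "state", outcome}
        missing = required - set(df.columns)
        if missing:
            raise ShapeError(f"missing columns: {sorted(missing)}")
        df = df.rename(columns={outcome: "outcome"})
    else:
        rows = []
        for r in records:
            for state, values in (("pre", r.pre), ("post", r.post)):
                if outcome not in values:
                    raise ShapeError(
                        f"subject {r.subject_id} lacks {outcome!r} in state {state}"
                    )
                rows.append(
                    dict(subject_id=r.subject_id, group=r.group, sex=r.sex,
                         age=r.age, state=state, outcome=values[outcome])
                )
        df = pd.DataFrame(rows)
    df["caffeine"] = (df["state"] == "post").astype(float)
    df["group_code"] = (df["group"] == "habituated").astype(float)
    df["sex_code"] = (df["sex"] == "M").astype(float)
    return df


def fit_lme(
    records,
    outcome: str,
    covariates: tuple[str, ...] = ("sex_code", "age"),
    inference: str = "wald-z",
    reml: bool = True,
    alpha: float = 0.05,
) -> LmeResult:
    """Random-intercept mixed model with caffeine x group interaction.

    ``records`` is a list of :class:`SubjectRecord` or a long/wide DataFrame
    accepted by :func:`records_to_long`. ``inference`` selects the CI/p
    method: ``"wald-z"`` (default) or ``"t-resid"`` (t with residual df
    ``n_obs - n_fixed - n_subjects``).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = records_to_long(records, outcome)
    formula = "outcome ~ caffeine * group_code"
    for c in covariates:
        formula += f" + {c}"
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        fit = model.fit(reml=reml)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning) or "singular" in str(
                w.message
            ).lower():
                singular = True
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    resid_var = float(fit.scale)
    if re_var <= 1e-10 * max(resid_var, 1e-12):
        singular = True
    params = fit.fe_params
    bse = fit.bse_fe
    if inference == "wald-z":
        crit = stats.norm.ppf(1 - alpha / 2)
        pvals = 2 * stats.norm.sf(np.abs(params / bse))
    elif inference == "t-resid":
        dof = max(len(df) - len(params) - df["subject_id"].nunique(), 1)
        crit = stats.t.ppf(1 - alpha / 2, dof)
        pvals = 2 * stats.t.sf(np.abs(params / bse), dof)
    else:
        raise ParameterError(f"unknown inference method {inference!r}")
    table = pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "ci_low": params - crit * bse,
            "ci_high": params + crit * bse,
            "p_value": pvals,
        }
    )
    # keep the interaction under a stable name
    table.index = [t.replace("caffeine:group_code", "interaction") for t in table.index]
    wanted = ["Intercept", "caffeine", "group_code", "interaction", *covariates]
    table = table.loc[[t for t in wanted if t in table.index]]
    return LmeResult(
        fixed_effects=table,
        random_intercept_var=re_var,
        residual_var=resid_var,
        converged=bool(getattr(fit, "converged", True)),
        singular=singular,
    )
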