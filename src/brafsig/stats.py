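"""Downstream association, survival, and drug-sensitivity statistics.

Thin, typed wrappers around scipy / scikit-learn / lifelines /
statsmodels with the study's conventions pinned down: one-sided
rank-sum tests for aberrant-vs-wildtype score comparisons (exact
enumeration at small sample sizes without ties), median dichotomization
with ties sent to the low group, Kaplan-Meier curves with the two-sample
log-rank test, univariate Cox models with Efron tie handling, per-drug
Pearson correlations of score against IC50, Fisher's exact test for
response tables, and a multivariate logistic model for therapy response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import DegenerateInputError, ParameterError

EXACT_WILCOXON_MAX_N = 12


@dataclass
class AssociationResult:
    test_name: str
    statistic: float
    p_value: float
    direction: str = ""
    n_per_group: tuple = ()


@dataclass
class SurvivalResult:
    hazard_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    logrank_statistic: Optional[float] = None
    logrank_p: Optional[float] = None
    group_sizes: tuple = ()
    km_curves: dict = field(default_factory=dict)
    converged: bool = True


@dataclass
class DrugAssociation:
    drug_name: str
    pearson_rho: float
    p_value: float
    n: int
    defined: bool = True


def dichotomize_by_median(values) -> pd.Series:
    """Median split: strictly above the median -> "high", else "low".

    Values exactly at the median go to the low group — the deterministic
    tie rule that best approximates two equal-sized groups.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ParameterError("need >= 2 values to dichotomize")
    if not np.isfinite(values).all():
        raise ParameterError("values must be finite")
    med = float(values.median())
    if values.nunique() == 1:
        raise DegenerateInputError("all values identical; no median split exists")
    return pd.Series(
        np.where(values > med, "high", "low"), index=values.index,
        name="group",
    )


def wilcoxon_one_sided(a, b) -> AssociationResult:
    """One-sided Wilcoxon rank-sum test of a stochastically greater than b.

    Exact enumeration when the pooled sample has at most 12 observations
    and no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="greater", method=method)
    return AssociationResult(
        test_name=f"wilcoxon_one_sided[{method}]",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction="a>b",
        n_per_group=(a.size, b.size),
    )


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> RocResult:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), with curve points."""
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ParameterError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(
        auc=float(roc_auc_score(labels, scores)), fpr=fpr, tpr=tpr,
        thresholds=thr,
    )


def _km_table(kmf) -> pd.DataFrame:
    tbl = kmf.event_table.copy()
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame(
        {
            "time": tbl.index.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
        }
    )


def km_logrank(clinical: pd.DataFrame, groups: pd.Series) -> SurvivalResult:
    """Kaplan-Meier curves per group plus the two-sample log-rank test.

    ``clinical`` needs ``sample_id``, ``os_time`` and ``os_event``
    columns; ``groups`` is a two-level series indexed by sample_id.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = clinical.set_index(clinical["sample_id"].astype(str))
    groups = pd.Series(groups)
    df = df.loc[[s for s in groups.index if s in df.index]]
    levels = pd.unique(groups.loc[df.index])
    if len(levels) != 2:
        raise ParameterError(f"expected exactly 2 groups, got {len(levels)}")
    if int(df["os_event"].sum()) == 0:
        raise DegenerateInputError("no events observed; log-rank undefined")

    masks = {lv: (groups.loc[df.index] == lv).to_numpy() for lv in levels}
    curves = {}
    for lv in levels:
        kmf = KaplanMeierFitter()
        kmf.fit(df["os_time"][masks[lv]], df["os_event"][masks[lv]],
                label=str(lv))
        curves[str(lv)] = _km_table(kmf)
    lr = logrank_test(
        df["os_time"][masks[levels[0]]], df["os_time"][masks[levels[1]]],
        df["os_event"][masks[levels[0]]], df["os_event"][masks[levels[1]]],
    )
    return SurvivalResult(
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_sizes=(int(masks[levels[0]].sum()), int(masks[levels[1]].sum())),
        km_curves=curves,
    )


def cox_univariate(clinical: pd.DataFrame, covariate: pd.Series) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    ``covariate`` may be a binary group indicator or a continuous
    variable, indexed by sample_id. Returns the hazard ratio with its
    95% Wald confidence interval; a fit that fails to converge (e.g.
    complete separation in survival) is flagged rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariate = pd.Series(covariate, name="x").astype(float)
    if covariate.nunique() < 2:
        raise ParameterError("covariate must vary")
    df = clinical.set_index(clinical["sample_id"].astype(str))
    common = [s for s in covariate.index if s in df.index]
    data = pd.DataFrame(
        {
            "os_time": df.loc[common, "os_time"].to_numpy(dtype=float),
            "os_event": df.loc[common, "os_event"].to_numpy(dtype=int),
            "x": covariate.loc[common].to_numpy(dtype=float),
        }
    )
    if int(data["os_event"].sum()) == 0:
        raise DegenerateInputError("no events observed; Cox model undefined")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="os_time", event_col="os_event")
    except ConvergenceError:
        return SurvivalResult(converged=False)
    summ = cph.summary.loc["x"]
    return SurvivalResult(
        hazard_ratio=float(np.exp(summ["coef"])),
        ci_low=float(np.exp(summ["coef lower 95%"])),
        ci_high=float(np.exp(summ["coef upper 95%"])),
        group_sizes=(len(data),),
    )


def drug_correlations(scores: pd.Series, drug_table: pd.DataFrame) -> pd.DataFrame:
    """Per-drug Pearson correlation of score with IC50.

    Each drug is correlated over the cell lines shared between the score
    vector and its IC50 rows (at least 3 required). Drugs with constant
    IC50 or constant score are retained with ``defined=False`` and NaN
    statistics. The result is sorted by ascending p for volcano-style
    reporting.
    """
    scores = pd.Series(scores).astype(float)
    rows = []
    for drug, sub in drug_table.groupby("drug_name"):
        sub = sub.set_index(sub["cell_line_id"].astype(str))
        common = [s for s in scores.index if s in sub.index]
        if len(common) < 3:
            raise ParameterError(
                f"drug {drug!r}: need >= 3 shared cell lines, got {len(common)}"
            )
        x = scores.loc[common].to_numpy()
        y = sub.loc[common, "ic50"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(DrugAssociation(str(drug), np.nan, np.nan,
                                        len(common), defined=False))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append(DrugAssociation(str(drug), float(r), float(p), len(common)))
    out = pd.DataFrame(
        {
            "drug_name": [r.drug_name for r in rows],
            "pearson_rho": [r.pearson_rho for r in rows],
            "p_value": [r.p_value for r in rows],
            "n": [r.n for r in rows],
            "defined": [r.defined for r in rows],
        }
    )
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)


def fisher_exact_2x2(table) -> AssociationResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table < 0) or np.any(table != np.floor(table)):
            raise ParameterError("table entries must be nonnegative integers")
        table = table.astype(int)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return AssociationResult(
        test_name="fisher_exact_2x2",
        statistic=float(odds),
        p_value=float(p),
        n_per_group=(int(table[0].sum()), int(table[1].sum())),
    )


def response_logistic(
    response,
    score,
    age=None,
    sex=None,
    other_therapy=None,
) -> pd.DataFrame:
    """Multivariate logistic regression of binary therapy response.

    Regresses response on score plus whichever of age, sex and
    other-therapy indicators are supplied. Returns a coefficient table
    (term, estimate, std_err, p_value, converged); a separated fit is
    flagged via ``converged=False`` on all rows.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    if np.unique(y).size < 2:
        raise ParameterError("response must contain both classes")
    cols = {"intercept": np.ones_like(y), "score": np.asarray(score, float)}
    for name, v in (("age", age), ("sex", sex), ("other_therapy", other_therapy)):
        if v is not None:
            cols[name] = np.asarray(v, dtype=float)
    X = pd.DataFrame(cols)
    converged = True
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=50)
        converged = bool(res.mle_retvals.get("converged", False)) and bool(
            np.isfinite(res.bse).all()
        )
        params, bse, pvals = res.params, res.bse, res.pvalues
    except Exception:
        converged = False
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
        pvals = pd.Series(np.nan, index=X.columns)
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": np.asarray(params, dtype=float),
            "std_err": np.asarray(bse, dtype=float),
            "p_value": np.asarray(pvals, dtype=float),
            "converged": converged,
        }
    )


def response_rate_by_group(response, groups, levels=None) -> tuple[pd.DataFrame, dict]:
    """2x2 responder table and per-group response rates.

    Returns a table with groups as rows and (responder, non-responder)
    counts as columns, ready for :func:`fisher_exact_2x2`. ``levels``
    optionally fixes the expected group labels; a declared group with no
    members is an error (its rate is undefined).
    """
    response = pd.Series(response).astype(int)
    groups = pd.Series(groups)
    if len(response) != len(groups):
        raise ParameterError("response and groups must be aligned")
    if levels is None:
        levels = sorted(pd.unique(groups).tolist())
    counts = {}
    rates = {}
    for lv in levels:
        mask = (groups == lv).to_numpy()
        if mask.sum() == 0:
            raise DegenerateInputError(f"group {lv!r} is empty; rate undefined")
        resp = int(response.to_numpy()[mask].sum())
        counts[lv] = (resp, int(mask.sum()) - resp)
        rates[lv] = resp / int(mask.sum())
    table = pd.DataFrame(
        counts, index=["responder", "non_responder"]
    ).T
    return table, rates
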