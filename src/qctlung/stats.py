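"""Statistical stage: agreement, recurrence regression, discrimination, survival.

Covers the analysis plan of a slice-thickness agreement + recurrence study:

* intraclass correlation (two-way random effects, absolute agreement,
  single measures) between thin- and thick-slice feature measurements,
  interpreted on kappa-style bands;
* univariate logistic regression of recurrence on each feature, with odds
  ratios on an explicit per-unit scale;
* multivariable logistic regression built by forward conditional
  selection (score test for entry, likelihood-ratio re-check for removal);
* ROC analysis of the fitted risk score (apparent C-index with a
  DeLong-type confidence interval);
* two-group comparisons (Student t, Pearson chi-square, Fisher exact);
* a univariate Cox model as a cross-check on the logistic results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelResult",
    "GroupComparison",
    "icc_agreement",
    "classify_agreement",
    "univariate_logistic",
    "forward_conditional_logistic",
    "roc_cindex",
    "group_compare",
    "cox_univariate",
    "reproduce_supplementary",
]


@dataclass
class ModelResult:
    """Uniform fitted-model summary.

    ``table`` has one row per term with columns ``term``, ``estimate``
    (OR/HR/ICC/AUC scale), ``lo``, ``hi`` (95% CI), ``p`` and ``scale``
    (units multiplier the estimate is reported per).  ``trace`` holds the
    ordered selection history for stepwise fits; ``notes`` carries flags
    such as separation warnings or the intercept-only fallback.
    """

    kind: str
    table: pd.DataFrame
    trace: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def estimate(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["estimate"].iloc[0])

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table["term"] if t != "Intercept"]


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def icc_agreement(
    x_thin: Sequence[float],
    x_thick: Sequence[float],
    kind: str = "absolute",
) -> ModelResult:
    """ICC between paired measurements of the same subjects.

    Default is the two-way random-effects, absolute-agreement,
    single-measure coefficient (ICC(A,1)), the defensible choice when the
    two "raters" are different measurement systems (thin- vs thick-slice
    reconstructions); ``kind="consistency"`` gives ICC(C,1).  Returns the
    estimate with its 95% CI and the p-value against ICC = 0.
    """
    import pingouin as pg

    x = np.asarray(x_thin, dtype=float)
    y = np.asarray(x_thick, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors of unequal length: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in ICC input")
    if np.var(np.r_[x, y]) == 0:
        raise ValueError("zero total variance: ICC undefined")

    df = pd.DataFrame(
        {
            "targets": np.r_[np.arange(x.size), np.arange(x.size)],
            "raters": ["thin"] * x.size + ["thick"] * x.size,
            "ratings": np.r_[x, y],
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes some off-variant CI terms 0/0 inside pingouin
        warnings.simplefilter("ignore", RuntimeWarning)
        icc = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        )
    row_type = "ICC(A,1)" if kind == "absolute" else "ICC(C,1)"
    row = icc.loc[icc["Type"] == row_type].iloc[0]
    lo, hi = row["CI95"]
    table = pd.DataFrame(
        [
            {
                "term": "ICC",
                "estimate": float(row["ICC"]),
                "lo": float(lo),
                "hi": float(hi),
                "p": float(row["pval"]),
                "scale": 1.0,
            }
        ]
    )
    return ModelResult(
        kind="icc",
        table=table,
        extras={"band": classify_agreement(float(row["ICC"])), "type": row_type},
    )


_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "excellent"),
)


def classify_agreement(icc: float) -> str:
    """Kappa-style agreement band of an ICC value.

    Boundaries as conventionally printed: <= 0.20 poor, 0.21-0.40 fair,
    0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 excellent.
    Values below 0 map to "poor".
    """
    if icc > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {icc}")
    for upper, label in _BANDS:
        if icc <= upper + 1e-12:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def _check_binary_outcome(y: np.ndarray) -> None:
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all():
        raise ValueError(f"outcome must be coded 0/1, found values {classes}")
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic model undefined")


def _logit_fit(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed (possible complete separation): {exc}")
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible complete separation)")
    if np.any(np.abs(res.params[1:]) > 50) or np.any(~np.isfinite(res.bse)):
        raise ValueError("complete separation detected: unbounded coefficient")
    return res


def _or_table(res, names: Sequence[str], scales: Sequence[float]) -> pd.DataFrame:
    z = sps.norm.ppf(0.975)
    rows = []
    for i, (name, scale) in enumerate(zip(names, scales)):
        b, se = res.params[i], res.bse[i]
        rows.append(
            {
                "term": name,
                "estimate": math.exp(b * scale) if name != "Intercept" else b,
                "lo": math.exp((b - z * se) * scale) if name != "Intercept" else b - z * se,
                "hi": math.exp((b + z * se) * scale) if name != "Intercept" else b + z * se,
                "p": float(res.pvalues[i]),
                "scale": scale,
            }
        )
    return pd.DataFrame(rows)


def univariate_logistic(
    cohort: pd.DataFrame,
    predictor: str,
    outcome: str = "recurrence",
    scale: float = 1.0,
) -> ModelResult:
    """Logistic regression of the binary outcome on one predictor.

    The odds ratio is reported per ``scale`` units of the predictor
    (``OR = exp(coef * scale)``), with a Wald 95% CI and p-value.  Mixing
    reporting scales (per mm^2, per HU, per 10 HU) is common, so the scale
    is explicit in the result table.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    _check_binary_outcome(y)
    x = cohort[predictor].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    res = _logit_fit(y, X)
    table = _or_table(res, ["Intercept", predictor], [1.0, scale])
    return ModelResult(kind="logistic-univariate", table=table,
                       extras={"coef": dict(zip(["Intercept", predictor], res.params))})


def forward_conditional_logistic(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "recurrence",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    scales: Mapping[str, float] | None = None,
) -> ModelResult:
    """Multivariable logistic model built by forward conditional selection.

    At each step the candidate with the smallest score-test p-value below
    ``p_enter`` is entered; entered terms are then re-checked and removed
    if their likelihood-ratio p-value exceeds ``p_remove``.  The returned
    result carries the final odds ratios (Wald CIs) and the full ordered
    selection trace.  If nothing passes the entry threshold, the
    intercept-only model is returned with a note.
    """
    import statsmodels.api as sm

    y = cohort[outcome].to_numpy(dtype=float)
    _check_binary_outcome(y)
    scales = dict(scales or {})
    included: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []

    def fit_glm(terms: Sequence[str]):
        X = np.column_stack(
            [np.ones(len(cohort))] + [cohort[t].to_numpy(dtype=float) for t in terms]
        )
        return sm.GLM(y, X, family=sm.families.Binomial()).fit(), X

    step = 0
    while remaining:
        res_cur, _ = fit_glm(included)
        # score (Rao) test of each candidate given the current model
        best_term, best_p = None, np.inf
        for term in remaining:
            stat, pval, _ = res_cur.score_test(
                exog_extra=cohort[term].to_numpy(dtype=float)[:, None]
            )
            pval = float(np.atleast_1d(pval)[0])
            if pval < best_p:
                best_term, best_p = term, pval
        if best_term is None or best_p >= p_enter:
            break
        step += 1
        included.append(best_term)
        remaining.remove(best_term)
        trace.append({"step": step, "action": "enter", "term": best_term, "p": best_p})

        # conditional re-check: remove any entered term whose LR p > p_remove
        changed = True
        while changed and len(included) > 1:
            changed = False
            res_full, _ = fit_glm(included)
            for term in list(included):
                res_red, _ = fit_glm([t for t in included if t != term])
                lr = 2.0 * (res_full.llf - res_red.llf)
                p_lr = float(sps.chi2.sf(max(lr, 0.0), df=1))
                if p_lr > p_remove:
                    included.remove(term)
                    remaining.append(term)
                    trace.append(
                        {"step": step, "action": "remove", "term": term, "p": p_lr}
                    )
                    changed = True
                    break

    notes: list[str] = []
    if not included:
        notes.append("no candidate passed the entry threshold; intercept-only model")
        res = _logit_fit(y, np.ones((len(cohort), 1)))
        table = _or_table(res, ["Intercept"], [1.0])
    else:
        X = np.column_stack(
            [np.ones(len(cohort))] + [cohort[t].to_numpy(dtype=float) for t in included]
        )
        res = _logit_fit(y, X)
        names = ["Intercept"] + included
        table = _or_table(res, names, [1.0] + [scales.get(t, 1.0) for t in included])
    return ModelResult(
        kind="logistic-forward-conditional",
        table=table,
        trace=trace,
        notes=notes,
        extras={
            "selected": included,
            "linear_predictor": (res.predict(X, which="linear")
                                 if included else np.full(len(cohort), res.params[0])),
        } if included else {"selected": included},
    )


# ---------------------------------------------------------------------------
# ROC / C-index
# ---------------------------------------------------------------------------


def _delong_auc_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midranks (Sun & Xu formulation)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_s = np.r_[pos, neg]
    rank_all = sps.rankdata(all_s)  # midranks handle ties
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n - auc  # structural components, cases
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m - auc  # controls
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_cindex(scores: Sequence[float], outcome: Sequence[int]) -> ModelResult:
    """Apparent AUC (C-index) of a risk score, with a DeLong-type 95% CI.

    The AUC is the probability that a random case outranks a random
    control, with ties counted half (trapezoidal/concordance rule).  The
    CI uses the asymptotic DeLong variance, clipped to [0, 1].  The AUC is
    in-sample when the score comes from a model fitted on the same
    patients; no cross-validation is applied.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    _check_binary_outcome(y)
    auc, var = _delong_auc_variance(s, y)
    z = sps.norm.ppf(0.975)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p = float("nan")
    table = pd.DataFrame(
        [
            {
                "term": "AUC",
                "estimate": auc,
                "lo": max(0.0, auc - z * se),
                "hi": min(1.0, auc + z * se),
                "p": p,
                "scale": 1.0,
            }
        ]
    )
    return ModelResult(kind="roc", table=table,
                       notes=["apparent (in-sample) C-index; no validation split"])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    test: str        # "t" | "chi2" | "fisher"
    statistic: float
    p: float


def group_compare(
    cohort: pd.DataFrame,
    variable: str,
    by: str = "recurrence",
    categorical: bool | None = None,
    exact: str = "auto",
) -> GroupComparison:
    """Two-group comparison of a cohort variable.

    Continuous variables use the two-sample Student t-test (equal
    variances); categorical variables use the Pearson chi-square test
    without continuity correction.  ``exact`` controls Fisher's exact
    test on 2x2 tables: ``"auto"`` switches when any expected cell is
    below 5 (the textbook rule), ``"always"``/``"never"`` force the
    choice (published tables do not always follow the switch rule, so it
    must be overridable to reproduce them).
    """
    if exact not in ("auto", "always", "never"):
        raise ValueError(f"exact must be auto/always/never, got {exact!r}")
    groups = cohort[by]
    levels = np.unique(groups.dropna())
    if levels.size != 2:
        raise ValueError(f"grouping column {by!r} must have exactly 2 levels")
    x = cohort[variable]
    a = x[groups == levels[0]].dropna()
    b = x[groups == levels[1]].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if categorical is None:
        categorical = (not pd.api.types.is_numeric_dtype(x)) or x.nunique() <= 2
    if not categorical:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison(test="t", statistic=float(stat), p=float(p))
    tab = pd.crosstab(cohort[variable], groups).to_numpy()
    if tab.shape == (2, 2) and exact != "never":
        use_fisher = exact == "always" or (sps.contingency.expected_freq(tab) < 5).any()
        if use_fisher:
            odds, p = sps.fisher_exact(tab)
            return GroupComparison(test="fisher", statistic=float(odds), p=float(p))
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return GroupComparison(test="chi2", statistic=float(stat), p=float(p))


# ---------------------------------------------------------------------------
# Cox cross-check
# ---------------------------------------------------------------------------


def cox_univariate(
    cohort: pd.DataFrame,
    predictor: str,
    time_col: str = "time_to_event_years",
    event_col: str = "event_observed",
    scale: float = 1.0,
) -> ModelResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns the hazard ratio per ``scale`` units with Wald 95% CI; used to
    corroborate the logistic odds ratios on the same cohort.
    """
    from lifelines import CoxPHFitter

    if cohort[event_col].sum() == 0:
        raise ValueError("no observed events; Cox model undefined")
    df = cohort[[time_col, event_col, predictor]].dropna()
    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    row = cph.summary.loc[predictor]
    b, se = float(row["coef"]), float(row["se(coef)"])
    z = sps.norm.ppf(0.975)
    table = pd.DataFrame(
        [
            {
                "term": predictor,
                "estimate": math.exp(b * scale),
                "lo": math.exp((b - z * se) * scale),
                "hi": math.exp((b + z * se) * scale),
                "p": float(row["p"]),
                "scale": scale,
            }
        ]
    )
    return ModelResult(kind="cox-univariate", table=table,
                       extras={"coef": b, "se": se})


# ---------------------------------------------------------------------------
# supplementary-table reproduction
# ---------------------------------------------------------------------------

_DEFAULT_S1_CANDIDATES = (
    "diameter_mm_1mm",
    "perimeter_mm_1mm",
    "area_mm2_1mm",
    "mean_attenuation_hu_1mm",
)


def reproduce_supplementary(
    table: str | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    candidates: Sequence[str] = _DEFAULT_S1_CANDIDATES,
) -> dict:
    """Re-run the headline analyses on a per-patient cohort spreadsheet.

    ``table`` may be a path to an XLSX/CSV export of the per-patient CT
    findings or an in-memory DataFrame; ``column_map`` renames source
    columns to the canonical names used here (``*_1mm``/``*_5mm`` feature
    columns plus ``recurrence``).  Returns the recurrence count, the
    thin/thick diameter ICC, the univariate diameter odds ratio (per mm),
    the forward-conditional model and the C-index of its risk score.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        path = str(table)
        df = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    else:
        df = table.copy()
    if column_map:
        df = df.rename(columns=dict(column_map))

    out: dict = {"n": int(len(df)), "recurrence_count": int(df["recurrence"].sum())}
    if {"diameter_mm_1mm", "diameter_mm_5mm"}.issubset(df.columns):
        icc = icc_agreement(df["diameter_mm_1mm"], df["diameter_mm_5mm"])
        out["icc_diameter"] = icc.estimate("ICC")
    if "diameter_mm_1mm" in df.columns:
        uni = univariate_logistic(df, "diameter_mm_1mm")
        out["or_diameter_per_mm"] = uni.estimate("diameter_mm_1mm")
    avail = [c for c in candidates if c in df.columns]
    if avail:
        model = forward_conditional_logistic(df, avail)
        out["selected"] = model.extras["selected"]
        out["model"] = model
        if model.extras["selected"]:
            roc = roc_cindex(model.extras["linear_predictor"], df["recurrence"])
            out["c_index"] = roc.estimate("AUC")
    return out
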