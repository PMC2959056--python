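"""The statistical chain: ROC threshold selection, diagnostic metrics,
logistic GEE for clustered segmental outcomes, model building for ΔEF,
Cohen's kappa and basic group comparisons.

AUC uses the Mann-Whitney pair-counting identity (ties count 1/2); the
operating threshold maximises Youden's J (sensitivity + specificity - 1)
with ties broken toward higher sensitivity, and a patient is test-positive
when the segment count is at or above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "DiagnosticResult",
    "ModelFit",
    "StatResult",
    "roc_threshold",
    "diagnostics_from_prevalence",
    "gee_logistic",
    "model_building",
    "cohens_kappa",
    "group_compare",
]


@dataclass
class DiagnosticResult:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    thresholds: np.ndarray = field(repr=False)
    sens_curve: np.ndarray = field(repr=False)
    spec_curve: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("threshold", "tp", "fp", "fn", "tn", "sensitivity", "specificity", "ppv", "npv", "auc")
        }
        d["curve"] = {
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sens_curve.tolist(),
            "specificity": self.spec_curve.tolist(),
        }
        return d


@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    n_obs: int
    n_clusters: int | None = None
    diagnostic: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": pd.Series(self.params),
                "se": pd.Series(self.bse),
                "p": pd.Series(self.pvalues),
            }
        )


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p: float


def _pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via average ranks: U / (n1*n0), with tied pairs counting 1/2."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_threshold(
    scores,
    labels,
    thresholds=None,
) -> DiagnosticResult:
    """ROC analysis of a segment-count predictor of recovery.

    ``scores`` are per-patient counts (0..16), ``labels`` the responder
    flags. The curve is evaluated at every integer threshold 0..17 by
    default (positivity: score >= threshold); the operating point
    maximises Youden's J, ties broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both responder classes must be present for ROC analysis")

    if thresholds is None:
        lo = min(0, int(np.floor(scores.min())))
        hi = max(16, int(np.ceil(scores.max()))) + 1
        thresholds = np.arange(lo, hi + 1, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pos = scores >= t
        sens[i] = (pos & labels).sum() / n_pos
        spec[i] = (~pos & ~labels).sum() / n_neg

    j = sens + spec - 1.0
    best = 0
    for i in range(1, thresholds.size):
        if j[i] > j[best] + 1e-12 or (abs(j[i] - j[best]) <= 1e-12 and sens[i] > sens[best]):
            best = i
    t_star = float(thresholds[best])
    pos = scores >= t_star
    tp = int((pos & labels).sum())
    fp = int((pos & ~labels).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    return DiagnosticResult(
        threshold=t_star,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        auc=_pair_count_auc(scores, labels),
        thresholds=thresholds,
        sens_curve=sens,
        spec_curve=spec,
    )


def diagnostics_from_prevalence(
    sens: float, spec: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV from sensitivity, specificity and prevalence (Bayes)."""
    for name, v in (("sensitivity", sens), ("specificity", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    pi = prevalence
    den_p = sens * pi + (1.0 - spec) * (1.0 - pi)
    den_n = spec * (1.0 - pi) + (1.0 - sens) * pi
    ppv = sens * pi / den_p if den_p > 0 else float("nan")
    npv = spec * (1.0 - pi) / den_n if den_n > 0 else float("nan")
    return ppv, npv


def gee_logistic(
    data: pd.DataFrame,
    outcome: str = "recovered",
    predictor: str = "grade",
    cluster: str = "patient_id",
    working_corr: str = "ar1",
    covariates: tuple[str, ...] = (),
    categorical_predictor: bool = False,
    time: str = "segment",
) -> ModelFit:
    """Logistic GEE for clustered binary segment outcomes.

    Clusters are patients; the AR1 working correlation orders segments
    within a patient by ``time`` (the segment index). Standard errors are
    robust (sandwich). With ``working_corr="independence"`` no
    within-cluster correlation is modelled, matching ordinary logistic
    regression on singleton clusters.
    """
    if working_corr not in ("ar1", "independence"):
        raise ValueError("working_corr must be 'ar1' or 'independence'")
    if data[cluster].nunique() < 2:
        raise ValueError("GEE requires at least 2 clusters")
    df = data.sort_values([cluster, time]).reset_index(drop=True)
    y = df[outcome].astype(float)

    cols = {}
    if categorical_predictor:
        levels = sorted(df[predictor].unique())
        for lv in levels[1:]:
            cols[f"{predictor}[{lv}]"] = (df[predictor] == lv).astype(float)
    else:
        cols[predictor] = df[predictor].astype(float)
    for c in covariates:
        cols[c] = df[c].astype(float)
    X = sm.add_constant(pd.DataFrame(cols), prepend=True)

    if working_corr == "ar1":
        cov_struct = sm.cov_struct.Autoregressive(grid=True)
        time_arg = df.groupby(cluster)[time].rank(method="first").astype(int).to_numpy() - 1
    else:
        cov_struct = sm.cov_struct.Independence()
        time_arg = None

    model = sm.GEE(
        y,
        X,
        groups=df[cluster],
        time=time_arg,
        family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    name = f"GEE-logistic-{'AR1' if working_corr == 'ar1' else 'independent'}"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        big = max(abs(v) for v in res.params)
        converged = bool(getattr(res, "converged", True)) and np.isfinite(big) and big < 50
        diagnostic = "" if converged else "possible separation: extreme or non-converged estimates"
    except Exception as exc:  # separation and other fit failures
        return ModelFit(
            model=name,
            params={},
            bse={},
            pvalues={},
            converged=False,
            n_obs=len(df),
            n_clusters=df[cluster].nunique(),
            diagnostic=f"fit failed: {exc}",
        )
    return ModelFit(
        model=name,
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        converged=converged,
        n_obs=len(df),
        n_clusters=df[cluster].nunique(),
        diagnostic=diagnostic,
    )


def model_building(
    data: pd.DataFrame,
    candidates: tuple[str, ...],
    outcome: str = "delta_ef",
    screen_alpha: float = 0.1,
) -> tuple[pd.DataFrame, ModelFit | None]:
    """Two-stage model building for late change in EF.

    Stage 1 screens each candidate with a simple linear regression on the
    outcome, retaining variables with p < ``screen_alpha`` (0.1). Stage 2
    enters all retained variables simultaneously in one OLS fit. Returns
    the univariate screen table (Pearson r, slope, p, retained flag) and
    the multivariate fit (None when nothing is retained).
    """
    y = data[outcome].astype(float)
    rows = []
    retained = []
    for var in candidates:
        x = data[var].astype(float)
        if x.nunique() < 2:
            rows.append({"variable": var, "r": np.nan, "slope": np.nan, "p": np.nan, "retained": False})
            continue
        fit = sps.linregress(x, y)
        keep = fit.pvalue < screen_alpha
        rows.append(
            {"variable": var, "r": fit.rvalue, "slope": fit.slope, "p": fit.pvalue, "retained": keep}
        )
        if keep:
            retained.append(var)
    screen = pd.DataFrame(rows)
    if not retained:
        return screen, None

    X = sm.add_constant(data[retained].astype(float), prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    res = sm.OLS(y, X).fit()
    fit = ModelFit(
        model="OLS",
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        converged=True,
        n_obs=len(data),
        diagnostic="" if rank == X.shape[1] else f"rank deficient: rank {rank} < {X.shape[1]} columns",
    )
    return screen, fit


def cohens_kappa(grades_a, grades_b) -> float:
    """Unweighted Cohen's kappa between two raters' ordinal gradings."""
    a = np.asarray(grades_a)
    b = np.asarray(grades_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be equal-length 1-d arrays")
    cats = np.union1d(a, b)
    if cats.size < 2:
        raise ValueError("kappa undefined: a single category in both raters")
    n = a.size
    p_o = np.mean(a == b)
    p_e = sum((a == c).mean() * (b == c).mean() for c in cats)
    if p_e == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def group_compare(values, groups=None, pairs=None, kind: str | None = None) -> StatResult:
    """Paired t, chi-square/Fisher, or Mann-Whitney comparison.

    ``kind``: ``paired_t`` (values, pairs = pre/post vectors),
    ``dichotomous`` (values = 2x2 table; Fisher's exact test replaces the
    chi-square when any expected cell count is < 5), or ``mann_whitney``
    (values, groups = the two samples).
    """
    if kind == "paired_t":
        x = np.asarray(values, float)
        y = np.asarray(pairs, float)
        if x.size != y.size or x.size < 2:
            raise ValueError("paired t-test needs >= 2 pairs")
        d = x - y
        if np.allclose(d, 0) and np.allclose(d.std(), 0):
            return StatResult("paired_t", 0.0, 1.0)  # identical vectors
        t, p = sps.ttest_rel(x, y)
        return StatResult("paired_t", float(t), float(p))
    if kind == "dichotomous":
        table = np.asarray(values, float)
        if table.shape != (2, 2):
            raise ValueError("dichotomous comparison expects a 2x2 table")
        expected = sps.contingency.expected_freq(table)
        if np.any(expected < 5):
            odds, p = sps.fisher_exact(table)
            return StatResult("fisher_exact", float(odds), float(p))
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return StatResult("chi2", float(chi2), float(p))
    if kind == "mann_whitney":
        x = np.asarray(values, float)
        y = np.asarray(groups, float)
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        return StatResult("mann_whitney", float(u), float(p))
    raise ValueError("kind must be 'paired_t', 'dichotomous' or 'mann_whitney'")
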