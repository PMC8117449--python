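"""Group statistics, ROC characterization, logistic models, and the FET-DKI
index for the TPR-vs-TRC classification problem.

The cohort table holds one row per patient: group label (TPR = tumor
progression, TRC = treatment-related change), the 18 diffusion/kurtosis
histogram variables, and the 4 PET parameters.  Intergroup differences use
the Mann-Whitney U test with family-specific Bonferroni correction (m = 18
for the diffusion/kurtosis family, m = 4 for PET); discriminative power uses
the empirical ROC with Youden-optimal cutoffs and DeLong variance; single
and multi-predictor logistic regressions are fit by maximum likelihood; and
the composite FET-DKI index

    index = 4.7 * TBR_max + 39.2 * MK_C90,   TPR iff index > 41

is the clinically applicable one-number classifier.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .cohort import DT_METRICS, FEATURE_NAMES, KT_METRICS, PET_FEATURES

__all__ = [
    "MannWhitneyResult",
    "RocResult",
    "LogisticModel",
    "FET_DKI_WEIGHT_TBR",
    "FET_DKI_WEIGHT_MKC90",
    "FET_DKI_CUTOFF",
    "mann_whitney",
    "bonferroni",
    "roc_analysis",
    "delong_compare",
    "logistic_fit",
    "fet_dki_index",
    "prevalence_weighted_accuracy",
    "run_group_analysis",
]

POSITIVE_GROUP = "TPR"
NEGATIVE_GROUP = "TRC"

FET_DKI_WEIGHT_TBR = 4.7
FET_DKI_WEIGHT_MKC90 = 39.2
FET_DKI_CUTOFF = 41.0

DT_FEATURES = tuple(f for f in FEATURE_NAMES if f.rsplit("_", 1)[0] in DT_METRICS)
KT_FEATURES = tuple(f for f in FEATURE_NAMES if f.rsplit("_", 1)[0] in KT_METRICS)


# --- Mann-Whitney -------------------------------------------------------------


@dataclass
class MannWhitneyResult:
    u: float                 # U statistic of the first sample
    p_value: float           # two-sided
    method: str              # 'exact' or 'asymptotic'


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: concordant pairs, ties counted 1/2 (midranks)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney(a, b, exact_limit: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Small samples (n_a + n_b <= ``exact_limit``) are handled by exact
    enumeration of all group assignments of the pooled values, which stays
    valid under ties; larger samples use the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        dev_obs = abs(u - mu)
        hits = total = 0
        for comb in itertools.combinations(idx, n1):
            ua = _u_statistic(pooled[list(comb)],
                              pooled[[i for i in idx if i not in comb]])
            total += 1
            if abs(ua - mu) >= dev_obs - 1e-9:
                hits += 1
        return MannWhitneyResult(u=u, p_value=hits / total, method="exact")
    # asymptotic with tie correction
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=u, p_value=1.0, method="asymptotic")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return MannWhitneyResult(u=u, p_value=min(p, 1.0), method="asymptotic")


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def significance_category(p: float, alpha: float, m: int) -> str:
    """'significant' (p <= alpha/m), 'significant prior to correction'
    (alpha/m < p <= alpha), or 'not significant'."""
    thr = bonferroni(alpha, m)
    if p <= thr:
        return "significant"
    if p <= alpha:
        return "significant prior to correction"
    return "not significant"


# --- ROC ----------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    auc_ci_95: tuple[float, float]
    optimal_cutoff: float
    sensitivity: float       # percent
    specificity: float       # percent
    accuracy: float          # percent
    direction: str           # 'higher' or 'lower' values indicate the positive class
    p_value: float           # vs AUC = 0.5 (DeLong variance)
    n_pos: int
    n_neg: int


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per positive, V01 per negative."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    return v10, v01


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    v10, v01 = _placements(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return s10 / pos.size + s01 / neg.size


def roc_analysis(values, labels, positive: str = POSITIVE_GROUP,
                 auto_orient: bool = True) -> RocResult:
    """Empirical ROC: AUC with ties counted 1/2, Youden-optimal cutoff.

    The cutoff maximizes J = sensitivity + specificity - 1 over criteria of
    the form "value > c" (ties broken toward higher specificity); when
    ``auto_orient`` and the marker runs the other way (AUC < 0.5), the
    orientation is flipped and reported as ``direction='lower'``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    if is_pos.all() or (~is_pos).all():
        raise ValueError("ROC needs both classes present")
    pos, neg = values[is_pos], values[~is_pos]
    direction = "higher"
    auc = _u_statistic(pos, neg) / (pos.size * neg.size)
    if auto_orient and auc < 0.5:
        direction = "lower"
        pos, neg = -pos, -neg
        auc = 1.0 - auc
    # candidate cutoffs between consecutive distinct values
    allv = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([[allv[0] - 1.0], (allv[:-1] + allv[1:]) / 2.0, [allv[-1] + 1.0]])
    best = None
    for c in cands:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    if direction == "lower":
        cutoff = -cutoff  # report on the original scale ("value < -c" criterion)
    acc = prevalence_weighted_accuracy(sens * 100, spec * 100, pos.size, neg.size)
    var = _delong_variance(pos, neg)
    se = math.sqrt(var) if var > 0 else 0.0
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    # exact-binomial (Clopper-Pearson) bounds on the concordant-pair proportion
    n_pairs = pos.size * neg.size
    k = auc * n_pairs
    lo = sps.beta.ppf(0.025, k, n_pairs - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(0.975, k + 1, n_pairs - k) if k < n_pairs else 1.0
    return RocResult(auc=float(auc), auc_ci_95=(float(lo), float(hi)),
                     optimal_cutoff=float(cutoff),
                     sensitivity=sens * 100, specificity=spec * 100, accuracy=acc,
                     direction=direction, p_value=float(min(p, 1.0)),
                     n_pos=int(pos.size), n_neg=int(neg.size))


def prevalence_weighted_accuracy(sensitivity_pct: float, specificity_pct: float,
                                 n_pos: int, n_neg: int) -> float:
    """Overall accuracy (percent) implied by sensitivity/specificity and the
    group sizes: (sens * n_pos + spec * n_neg) / (n_pos + n_neg)."""
    return (sensitivity_pct * n_pos + specificity_pct * n_neg) / (n_pos + n_neg)


def delong_compare(values1, values2, labels,
                   positive: str = POSITIVE_GROUP) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns (auc1, auc2, z, p_two_sided).
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    labels = np.asarray(labels)
    if v1.shape != v2.shape or v1.shape[0] != labels.shape[0]:
        raise ValueError("markers must be paired on the same subjects")
    is_pos = labels == positive
    if is_pos.all() or (~is_pos).all():
        raise ValueError("need both classes present")
    p1, n1 = v1[is_pos], v1[~is_pos]
    p2, n2 = v2[is_pos], v2[~is_pos]
    m, n = p1.size, n1.size
    auc1 = _u_statistic(p1, n1) / (m * n)
    auc2 = _u_statistic(p2, n2) / (m * n)
    V10 = np.stack([_placements(p1, n1)[0], _placements(p2, n2)[0]])
    V01 = np.stack([_placements(p1, n1)[1], _placements(p2, n2)[1]])
    S10 = np.cov(V10) if m > 1 else np.zeros((2, 2))
    S01 = np.cov(V01) if n > 1 else np.zeros((2, 2))
    S = S10 / m + S01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 1e-15:
        return float(auc1), float(auc2), 0.0, 1.0
    z = (auc1 - auc2) / math.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(auc1), float(auc2), float(z), float(p)


# --- logistic regression ------------------------------------------------------


@dataclass
class LogisticModel:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]    # includes 'intercept'
    converged: bool
    separation: bool
    accuracy: float                   # percent, at probability 0.5
    auc: float
    fitted_probabilities: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit as _expit

        X = np.asarray(X, dtype=float)
        beta = np.array([self.coefficients[p] for p in self.predictors])
        return _expit(self.coefficients["intercept"] + X @ beta)


def logistic_fit(cohort: pd.DataFrame, predictors: list[str],
                 positive: str = POSITIVE_GROUP) -> LogisticModel:
    """Maximum-likelihood logistic regression of diagnosis on the predictors.

    Newton/IRLS via statsmodels (tol 1e-8, <= 100 iterations); complete or
    quasi-separation is detected (statsmodels' perfect-separation check or a
    diverging coefficient norm) and flagged rather than raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    if not predictors:
        raise ValueError("need at least one predictor")
    sub = cohort[predictors + ["group"]]
    if sub[predictors].isna().any().any():
        raise ValueError("missing values among selected predictors")
    y = (sub["group"].to_numpy() == positive).astype(float)
    X = sm.add_constant(sub[predictors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=False)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationWarning, np.linalg.LinAlgError):
            # diverging Newton steps (singular Hessian) and statsmodels'
            # explicit perfect-separation detection both mean separation
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=False,
                                         warn_convergence=False)
            params = res.params
            converged = False
    if np.abs(params[1:]).max(initial=0.0) > 1e3:
        separation = True
    coef = {"intercept": float(params[0])}
    coef.update({p: float(v) for p, v in zip(predictors, params[1:])})
    proba = expit(X @ params)
    pred = proba > 0.5
    acc = float(np.mean(pred == (y > 0.5))) * 100.0
    auc = _u_statistic(proba[y > 0.5], proba[y <= 0.5]) / max(
        1, int(y.sum()) * int((1 - y).sum()))
    return LogisticModel(predictors=tuple(predictors), coefficients=coef,
                         converged=converged, separation=separation,
                         accuracy=acc, auc=float(auc),
                         fitted_probabilities=proba)


# --- FET-DKI index ------------------------------------------------------------


def fet_dki_index(tbr_max, mk_c90,
                  cutoff: float = FET_DKI_CUTOFF) -> tuple[np.ndarray, np.ndarray]:
    """Composite index 4.7*TBR_max + 39.2*MK_C90 and its class calls.

    Classification is TPR iff index > cutoff (strictly).  Missing inputs
    yield NaN index and a masked (empty-string) call.
    """
    tbr = np.asarray(tbr_max, dtype=float)
    mk = np.asarray(mk_c90, dtype=float)
    index = FET_DKI_WEIGHT_TBR * tbr + FET_DKI_WEIGHT_MKC90 * mk
    calls = np.where(np.isnan(index), "",
                     np.where(index > cutoff, POSITIVE_GROUP, NEGATIVE_GROUP))
    if np.isnan(index).any():
        warnings.warn("missing TBR_max or MK_C90 for some patients; calls left blank")
    if np.ndim(tbr_max) == 0 and np.ndim(mk_c90) == 0:
        return float(index), str(calls)
    return index, calls


# --- cohort-level orchestration -----------------------------------------------

_MULTIVARIATE_PRESETS: tuple[tuple[str, ...], ...] = (
    ("MK_C90", "TBR_max"),
    ("MK_mean", "TBR_max"),
    ("MK_mean", "MK_C90", "TBR_max"),
)


def run_group_analysis(cohort: pd.DataFrame, alpha: float = 0.05,
                       roc_on: str = "significant") -> dict:
    """Full statistical screen of a cohort table.

    Per feature: Mann-Whitney with family-specific Bonferroni (m = 18 for
    diffusion/kurtosis, m = 4 for PET).  ROC analysis runs on features whose
    category is at least ``roc_on`` ('significant' for Bonferroni-corrected
    only, 'prior' to include pre-correction hits).  Univariate logistic fits
    mirror the ROC set; multivariate presets and the FET-DKI index complete
    the report.  Returns a JSON-serializable dict.
    """
    groups = set(cohort["group"].unique())
    if not {POSITIVE_GROUP, NEGATIVE_GROUP} <= groups:
        raise ValueError(
            f"cohort must contain both groups {POSITIVE_GROUP} and {NEGATIVE_GROUP}"
        )
    pos = cohort[cohort["group"] == POSITIVE_GROUP]
    neg = cohort[cohort["group"] == NEGATIVE_GROUP]
    features: dict[str, dict] = {}
    for name in FEATURE_NAMES:
        if name not in cohort.columns:
            continue
        m = 18 if name in DT_FEATURES + KT_FEATURES else 4
        a = neg[name].dropna().to_numpy()
        b = pos[name].dropna().to_numpy()
        mw = mann_whitney(a, b)
        cat = significance_category(mw.p_value, alpha, m)
        entry = {
            "family": "DKI" if m == 18 else "PET",
            "median_trc": float(np.median(a)) if a.size else math.nan,
            "q1_trc": float(np.percentile(a, 25)) if a.size else math.nan,
            "q3_trc": float(np.percentile(a, 75)) if a.size else math.nan,
            "median_tpr": float(np.median(b)) if b.size else math.nan,
            "q1_tpr": float(np.percentile(b, 25)) if b.size else math.nan,
            "q3_tpr": float(np.percentile(b, 75)) if b.size else math.nan,
            "u": mw.u,
            "p_value": mw.p_value,
            "bonferroni_m": m,
            "category": cat,
        }
        features[name] = entry

    wanted = {"significant"} if roc_on == "significant" else {
        "significant", "significant prior to correction"}
    roc: dict[str, dict] = {}
    logit_uni: dict[str, dict] = {}
    for name, entry in features.items():
        if entry["category"] not in wanted:
            continue
        vals = cohort[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        r = roc_analysis(vals[ok], cohort["group"].to_numpy()[ok])
        roc[name] = {
            "auc": r.auc, "ci_95": list(r.auc_ci_95), "cutoff": r.optimal_cutoff,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "accuracy": r.accuracy, "direction": r.direction, "p_value": r.p_value,
        }
        try:
            lm = logistic_fit(cohort.loc[ok], [name])
        except ValueError as err:
            logit_uni[name] = {"error": str(err)}
        else:
            logit_uni[name] = {"coefficients": lm.coefficients,
                               "accuracy": lm.accuracy,
                               "auc": lm.auc, "separation": lm.separation}

    logit_multi: dict[str, dict] = {}
    for preset in _MULTIVARIATE_PRESETS:
        if not all(p in cohort.columns for p in preset):
            continue
        ok = np.isfinite(cohort[list(preset)].to_numpy(dtype=float)).all(axis=1)
        key = " + ".join(preset)
        if ok.sum() <= len(preset) + 1:
            logit_multi[key] = {"error": "too few complete rows for this model"}
            continue
        try:
            lm = logistic_fit(cohort.loc[ok], list(preset))
        except ValueError as err:
            logit_multi[key] = {"error": str(err)}
            continue
        logit_multi[key] = {
            "coefficients": lm.coefficients, "accuracy": lm.accuracy,
            "auc": lm.auc, "separation": lm.separation,
        }

    idx, calls = fet_dki_index(cohort["TBR_max"].to_numpy(dtype=float),
                               cohort["MK_C90"].to_numpy(dtype=float))
    ok = np.isfinite(idx)
    idx_roc = roc_analysis(idx[ok], cohort["group"].to_numpy()[ok])
    correct = calls[ok] == cohort["group"].to_numpy()[ok]
    index_report = {
        "weights": {"TBR_max": FET_DKI_WEIGHT_TBR, "MK_C90": FET_DKI_WEIGHT_MKC90},
        "cutoff": FET_DKI_CUTOFF,
        "values": idx.tolist(),
        "calls": calls.tolist(),
        "accuracy_at_cutoff": float(np.mean(correct)) * 100.0,
        "roc": {"auc": idx_roc.auc, "cutoff": idx_roc.optimal_cutoff,
                "sensitivity": idx_roc.sensitivity,
                "specificity": idx_roc.specificity, "accuracy": idx_roc.accuracy,
                "p_value": idx_roc.p_value},
    }
    return {
        "n_trc": int(len(neg)),
        "n_tpr": int(len(pos)),
        "alpha": alpha,
        "bonferroni_thresholds": {"dki": bonferroni(alpha, 18), "pet": bonferroni(alpha, 4)},
        "features": features,
        "roc": roc,
        "logistic_univariate": logit_uni,
        "logistic_multivariate": logit_multi,
        "fet_dki_index": index_report,
    }


def group_table(report: dict) -> pd.DataFrame:
    """Median (Q1/Q3) per group and p-values, one row per feature."""
    rows = []
    for name, e in report["features"].items():
        rows.append({
            "feature": name, "family": e["family"],
            "TRC": f"{e['median_trc']:.2f} ({e['q1_trc']:.2f}/{e['q3_trc']:.2f})",
            "TPR": f"{e['median_tpr']:.2f} ({e['q1_tpr']:.2f}/{e['q3_tpr']:.2f})",
            "p_value": e["p_value"], "category": e["category"],
        })
    return pd.DataFrame(rows)


def roc_table(report: dict) -> pd.DataFrame:
    """AUC / cutoff / sensitivity / specificity / accuracy per analyzed marker."""
    rows = []
    for name, e in report["roc"].items():
        rows.append({"marker": name, "auc": e["auc"],
                     "ci_95_low": e["ci_95"][0], "ci_95_high": e["ci_95"][1],
                     "cutoff": e["cutoff"], "sensitivity": e["sensitivity"],
                     "specificity": e["specificity"], "accuracy": e["accuracy"],
                     "p_value": e["p_value"]})
    e = report["fet_dki_index"]["roc"]
    rows.append({"marker": "FET-DKI index", "auc": e["auc"], "ci_95_low": math.nan,
                 "ci_95_high": math.nan, "cutoff": e["cutoff"],
                 "sensitivity": e["sensitivity"], "specificity": e["specificity"],
                 "accuracy": e["accuracy"], "p_value": e["p_value"]})
    return pd.DataFrame(rows)
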