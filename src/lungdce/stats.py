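"""Group statistics for imaging-biomarker stratification.

The layer mirrors a conventional exploratory biomarker analysis: two-group
Mann-Whitney U tests and ROC analysis per feature at a chosen TPS threshold,
Kruskal-Wallis across histologies, Lin's concordance correlation coefficient
for inter-reader agreement, and bivariable logistic regression to probe
confounding.  No multiplicity correction is applied (12 features per
threshold are tested as-is); reports flag this explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import InvalidInputError, UndefinedStatisticError
from .features import FEATURE_COLUMNS

__all__ = [
    "mann_whitney_u",
    "kruskal_wallis",
    "RocResult",
    "roc_analysis",
    "lin_ccc",
    "CCC_REPRODUCIBLE_THRESHOLD",
    "ccc_report",
    "bivariable_logistic",
    "run_stratification",
    "kruskal_by_histology",
]

EXACT_MW_MAX_N = 16
CCC_REPRODUCIBLE_THRESHOLD = 0.85


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    The exact permutation null is used for small tie-free samples
    (n_x + n_y <= 16); otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InvalidInputError("need >= 2 non-empty groups")
    if np.unique(np.concatenate(groups)).size == 1:
        return 0.0, 1.0  # every observation tied: no evidence of any difference
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    positive_class: str  # which label value was treated as positive
    n_boot: int


def _operating_point(y: np.ndarray, scores: np.ndarray, rule: str) -> tuple[float, float, float, float]:
    fpr, tpr, thresholds = roc_curve(y, scores)
    # drop the sentinel threshold at +inf (classify-none point)
    fpr, tpr, thresholds = fpr[1:], tpr[1:], thresholds[1:]
    if rule == "youden":
        score = tpr - fpr
    elif rule == "accuracy":
        n_pos, n_neg = y.sum(), (~y).sum()
        score = (tpr * n_pos + (1 - fpr) * n_neg) / y.size
    else:
        raise InvalidInputError(f"unknown operating-point rule {rule!r}")
    best = np.max(score)
    candidates = np.flatnonzero(score >= best - 1e-12)
    idx = candidates[np.argmin(fpr[candidates])]  # ties -> higher specificity
    thr = float(thresholds[idx])
    pred = scores >= thr
    sens = float(np.mean(pred[y]))
    spec = float(np.mean(~pred[~y]))
    acc = float(np.mean(pred == y))
    return thr, acc, sens, spec


def _auc(y: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


def roc_analysis(
    feature, labels, n_boot: int = 2000, seed: int = 0, rule: str = "youden"
) -> RocResult:
    """ROC analysis of one feature against binary group labels.

    The positive class is the group with the higher feature median, so the
    reported AUC is oriented >= 0.5 in expectation and the orientation is
    recorded in the result.  The 95% CI is a seeded stratified nonparametric
    bootstrap (percentile interval).
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise InvalidInputError("labels must contain exactly two classes")
    med = {c: np.median(feature[labels == c]) for c in classes}
    positive = max(classes, key=lambda c: med[c])
    y = labels == positive
    auc = _auc(y, feature)
    thr, acc, sens, spec = _operating_point(y, feature, rule)

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(y), np.flatnonzero(~y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
        )
        boot[b] = _auc(y[idx], feature[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RocResult(
        auc=auc,
        ci95=(float(min(lo, auc)), float(max(hi, auc))),
        threshold=thr,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        positive_class=str(positive),
        n_boot=n_boot,
    )


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2); penalizes both
    location and scale shifts, so CCC <= |Pearson r| always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidInputError("need equal-length vectors with >= 3 samples")
    vx, vy = np.var(x), np.var(y)
    if vx == 0.0 and vy == 0.0:
        raise UndefinedStatisticError("CCC undefined: both vectors have zero variance")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def ccc_report(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Per-feature CCC table with the > 0.85 high-reproducibility flag."""
    rows = []
    for name, (x, y) in pairs.items():
        try:
            ccc = lin_ccc(x, y)
        except UndefinedStatisticError:
            ccc = np.nan
        rows.append(
            {"feature": name, "ccc": ccc, "highly_reproducible": bool(ccc > CCC_REPRODUCIBLE_THRESHOLD)}
        )
    return pd.DataFrame(rows).set_index("feature")


def bivariable_logistic(feature, labels, histology=None, nodal=None) -> pd.DataFrame:
    """Logistic fits label ~ feature + covariate, one covariate at a time.

    ``histology`` is dummy-coded; constant covariates reduce to the
    univariable fit.  Complete separation is detected and flagged rather than
    reported as a spuriously perfect fit.

    Returns a row per adjusted model with the feature's Wald p-value, whether
    it stays < 0.05, and a separation flag.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    feature = np.asarray(feature, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise InvalidInputError("labels must be binary")
    covariates: dict[str, pd.DataFrame] = {}
    if nodal is not None:
        nod = pd.get_dummies(pd.Series(nodal, name="nodal"), drop_first=True, dtype=float)
        covariates["nodal"] = nod
    if histology is not None:
        hist = pd.get_dummies(pd.Series(histology, name="histology"), drop_first=True, dtype=float)
        covariates["histology"] = hist
    if not covariates:
        covariates["none"] = pd.DataFrame(index=range(y.size))

    rows = []
    for name, cov in covariates.items():
        cov = cov.loc[:, cov.std(axis=0) > 0] if cov.shape[1] else cov
        design = pd.DataFrame({"feature": feature})
        design = pd.concat([design, cov.reset_index(drop=True)], axis=1)
        design = sm.add_constant(design)
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            coef = float(fit.params["feature"])
            pval = float(fit.pvalues["feature"])
            if not np.isfinite(pval) or abs(coef) > 1e3:
                separation = True
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            if not isinstance(exc, (PerfectSeparationWarning, np.linalg.LinAlgError)) and \
                    "separation" not in str(exc).lower() and "singular" not in str(exc).lower():
                raise
            separation, coef, pval = True, np.nan, np.nan
        rows.append(
            {
                "adjusted_for": name,
                "feature_coef": coef,
                "feature_p": pval,
                "feature_significant": bool(np.isfinite(pval) and pval < 0.05),
                "complete_separation": separation,
            }
        )
    return pd.DataFrame(rows).set_index("adjusted_for")


def run_stratification(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: float,
    n_boot: int = 2000,
    seed: int = 0,
    rule: str = "youden",
) -> pd.DataFrame:
    """Per-feature stratification table at a TPS threshold (1 or 50).

    One row per first-order feature with group medians, Mann-Whitney p, and
    the ROC block (AUC, bootstrap 95% CI, Youden operating point with
    accuracy/sensitivity/specificity).  Significance is marked at p < 0.05
    with NO multiple-testing correction; treat marked rows as exploratory.
    """
    if threshold not in (1, 50) and not 0 < threshold < 100:
        raise InvalidInputError("threshold must be a TPS percentage in (0, 100)")
    joined = features.join(labels, how="inner")
    if joined.empty:
        raise InvalidInputError("no overlapping patients between features and labels")
    ge = joined["tps_percent"].to_numpy(float) >= threshold
    if ge.all() or not ge.any():
        raise InvalidInputError("both TPS groups must be non-empty at this threshold")
    rows = []
    for i, col in enumerate(FEATURE_COLUMNS):
        vals = joined[col].to_numpy(float)
        ok = np.isfinite(vals)
        v, g = vals[ok], ge[ok]
        u, p = mann_whitney_u(v[~g], v[g])
        roc = roc_analysis(
            v, np.where(g, f">={threshold}%", f"<{threshold}%"), n_boot=n_boot,
            seed=seed + i, rule=rule,
        )
        rows.append(
            {
                "feature": col,
                f"median_lt{threshold}": float(np.median(v[~g])),
                f"median_ge{threshold}": float(np.median(v[g])),
                "roc_auc": roc.auc,
                "auc_ci_lo": roc.ci95[0],
                "auc_ci_hi": roc.ci95[1],
                "threshold": roc.threshold,
                "accuracy": roc.accuracy,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "positive_class": roc.positive_class,
                "U": u,
                "p_value": p,
                "significant_uncorrected": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def kruskal_by_histology(features: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis H test of every feature across histology subgroups."""
    joined = features.join(labels, how="inner")
    rows = []
    for col in FEATURE_COLUMNS:
        groups = [
            sub[col].dropna().to_numpy(float)
            for _, sub in joined.groupby("histology")
            if sub[col].notna().any()
        ]
        h, p = kruskal_wallis(groups)
        rows.append({"feature": col, "H": h, "p_value": p})
    return pd.DataFrame(rows).set_index("feature")
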