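"""Evaluation of features and risk models: ROC/AUC with Youden cutoffs,
univariate association reports, Cox proportional-hazards fits,
Kaplan-Meier / log-rank stratification, and the three-model comparison
(clinical-only, radiomics-only, combined) on train and test sides.

All operating points (per-variable orientations and Youden cutoffs, the
factor sets entering each model, and the model-score cutoffs) are chosen
on the training side and applied frozen to the testing side; the audit
trail records them so the absence of re-optimization is checkable.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "RocResult",
    "SurvivalFit",
    "KMResult",
    "ModelComparison",
    "roc_auc",
    "youden_cutoff",
    "univariate_report",
    "cox_fit",
    "km_logrank",
    "evaluate_models",
    "logistic_or_report",
]


@dataclass
class RocResult:
    """AUC (orientation-corrected to >= 0.5), the Youden operating point,
    and the p-value of AUC against 0.5 (Mann-Whitney)."""

    auc: float
    orientation: str          # "high": high values predict the event
    cutoff: float
    sensitivity: float        # percent
    specificity: float        # percent
    p_value: float


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic with mid-ranks for ties."""
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(values)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_auc(values: np.ndarray, labels: np.ndarray) -> RocResult:
    """Rank-statistic AUC with orientation handling.

    If the raw AUC is below 0.5 the orientation is flipped (low values
    predict the event) and the reported AUC is 1 - raw, so the result is
    always in [0.5, 1].  A constant feature scores exactly 0.5.
    """
    y = np.asarray(labels).astype(int)
    x = np.asarray(values, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    raw = _rank_auc(x, y)
    orientation = "high" if raw >= 0.5 else "low"
    auc = raw if raw >= 0.5 else 1.0 - raw
    if np.ptp(x) == 0:
        p = 1.0
    else:
        res = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided",
                                 method="auto")
        p = float(res.pvalue)
    cutoff, se, sp = youden_cutoff(x, y, orientation)
    return RocResult(auc, orientation, cutoff, se, sp, p)


def youden_cutoff(
    values: np.ndarray, labels: np.ndarray, orientation: str = "high"
) -> tuple[float, float, float]:
    """Operating point maximizing J = Se + Sp - 1.

    Candidate thresholds are midpoints between consecutive distinct
    values; ties on J are broken toward the cutoff with the higher
    sensitivity.  Returns (cutoff, sensitivity %, specificity %); with
    orientation "high" a subject is called positive when value > cutoff,
    with "low" when value < cutoff.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    score = x if orientation == "high" else -x
    distinct = np.unique(score)
    if len(distinct) == 1:
        cut = distinct[0]
        return (float(cut if orientation == "high" else -cut), 0.0,
                100.0)
    mids = (distinct[:-1] + distinct[1:]) / 2
    n1 = y.sum()
    n0 = len(y) - n1
    best = None
    for c in mids:
        pos = score > c
        se = (pos & (y == 1)).sum() / n1
        sp = (~pos & (y == 0)).sum() / n0
        j = se + sp - 1
        if best is None or (j, se) > (best[0], best[1]):
            best = (j, se, sp, c)
    _, se, sp, c = best
    cutoff = float(c if orientation == "high" else -c)
    return cutoff, float(100 * se), float(100 * sp)


def univariate_report(
    features: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Per-variable AUC / Se / Sp / best cutoff / p-value table, one row
    per column of ``features`` in column order."""
    rows = []
    for col in features.columns:
        r = roc_auc(features[col].to_numpy(dtype=float), labels)
        rows.append({
            "variable": col,
            "auc": r.auc,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "cutoff": r.cutoff,
            "orientation": r.orientation,
            "p_value": r.p_value,
        })
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class SurvivalFit:
    """Cox proportional-hazards fit: per-covariate HR, CI and p-value."""

    summary: pd.DataFrame      # index: covariate; columns: hr, ci_lower, ci_upper, p
    log_likelihood: float
    penalized: bool = False

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    penalizer: float = 0.0,
) -> SurvivalFit:
    """Cox partial-likelihood fit (Efron tie handling).

    On failure to converge (e.g. complete separation of a dichotomized
    covariate) the model is refit with a ridge penalty and flagged, so
    callers get finite, documented estimates rather than divergence.
    """
    def _fit(pen: float) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=pen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        return cph

    penalized = penalizer > 0
    try:
        cph = _fit(penalizer)
        coefs = cph.summary["coef"]
        # |log HR| beyond ~10 is a separation artifact, not an estimate
        if not np.isfinite(coefs).all() or np.abs(coefs).max() > 10:
            raise ConvergenceError("divergent coefficients")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        cph = _fit(max(penalizer, 0.1))
        penalized = True
    s = cph.summary
    summary = pd.DataFrame({
        "hr": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    summary.index = [i[-1] if isinstance(i, tuple) else i for i in s.index]
    return SurvivalFit(summary, float(cph.log_likelihood_), penalized)


@dataclass
class KMResult:
    """Product-limit curves per group and the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]   # columns: time, survival
    statistic: float
    p_value: float

    def export_csv(self, path: str | Path) -> None:
        frames = []
        for g, c in self.curves.items():
            f = c.copy()
            f.insert(0, "group", g)
            frames.append(f)
        pd.concat(frames).to_csv(path, index=False)


def km_logrank(
    groups: np.ndarray, times: np.ndarray, events: np.ndarray
) -> KMResult:
    """Kaplan-Meier estimates per group plus the 1-df two-sided log-rank
    test between the two groups.  Identical event experience in a single
    group (or an empty comparison group) yields statistic 0, p = 1."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    uniq = np.unique(groups)
    curves = {}
    for g in uniq:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(g)] = sf
    if len(uniq) != 2:
        return KMResult(curves, 0.0, 1.0)
    a = groups == uniq[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    stat, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return KMResult(curves, stat, p)


# ---------------------------------------------------------------------------
# three-model comparison


@dataclass
class DichotomizedFactor:
    """A train-side frozen operating rule for one variable."""

    variable: str
    cutoff: float
    orientation: str    # "high": positive when value > cutoff

    def apply(self, values: pd.Series) -> np.ndarray:
        v = values.to_numpy(dtype=float)
        return (v > self.cutoff).astype(int) if self.orientation == "high" \
            else (v < self.cutoff).astype(int)


@dataclass
class ModelSideResult:
    auc: float
    sensitivity: float
    specificity: float
    p_value: float
    logrank_p: float
    logrank_stat: float
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float


@dataclass
class ModelComparison:
    """Per model (clinical / radiomics / combined) and per cohort side:
    ROC of the additive risk score, and KM/Cox of the dichotomized risk
    groups.  ``factors`` and ``score_cutoffs`` are the train-side frozen
    decisions (the leakage audit)."""

    results: dict[str, dict[str, ModelSideResult]]
    factors: dict[str, list[DichotomizedFactor]]
    score_cutoffs: dict[str, float]
    audit: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "models": {
                m: {side: vars(r) for side, r in sides.items()}
                for m, sides in self.results.items()
            },
            "factors": {
                m: [vars(f) for f in fs] for m, fs in self.factors.items()
            },
            "score_cutoffs": self.score_cutoffs,
            "audit": self.audit,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for m, sides in self.results.items():
            for side, r in sides.items():
                rows.append({
                    "model": m, "side": side, "auc": r.auc,
                    "sensitivity": r.sensitivity, "specificity": r.specificity,
                    "p_value": r.p_value, "logrank_p": r.logrank_p,
                    "hr": r.hr, "hr_p": r.hr_p,
                })
        return pd.DataFrame(rows)


def _score(factors: list[DichotomizedFactor], table: pd.DataFrame) -> np.ndarray:
    if not factors:
        return np.zeros(len(table))
    return np.sum([f.apply(table[f.variable]) for f in factors], axis=0)


def _roc_or_flat(score: np.ndarray, labels: np.ndarray) -> RocResult:
    if np.ptp(score) == 0:
        return RocResult(0.5, "high", float(score[0]) if len(score) else 0.0,
                         0.0, 100.0, 1.0)
    return roc_auc(score, labels)


def _best_factor_set(
    table: pd.DataFrame,
    labels: np.ndarray,
    candidates: list[str],
    max_factors: int,
) -> list[DichotomizedFactor]:
    """Additive-combination search on the training side: dichotomize every
    candidate at its Youden point, then pick the subset (size 1..max)
    whose additive score maximizes train AUC.  Ties prefer fewer factors,
    then lexicographic order."""
    dichotomized: dict[str, DichotomizedFactor] = {}
    for var in candidates:
        r = roc_auc(table[var].to_numpy(dtype=float), labels)
        dichotomized[var] = DichotomizedFactor(var, r.cutoff, r.orientation)
    best: tuple[float, int, tuple[str, ...]] | None = None
    for size in range(1, max_factors + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            factors = [dichotomized[v] for v in combo]
            auc = _roc_or_flat(_score(factors, table), labels).auc
            key = (-auc, size, combo)
            if best is None or key < best:
                best = key
    if best is None:
        return []
    return [dichotomized[v] for v in best[2]]


def _side_result(
    factors: list[DichotomizedFactor],
    score_cutoff: float,
    features: pd.DataFrame,
    outcome: pd.DataFrame,
) -> ModelSideResult:
    labels = outcome["event"].to_numpy(dtype=int)
    score = _score(factors, features)
    roc = _roc_or_flat(score, labels)
    high_risk = (score > score_cutoff).astype(int)
    if high_risk.min() == high_risk.max():
        km = KMResult({}, 0.0, 1.0)
        hr, ci, hr_p = float("nan"), (float("nan"), float("nan")), 1.0
    else:
        km = km_logrank(high_risk, outcome["time_months"].to_numpy(),
                        labels)
        fit = cox_fit(pd.DataFrame({
            "high_risk": high_risk,
            "time_months": outcome["time_months"].to_numpy(dtype=float),
            "event": labels,
        }))
        hr = fit.hr("high_risk")
        ci = (float(fit.summary.loc["high_risk", "ci_lower"]),
              float(fit.summary.loc["high_risk", "ci_upper"]))
        hr_p = float(fit.summary.loc["high_risk", "p"])
    return ModelSideResult(roc.auc, roc.sensitivity, roc.specificity,
                           roc.p_value, km.p_value, km.statistic, hr, ci, hr_p)


def evaluate_models(
    radiomic_train: pd.DataFrame,
    radiomic_test: pd.DataFrame,
    clinical_train: pd.DataFrame,
    clinical_test: pd.DataFrame,
    outcome_train: pd.DataFrame,
    outcome_test: pd.DataFrame,
    max_factors: int = 2,
) -> ModelComparison:
    """Build and evaluate the three risk models.

    The clinical model is the best additive combination (up to
    ``max_factors``) of dichotomized clinical covariates on the train
    side; the radiomics model likewise over the selected radiomic
    features; the combined model is the union of both factor sets.  All
    cutoffs are frozen on the train side.  With no radiomic candidates
    the radiomics score is identically zero (AUC 0.5 by convention).
    """
    y_train = outcome_train["event"].to_numpy(dtype=int)
    factor_sets = {
        "clinical": _best_factor_set(
            clinical_train, y_train, list(clinical_train.columns), max_factors
        ),
        "radiomics": _best_factor_set(
            radiomic_train, y_train, list(radiomic_train.columns), max_factors
        ),
    }
    factor_sets["combined"] = factor_sets["clinical"] + factor_sets["radiomics"]

    audit = []
    score_cutoffs = {}
    results: dict[str, dict[str, ModelSideResult]] = {}
    sides = {
        "train": (radiomic_train, clinical_train, outcome_train),
        "test": (radiomic_test, clinical_test, outcome_test),
    }
    for name, factors in factor_sets.items():
        features_train = pd.concat([radiomic_train, clinical_train], axis=1)
        score_train = _score(factors, features_train)
        if np.ptp(score_train) == 0:
            cut = 0.0
        else:
            cut, _, _ = youden_cutoff(score_train, y_train, "high")
        score_cutoffs[name] = float(cut)
        audit.append(
            f"model {name}: factors "
            + (", ".join(f"{f.variable} ({f.orientation} vs {f.cutoff:.4g})"
                         for f in factors) or "none")
            + f"; score cutoff {cut:.4g} (train-side frozen)"
        )
        results[name] = {}
        for side, (rad, clin, outcome) in sides.items():
            features = pd.concat([rad, clin], axis=1)
            results[name][side] = _side_result(factors, cut, features, outcome)
    return ModelComparison(results, factor_sets, score_cutoffs, audit)


# ---------------------------------------------------------------------------
# optional cross-check: logistic odds ratios


def logistic_or_report(
    covariates: pd.DataFrame, labels: np.ndarray, max_iter: int = 50
) -> pd.DataFrame:
    """Multivariate logistic regression odds ratios (Newton/IRLS with Wald
    p-values) as a cross-check on the Cox hazard ratios."""
    x = np.column_stack([np.ones(len(covariates)),
                         covariates.to_numpy(dtype=float)])
    y = np.asarray(labels, dtype=float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = x.T @ (y - mu)
        hess = (x * w[:, None]).T @ x + 1e-10 * np.eye(x.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv((x * w[:, None]).T @ x + 1e-10 * np.eye(x.shape[1]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"odds_ratio": np.exp(beta[1:]), "p": p[1:]},
        index=list(covariates.columns),
    )
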