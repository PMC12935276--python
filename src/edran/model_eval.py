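"""Repeated cross-validated model comparison across Rényi orders.

The protocol: for each α, a Random-Forest match-winner classifier on the ten
ΔH_α(t_i) features is evaluated with 50 repeats of 5-fold cross-validation
(shuffle seed = repetition index 1..50, model seed fixed at 42), with a
fold-internal accuracy-scored grid search, giving 250 held-out evaluations
per model. Metric distributions (accuracy, precision, recall, F1, MCC) are
summarized as mean ± sd with a 95% normal CI, and each α is compared against
the Shannon (α → 1) baseline on MCC with Welch's t, Hedges' g, and
Bonferroni / Holm–Bonferroni corrected p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_score, recall_score, f1_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .core import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "recall", "f1", "mcc")

#: Full hyperparameter grid of the evaluation protocol.
FULL_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 200],
    "max_depth": [None, 10, 20, 30],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "bootstrap": [True, False],
}

#: Desk-scale grid used by default in tests and simulations.
REDUCED_GRID: dict[str, list] = {
    "n_estimators": [100],
    "max_depth": [None, 10],
}

GRIDS = {"full": FULL_GRID, "reduced": REDUCED_GRID}


@dataclass(frozen=True)
class CVProtocol:
    """Repeated k-fold evaluation protocol.

    ``n_repeats`` x ``n_folds`` held-out evaluations; the shuffle seed of
    repetition r is r itself (1-based), the model seed is fixed. Outer folds
    are plain shuffled k-fold by default; stratification is opt-in.
    """

    n_repeats: int = 50
    n_folds: int = 5
    model_seed: int = 42
    inner_cv_folds: int = 5
    stratified: bool = False
    scoring: str = "accuracy"

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ValueError("need n_repeats >= 1 and n_folds >= 2")


def evaluation_fold_count(protocol: CVProtocol) -> int:
    """Number of held-out evaluations the protocol produces per model."""
    return protocol.n_repeats * protocol.n_folds


def mcc(confusion: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table
    ``[[TN, FP], [FN, TP]]``; a zero denominator yields 0 by convention."""
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ValueError(f"confusion table must be 2x2, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("confusion counts must be non-negative")
    tn, fp = c[0]
    fn, tp = c[1]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("MCC denominator zero; returning 0 by convention")
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


@dataclass
class EvaluationResult:
    """Per-fold metric rows (and feature importances) of one repeated-CV run."""

    metrics: pd.DataFrame  # columns: repeat, fold, accuracy, precision, recall, f1, mcc
    importances: pd.DataFrame  # columns: repeat, fold, dH_t1..dH_t10
    protocol: CVProtocol
    grid_mode: str
    n_skipped_folds: int = 0
    best_params: list[dict] = field(default_factory=list)


def repeated_cv_evaluate(
    features: pd.DataFrame,
    protocol: CVProtocol | None = None,
    grid_mode: str = "reduced",
    capture_importance: bool = True,
    n_jobs: int | None = None,
) -> EvaluationResult:
    """Run the repeated-CV Random-Forest evaluation on a ΔH feature table.

    Each repetition shuffles and splits the matches; each outer training set
    is grid-searched internally (accuracy), the best model refit (seed 42)
    and scored on the held-out fold with all five metrics. Deterministic for
    fixed data and protocol. A training fold containing a single class is
    skipped with a warning and counted in ``n_skipped_folds``.
    """
    protocol = protocol or CVProtocol()
    if grid_mode not in GRIDS:
        raise ValueError(f"grid_mode must be one of {sorted(GRIDS)}, got {grid_mode!r}")
    feat_cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if not feat_cols:
        raise ValueError("feature table has no dH_t* columns")
    if "result" not in features.columns:
        raise ValueError("feature table must contain a 'result' column")
    X = features[feat_cols].to_numpy(dtype=float)
    y = features["result"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")

    rows, imp_rows, best_params = [], [], []
    n_skipped = 0
    for rep in range(1, protocol.n_repeats + 1):
        splitter_cls = StratifiedKFold if protocol.stratified else KFold
        kf = splitter_cls(n_splits=protocol.n_folds, shuffle=True, random_state=rep)
        for fold, (tr, te) in enumerate(kf.split(X, y), start=1):
            if np.unique(y[tr]).size < 2:
                logger.warning("repeat %d fold %d: single-class training fold skipped", rep, fold)
                n_skipped += 1
                continue
            search = GridSearchCV(
                RandomForestClassifier(random_state=protocol.model_seed),
                GRIDS[grid_mode],
                scoring=protocol.scoring,
                cv=protocol.inner_cv_folds,
                n_jobs=n_jobs,
            )
            search.fit(X[tr], y[tr])
            y_hat = search.predict(X[te])
            conf = confusion_matrix(y[te], y_hat, labels=[0, 1])
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": float(np.mean(y_hat == y[te])),
                    "precision": precision_score(y[te], y_hat, zero_division=0),
                    "recall": recall_score(y[te], y_hat, zero_division=0),
                    "f1": f1_score(y[te], y_hat, zero_division=0),
                    "mcc": mcc(conf),
                }
            )
            best_params.append(dict(search.best_params_))
            if capture_importance:
                imp = {"repeat": rep, "fold": fold}
                imp.update(dict(zip(feat_cols, search.best_estimator_.feature_importances_)))
                imp_rows.append(imp)
    return EvaluationResult(
        metrics=pd.DataFrame(rows),
        importances=pd.DataFrame(imp_rows),
        protocol=protocol,
        grid_mode=grid_mode,
        n_skipped_folds=n_skipped,
        best_params=best_params,
    )


# ---------------------------------------------------------------------------
# Summaries and comparisons
# ---------------------------------------------------------------------------


def normal_ci(mean: float, sd: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """95% normal confidence interval ``mean ± z·sd/sqrt(n)``."""
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half


def summarize(dist: EvaluationResult | pd.DataFrame) -> pd.DataFrame:
    """Mean, sample sd, and 95% CI per metric over the evaluation folds."""
    metrics = dist.metrics if isinstance(dist, EvaluationResult) else dist
    rows = []
    for metric in METRICS:
        if metric not in metrics.columns:
            continue
        vals = np.asarray(metrics[metric], dtype=float)
        if vals.size < 2:
            raise ValueError(f"metric {metric}: need >= 2 values to summarize")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        lo, hi = normal_ci(mean, sd, vals.size)
        rows.append(
            {"metric": metric, "mean": mean, "sd": sd, "ci_low": lo, "ci_high": hi, "n": vals.size}
        )
    return pd.DataFrame(rows).set_index("metric")


@dataclass(frozen=True)
class WelchComparison:
    mean_diff: float
    t: float
    df: float
    p_value: float
    hedges_g: float


def welch_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchComparison:
    """Two-sided Welch t-test of ``a`` vs ``b`` plus Hedges' g.

    Welch uses unpooled variances with Satterthwaite degrees of freedom;
    Hedges' g is pooled-sd Cohen's d times the small-sample correction
    ``1 - 3/(4(n1+n2)-9)``. Signs follow ``mean(a) - mean(b)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchComparison(0.0, 0.0, float(a.size + b.size - 2), 1.0, 0.0)
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    n1, n2 = a.size, b.size
    sp = math.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    g = d * (1 - 3 / (4 * (n1 + n2) - 9))
    return WelchComparison(
        mean_diff=float(a.mean() - b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        hedges_g=float(g),
    )


def adjust_pvalues(raw: Sequence[float], method: str = "holm") -> np.ndarray:
    """Bonferroni (``min(K·p, 1)``) or Holm step-down adjusted p-values,
    returned in input order."""
    p = np.asarray(raw, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"method must be 'bonferroni' or 'holm', got {method!r}")
    return multipletests(p, method=method)[1]


def compare_to_baseline(
    metric_samples: Mapping[float, Sequence[float]],
    baseline_alpha: float = 1.0,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Welch comparisons of each α's metric sample vs the baseline.

    Returns one row per non-baseline α: ``alpha, mean_diff, t, df, p_raw,
    hedges_g, p_bonf, p_holm, significant_holm`` (family-wise level
    ``alpha_level`` after Holm adjustment).
    """
    if baseline_alpha not in metric_samples:
        raise ValueError(f"baseline alpha {baseline_alpha} not among samples")
    base = metric_samples[baseline_alpha]
    rows = []
    for a, sample in metric_samples.items():
        if a == baseline_alpha:
            continue
        cmp = welch_compare(sample, base)
        rows.append(
            {
                "alpha": a,
                "mean_diff": cmp.mean_diff,
                "t": cmp.t,
                "df": cmp.df,
                "p_raw": cmp.p_value,
                "hedges_g": cmp.hedges_g,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonf"] = adjust_pvalues(out["p_raw"], "bonferroni")
    out["p_holm"] = adjust_pvalues(out["p_raw"], "holm")
    out["significant_holm"] = out["p_holm"] < alpha_level
    return out


def feature_importance_summary(result: EvaluationResult) -> pd.DataFrame:
    """Mean and sd of impurity-based feature importance over all fitted
    models (each model's importances sum to 1)."""
    cols = [c for c in FEATURE_COLUMNS if c in result.importances.columns]
    if not cols:
        raise ValueError("no importances captured; rerun with capture_importance=True")
    imp = result.importances[cols]
    return pd.DataFrame({"mean": imp.mean(), "sd": imp.std(ddof=1)}).rename_axis("feature")
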