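"""Cohort-level statistics and model-agnostic importance ranking.

``compare_groups`` mirrors a classic biomarker table: per marker, the group
means, SDs, a two-sided Welch t test and a Wilcoxon rank-sum test, plus a
Benjamini-Hochberg column for honest multiple-testing reporting.

``rank_importance`` fits a pluggable classification backend on the marker
matrix and returns a global feature-importance ranking; backends share one
contract (``fit(X, y)`` then ``global_importance()``) so the harness never
depends on a particular attribution algorithm's internals.  Available
backends:

- ``tree_shap``: XGBoost with its native exact TreeSHAP attribution
  (mean absolute contribution per feature).
- ``additive_boosting``: a boosted generalised additive model
  (gradient-boosted trees constrained to single-feature splits) scored by
  seeded permutation importance.
- ``attention_tabular``: attention-based tabular network; registered for
  interface completeness but reported as missing because no deep-learning
  stack is declared by this package.

``undersample_stability`` refits on repeated random undersamples of the
majority group and counts how often each marker stays in the top k — a
robustness check for class-imbalanced cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.inspection import permutation_importance
from statsmodels.stats.multitest import multipletests

from .markers import MARKER_NAMES

COVARIATE_NAMES = ("age", "sex", "bmi")


class BackendMissingError(RuntimeError):
    """Raised when a named importance backend is not available."""


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRow:
    marker: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    p_t: float
    p_w: float
    n_case: int
    n_control: int


def compare_groups(
    table: pd.DataFrame,
    markers: tuple[str, ...] = MARKER_NAMES,
    pooled_variance: bool = False,
) -> pd.DataFrame:
    """Per-marker two-sample comparison between case and control groups.

    Missing values are dropped marker-wise.  The t test defaults to the
    Welch (unequal-variance) form; ``pooled_variance=True`` selects the
    classic pooled form.  A BH-adjusted column ``p_t_bh`` is appended; the
    raw p-values remain the primary report.
    """
    if not {"group"}.issubset(table.columns):
        raise ValueError("table must have a 'group' column")
    rows = []
    for marker in markers:
        case = table.loc[table["group"] == "case", marker].dropna().to_numpy(float)
        control = table.loc[table["group"] == "control", marker].dropna().to_numpy(float)
        if len(case) < 2 or len(control) < 2:
            p_t = p_w = np.nan
        else:
            p_t = stats.ttest_ind(case, control, equal_var=pooled_variance).pvalue
            p_w = stats.ranksums(case, control).pvalue
        rows.append(
            ComparisonRow(
                marker=marker,
                case_mean=case.mean() if len(case) else np.nan,
                case_sd=case.std(ddof=1) if len(case) > 1 else np.nan,
                control_mean=control.mean() if len(control) else np.nan,
                control_sd=control.std(ddof=1) if len(control) > 1 else np.nan,
                p_t=p_t,
                p_w=p_w,
                n_case=len(case),
                n_control=len(control),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    valid = df["p_t"].notna()
    df["p_t_bh"] = np.nan
    if valid.any():
        df.loc[valid, "p_t_bh"] = multipletests(df.loc[valid, "p_t"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# importance backends
# ---------------------------------------------------------------------------


class TreeShapBackend:
    """XGBoost classifier attributed with its built-in exact TreeSHAP."""

    name = "tree_shap"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._booster = None
        self._n_features = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeShapBackend":
        import xgboost as xgb

        self._n_features = X.shape[1]
        self._dtrain = xgb.DMatrix(np.asarray(X, float), label=np.asarray(y, int))
        params = {
            "booster": "gbtree",
            "objective": "binary:logistic",
            "seed": self.seed,
            "nthread": 1,
        }
        self._booster = xgb.train(params, self._dtrain, num_boost_round=100)
        return self

    def global_importance(self) -> np.ndarray:
        contribs = self._booster.predict(self._dtrain, pred_contribs=True)
        return np.abs(contribs[:, : self._n_features]).mean(axis=0)


class AdditiveBoostingBackend:
    """Boosted GAM: gradient-boosted trees restricted to one feature per tree.

    Global importance is seeded permutation importance of the fitted
    additive model on the training matrix.
    """

    name = "additive_boosting"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._model = None
        self._X = None
        self._y = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdditiveBoostingBackend":
        X = np.asarray(X, float)
        self._model = HistGradientBoostingClassifier(
            interaction_cst=[{i} for i in range(X.shape[1])],
            random_state=self.seed,
            max_iter=200,
        )
        self._model.fit(X, y)
        self._X, self._y = X, np.asarray(y)
        return self

    def global_importance(self) -> np.ndarray:
        result = permutation_importance(
            self._model,
            self._X,
            self._y,
            n_repeats=10,
            random_state=self.seed,
            scoring="neg_log_loss",
        )
        return np.maximum(result.importances_mean, 0.0)


class AttentionTabularBackend:
    """Placeholder for an attention-based tabular network backend."""

    name = "attention_tabular"

    def __init__(self, seed: int = 0):
        raise BackendMissingError(
            "backend missing: 'attention_tabular' requires a deep-learning "
            "stack that circamark does not declare; use 'tree_shap' or "
            "'additive_boosting'"
        )


BACKENDS = {
    "tree_shap": TreeShapBackend,
    "additive_boosting": AdditiveBoostingBackend,
    "attention_tabular": AttentionTabularBackend,
}

#: backends whose model is an ensemble of decision trees
TREE_BACKENDS = ("tree_shap", "additive_boosting")


def make_backend(backend: str, seed: int = 0):
    if backend not in BACKENDS:
        raise BackendMissingError(f"backend missing: unknown backend {backend!r}")
    return BACKENDS[backend](seed=seed)


# ---------------------------------------------------------------------------
# importance harness
# ---------------------------------------------------------------------------


@dataclass
class ImportanceReport:
    backend: str
    features: list[str]
    scores: np.ndarray  # per-feature global importance, full-data fit
    ranking: list[str]  # features ordered by decreasing importance
    repeats: list[list[str]] = field(default_factory=list)  # rankings per undersample
    topk_frequency: dict[str, int] = field(default_factory=dict)
    top_k: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.features, "importance": self.scores})
        df = df.sort_values("importance", ascending=False).reset_index(drop=True)
        if self.topk_frequency:
            df[f"top{self.top_k}_frequency"] = df["feature"].map(self.topk_frequency)
        return df


def _feature_matrix(
    table: pd.DataFrame, include_covariates: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    features = [m for m in MARKER_NAMES if m in table.columns]
    if include_covariates:
        features += [c for c in COVARIATE_NAMES if c in table.columns]
    X = table[features].copy()
    if "sex" in X.columns:
        X["sex"] = (X["sex"].astype(str) == "M").astype(float)
    # median-fill residual missing values for model fitting (complete-case
    # statistics are handled separately in compare_groups)
    X = X.astype(float).fillna(X.astype(float).median())
    y = (table["group"] == "case").to_numpy(int)
    return X.to_numpy(), y, features


def rank_importance(
    table: pd.DataFrame,
    backend: str = "tree_shap",
    include_covariates: bool = False,
    seed: int = 0,
) -> ImportanceReport:
    """Global importance ranking of the marker panel for the group label."""
    X, y, features = _feature_matrix(table, include_covariates)
    model = make_backend(backend, seed=seed)
    model.fit(X, y)
    scores = np.asarray(model.global_importance(), float)
    order = np.argsort(-scores, kind="stable")
    return ImportanceReport(
        backend=backend,
        features=features,
        scores=scores,
        ranking=[features[i] for i in order],
    )


def undersample_stability(
    table: pd.DataFrame,
    backend: str = "tree_shap",
    k: int = 10,
    repeats: int = 5,
    include_covariates: bool = False,
    seed: int = 0,
) -> ImportanceReport:
    """Importance stability under repeated majority-group undersampling.

    Each repeat draws a without-replacement subsample of the majority group
    matching the minority size, refits the backend, and re-ranks; the report
    counts top-``k`` appearances per marker across repeats.
    """
    report = rank_importance(table, backend, include_covariates, seed)
    n_case = int((table["group"] == "case").sum())
    n_control = int((table["group"] == "control").sum())
    minority, majority = ("case", "control") if n_case <= n_control else ("control", "case")
    n_minority = min(n_case, n_control)
    balanced = n_case == n_control

    rng = np.random.default_rng(seed)
    repeat_rankings: list[list[str]] = []
    topk: dict[str, int] = {f: 0 for f in report.features}
    for rep in range(repeats):
        maj_rows = table.index[table["group"] == majority]
        keep = rng.choice(maj_rows, size=n_minority, replace=False)
        sub = table.loc[table.index.isin(keep) | (table["group"] == minority)]
        sub_report = rank_importance(
            sub, backend, include_covariates, seed=seed + 1 + rep
        )
        repeat_rankings.append(sub_report.ranking)
        for f in sub_report.ranking[:k]:
            topk[f] += 1
    report.repeats = repeat_rankings
    report.topk_frequency = topk
    report.top_k = k
    if balanced:
        import warnings

        warnings.warn("groups already balanced: repeats differ only by model seed")
    return report
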