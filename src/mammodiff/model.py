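"""Boosted-tree classification of hardest vs easiest cases, with LOOCV.

The classifier is an additive logistic model fitted stagewise (LogitBoost):
at each round, Newton working responses and weights are computed from the
current class probabilities, a depth-limited regression tree is fitted to
the weighted working response, and the additive score is updated with
shrinkage. Evaluation is leave-one-out cross-validation, with the z-score
normalisation refitted inside every fold from the training cases only so
no information leaks from the held-out case. Model quality is summarised
by the Mann-Whitney AUC with a DeLong 95% confidence interval; feature
usefulness by split-gain importance with a scree (maximum-consecutive-drop)
selection, and by per-feature Kruskal-Wallis screening at alpha = 0.05.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .radiomics import zscore_table

logger = logging.getLogger(__name__)

_Z_CLIP = 4.0  # standard LogitBoost working-response clamp
_P_CLIP = 1e-10


@dataclass(frozen=True)
class BoostConfig:
    """LogitBoost hyperparameters.

    Defaults: 100 rounds of depth-1 trees (stumps) with shrinkage 0.1 and
    70% case subsampling per round (stochastic boosting). Stumps with
    subsampling spread split-gain importance across features of similar
    strength, where deeper deterministic trees let whichever feature is
    marginally stronger in-sample absorb nearly all of it.
    """

    n_rounds: int = 100
    learning_rate: float = 0.1
    max_tree_depth: int = 1
    subsample: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_tree_depth < 1:
            raise ValueError("max_tree_depth must be >= 1")
        if not 0.0 < self.subsample <= 1.0:
            raise ValueError("subsample must be in (0, 1]")


@dataclass
class BoostedEnsemble:
    """A fitted stagewise additive logistic model."""

    trees: list[DecisionTreeRegressor]
    config: BoostConfig
    feature_names: list[str]
    prior_score: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        f = np.full(X.shape[0], self.prior_score)
        for tree in self.trees:
            f += 0.5 * self.config.learning_rate * tree.predict(X, check_input=False)
        return f

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(class 1) via the logistic link p = 1 / (1 + exp(-2F))."""
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))


def fit_boosted_ensemble(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: BoostConfig = BoostConfig(),
) -> BoostedEnsemble:
    """Fit LogitBoost with depth-limited regression trees as base learners.

    Per round, with p the current probability of class 1:
    weights w = p(1-p), working response z = (y - p)/w (clamped), a tree is
    fitted to (X, z) with sample weights w, and the additive score gets
    F += 0.5 * learning_rate * tree(X).
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if np.isnan(Xa).any():
        raise ValueError("X contains missing values")

    rng = np.random.default_rng(cfg.seed)
    # trees store X as float32 internally; pre-casting lets fit/predict
    # skip their per-call validation without changing the fitted model
    X32 = np.ascontiguousarray(Xa, dtype=np.float32)
    f = np.zeros(len(y))
    trees: list[DecisionTreeRegressor] = []
    for _ in range(cfg.n_rounds):
        p = 1.0 / (1.0 + np.exp(-2.0 * f))
        p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
        w = p * (1.0 - p)
        z = np.clip((y - p) / w, -_Z_CLIP, _Z_CLIP)
        if cfg.subsample < 1.0:
            # stochastic boosting: each round fits on a random case subset,
            # which decorrelates round-to-round split choices
            keep = rng.random(len(y)) < cfg.subsample
            if keep.sum() < 2 or np.unique(y[keep]).size < 2:
                keep = np.ones(len(y), dtype=bool)
            w = np.where(keep, w, 0.0)
        tree = DecisionTreeRegressor(
            max_depth=cfg.max_tree_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X32, z, sample_weight=w, check_input=False)
        trees.append(tree)
        f += 0.5 * cfg.learning_rate * tree.predict(X32, check_input=False)
    return BoostedEnsemble(trees=trees, config=cfg, feature_names=feature_names)


def feature_importance(model: BoostedEnsemble, normalize: bool = True) -> pd.Series:
    """Split-gain importance: summed weighted squared-error risk reduction.

    For every split in every tree, the reduction in weighted node impurity
    (parent minus children) is credited to the split feature; totals are
    normalised to sum 1. Features never split score 0. If no split was ever
    made (constant X) the all-zero scores are returned unnormalised with a
    warning.
    """
    totals = np.zeros(len(model.feature_names))
    for tree in model.trees:
        t = tree.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            gain = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            totals[t.feature[node]] += max(gain, 0.0)
    if normalize:
        total = totals.sum()
        if total == 0:
            logger.warning("no splits made; returning unnormalised zero importances")
        else:
            totals = totals / total
    return pd.Series(totals, index=model.feature_names)


def loocv_predict(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: BoostConfig = BoostConfig(),
    normalize_in_fold: bool = True,
) -> np.ndarray:
    """Leave-one-out probabilities: one fit per case, excluding that case.

    With ``normalize_in_fold`` (default) the z-score transform is refitted
    on each fold's training cases and applied to the held-out case,
    avoiding leakage; set False to reproduce a single global normalisation.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    probs = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        X_tr, y_tr = X.iloc[train], y[train]
        X_te = X.iloc[[i]]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i}: training labels are single-class")
        if normalize_in_fold:
            X_tr, zp = zscore_table(X_tr)
            X_te = zp.transform(X_te)
        model = fit_boosted_ensemble(X_tr, y_tr, cfg)
        probs[i] = model.predict_proba(X_te.to_numpy())[0]
    return probs


def auc(probabilities, labels) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    pos, neg = p[y == 1], p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the Mann-Whitney AUC (structural components)."""
    m, n = pos.size, neg.size
    # V10[i] = P(pos_i > neg) with ties 1/2; V01[j] likewise per negative
    cmp_ = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(probabilities, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, truncated to [0, 1].

    Degenerate variance (e.g. perfect separation) collapses the interval to
    the point estimate with a warning.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    a = auc(p, y)
    var = _delong_variance(p[y == 1], p[y == 0])
    if var <= 0:
        logger.warning("degenerate AUC variance: interval collapses to the point estimate")
        return a, a
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def scree_select(importance: pd.Series) -> list[str]:
    """Elbow selection on descending importance scores.

    Scores are sorted descending; the elbow is the largest consecutive drop
    (first occurrence on ties) and every feature strictly before the
    elbow's lower side is selected. All-zero importances select nothing
    (with a warning).
    """
    if len(importance) < 3:
        raise ValueError("scree selection needs >= 3 features")
    if (importance <= 0).all():
        logger.warning("all importances zero: empty scree selection")
        return []
    ranked = importance.sort_values(ascending=False, kind="stable")
    drops = -np.diff(ranked.to_numpy())
    elbow = int(np.argmax(drops))  # first occurrence of the maximum drop
    return list(ranked.index[: elbow + 1])


def kruskal_wallis_per_feature(
    X: pd.DataFrame,
    labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group Kruskal-Wallis per feature, no multiplicity adjustment.

    Returns a frame indexed by feature with columns H, p, significant
    (p < alpha) and, for transparency, significant_bonferroni. A feature
    constant across all cases yields H = 0, p = 1.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be nonempty")
    rows = []
    m = len(X.columns)
    for name in X.columns:
        v = X[name].to_numpy(dtype=np.float64)
        if np.unique(v).size == 1:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(v[y == 1], v[y == 0])
        rows.append((name, float(h), float(p), p < alpha, p < alpha / m))
    return pd.DataFrame(
        rows, columns=["feature", "H", "p", "significant", "significant_bonferroni"]
    ).set_index("feature")


@dataclass
class ModelReport:
    """Everything the modelling stage reports for one dataset."""

    per_case_probability: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    importance: pd.Series
    selected_features: list[str]
    kw_table: pd.DataFrame
    config: BoostConfig = field(default_factory=BoostConfig)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_cases": int(len(self.per_case_probability)),
            "per_case_probability": {
                str(k): float(v) for k, v in self.per_case_probability.items()
            },
            "importance": {str(k): float(v) for k, v in self.importance.items()},
            "selected_features": list(self.selected_features),
            "kw": {
                str(k): {
                    "H": float(r["H"]),
                    "p": float(r["p"]),
                    "significant": bool(r["significant"]),
                    "significant_bonferroni": bool(r["significant_bonferroni"]),
                }
                for k, r in self.kw_table.iterrows()
            },
            "n_significant": int(self.kw_table["significant"].sum()),
            "config": {
                "n_rounds": self.config.n_rounds,
                "learning_rate": self.config.learning_rate,
                "max_tree_depth": self.config.max_tree_depth,
                "seed": self.config.seed,
                "ci_method": "delong",
            },
        }


def evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: BoostConfig = BoostConfig(),
    normalize_in_fold: bool = True,
) -> ModelReport:
    """Full modelling stage: LOOCV probabilities, AUC + CI, importance,
    scree selection, and per-feature Kruskal-Wallis screening."""
    y = np.asarray(y, dtype=np.float64)
    probs = loocv_predict(X, y, cfg, normalize_in_fold=normalize_in_fold)
    a = auc(probs, y)
    ci = auc_ci(probs, y)
    Xn, _ = zscore_table(X)
    full_model = fit_boosted_ensemble(Xn, y, cfg)
    imp = feature_importance(full_model)
    selected = scree_select(imp)
    kw = kruskal_wallis_per_feature(X, y)
    return ModelReport(
        per_case_probability=pd.Series(probs, index=X.index),
        auc=a,
        auc_ci=ci,
        importance=imp,
        selected_features=selected,
        kw_table=kw,
        config=cfg,
    )
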