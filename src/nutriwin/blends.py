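"""Nutrient-blend regression: which nutrient combinations predict MWF.

The cohort (per detected window, or across all ages) is split 75/25 into
train and test.  On the training rows an elastic net and/or a random
forest are fit with 10-fold cross-validation (penalty and mixing chosen on
a grid with a one-standard-error rule for the elastic net; features per
split tuned for the forest).  Predictors and outcome are z-scored on
training statistics, so reported RMSE is in SD units of the outcome.
Held-out predictions are scored by Spearman correlation (Fisher-z 95% CI)
and RMSE.  For across-age runs a shadow-feature (Boruta-style) selector
confirms nutrients whose forest importance beats permuted copies of
themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import GridSearchCV, KFold

from .cohort import CohortTable
from .detect import AgeWindow

AGE_COLUMN = "age_months"

NUTRIENT_SETS = ("untargeted_63", "micronutrients", "lipids", "amino_acids",
                 "fatty_acids", "window_preselected")
_SET_CATEGORIES = {
    "micronutrients": ("mineral", "vitamin"),
    "lipids": ("polar_lipid",),
    "amino_acids": ("amino_acid",),
    "fatty_acids": ("fatty_acid",),
}


# --------------------------------------------------------------------------
# train/test split

def split_train_test(table: CohortTable, test_fraction: float = 0.25,
                     seed: int = 0) -> tuple[CohortTable, CohortTable]:
    """Seeded uniform split without replacement; train size is
    round(N * (1 - test_fraction)), test gets the remainder."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    n = table.n
    if n < 8:
        raise ValueError(f"need at least 8 children to split, got {n}")
    n_train = int(round(n * (1 - test_fraction)))
    n_test = n - n_train
    if min(n_train, n_test) < 4:
        raise ValueError(
            f"degenerate split sizes train={n_train}, test={n_test}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return (CohortTable(table.data.iloc[train_idx], table.dictionary),
            CohortTable(table.data.iloc[test_idx], table.dictionary))


# --------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvalResult:
    rho: float
    ci_low: float
    ci_high: float
    rmse: float
    n: int


def spearman_fisher_ci(rho: float, n: int,
                       level: float = 0.95) -> tuple[float, float]:
    """Fisher-z interval tanh(atanh(rho) +/- z * 1/sqrt(n-3))."""
    if n < 4:
        raise ValueError(f"need n >= 4 for a Fisher-z interval, got {n}")
    z = stats.norm.ppf(0.5 + level / 2)
    center = np.arctanh(rho)
    half = z / np.sqrt(n - 3)
    return float(np.tanh(center - half)), float(np.tanh(center + half))


def evaluate_predictions(predicted, observed) -> EvalResult:
    """Spearman rho (average ranks on ties) with Fisher-z 95% CI, and RMSE
    of (predicted - observed).  Both vectors should already be on the
    standardized outcome scale when SD-unit RMSE is wanted."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    n = len(predicted)
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(predicted, observed).statistic)
    lo, hi = spearman_fisher_ci(rho, n)
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    return EvalResult(rho=rho, ci_low=lo, ci_high=hi, rmse=rmse, n=n)


# --------------------------------------------------------------------------
# estimators

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class BlendRegressor(BaseEstimator, RegressorMixin):
    """Elastic-net or random-forest regression with CV-tuned settings.

    Predictors and outcome are z-scored on the training statistics inside
    ``fit``; ``predict`` returns values on the original outcome scale and
    ``predict_standardized`` on the z-scale (the scale on which RMSE is
    reported).

    Parameters
    ----------
    model : 'elastic_net' or 'random_forest'
    cv_folds : folds for every internal cross-validation (default 10)
    n_trees : forest size (default 500)
    compute_importance : for the forest, compute out-of-fold permutation
        importance (skippable to save time when only predictions matter)
    """

    def __init__(self, model: str = "random_forest", cv_folds: int = 10,
                 n_trees: int = 500, l1_ratios=(0.1, 0.2, 0.3, 0.4, 0.5,
                                                0.6, 0.7, 0.8, 0.9, 1.0),
                 n_alphas: int = 50,
                 max_features_grid=(0.3333333333333333, "sqrt", 1.0),
                 compute_importance: bool = True, seed: int = 0):
        self.model = model
        self.cv_folds = cv_folds
        self.n_trees = n_trees
        self.l1_ratios = l1_ratios
        self.n_alphas = n_alphas
        self.max_features_grid = max_features_grid
        self.compute_importance = compute_importance
        self.seed = seed

    def fit(self, X, y) -> "BlendRegressor":
        if self.model not in ("elastic_net", "random_forest"):
            raise ValueError(
                f"model must be 'elastic_net' or 'random_forest', got "
                f"{self.model!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        Xf = _as_frame(X)
        y = np.asarray(y, float)
        if np.ptp(y) == 0:
            raise ValueError("outcome is constant; nothing to fit")
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        Xv = Xf.to_numpy(float)
        self.x_mean_ = Xv.mean(axis=0)
        sd = Xv.std(axis=0, ddof=0)
        self.x_sd_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=0))
        Xz = (Xv - self.x_mean_) / self.x_sd_
        yz = (y - self.y_mean_) / self.y_sd_
        cv = KFold(n_splits=min(self.cv_folds, len(y)), shuffle=True,
                   random_state=self.seed)
        if self.model == "elastic_net":
            self._fit_enet(Xz, yz, cv)
        else:
            self._fit_forest(Xz, yz, cv)
        self.importances_ = pd.Series(
            self.importance_values_, index=self.feature_names_in_
        ).sort_values(ascending=False)
        return self

    def _fit_enet(self, Xz, yz, cv) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search = ElasticNetCV(l1_ratio=list(self.l1_ratios),
                                  alphas=self.n_alphas, cv=cv,
                                  random_state=self.seed, max_iter=5000)
            search.fit(Xz, yz)
            # one-standard-error rule on the penalty, at the CV-best mixing
            ratios = np.atleast_1d(search.l1_ratio)
            mse = search.mse_path_      # (n_l1, n_alphas, n_folds)
            if mse.ndim == 2:
                mse = mse[None, ...]
            mean = mse.mean(axis=-1)
            se = mse.std(axis=-1, ddof=1) / np.sqrt(mse.shape[-1])
            li, ai = np.unravel_index(np.argmin(mean), mean.shape)
            limit = mean[li, ai] + se[li, ai]
            alphas = np.atleast_2d(search.alphas_)[li if search.alphas_.ndim > 1
                                                   else 0]
            ok = np.where(mean[li] <= limit)[0]
            # alphas are stored descending: the smallest index is the
            # largest (sparsest) penalty within one SE
            ai_1se = int(ok[0]) if len(ok) else int(ai)
            self.alpha_ = float(alphas[ai_1se])
            self.l1_ratio_ = float(ratios[li] if len(ratios) > 1
                                   else search.l1_ratio_)
            self.model_ = ElasticNet(alpha=self.alpha_,
                                     l1_ratio=self.l1_ratio_,
                                     max_iter=10000)
            self.model_.fit(Xz, yz)
        self.importance_values_ = np.abs(self.model_.coef_)

    def _fit_forest(self, Xz, yz, cv) -> None:
        base = RandomForestRegressor(n_estimators=self.n_trees,
                                     random_state=self.seed, n_jobs=1)
        grid = GridSearchCV(base,
                            {"max_features": list(self.max_features_grid)},
                            cv=cv, scoring="neg_mean_squared_error")
        grid.fit(Xz, yz)
        self.max_features_ = grid.best_params_["max_features"]
        self.model_ = grid.best_estimator_
        if self.compute_importance:
            self.importance_values_ = self._oof_permutation_importance(Xz, yz, cv)
        else:
            self.importance_values_ = np.asarray(
                self.model_.feature_importances_)

    def _oof_permutation_importance(self, Xz, yz, cv) -> np.ndarray:
        """Permutation importance measured on held-out folds only."""
        total = np.zeros(Xz.shape[1])
        count = 0
        for train_idx, test_idx in cv.split(Xz):
            if np.ptp(yz[train_idx]) == 0:
                warnings.warn("skipping CV fold with constant outcome")
                continue
            rf = RandomForestRegressor(n_estimators=self.n_trees,
                                       max_features=self.max_features_,
                                       random_state=self.seed, n_jobs=1)
            rf.fit(Xz[train_idx], yz[train_idx])
            r = permutation_importance(rf, Xz[test_idx], yz[test_idx],
                                       n_repeats=5, random_state=self.seed)
            total += r.importances_mean
            count += 1
        if count == 0:
            raise ValueError("all CV folds skipped (constant outcome)")
        return total / count

    def _transform_X(self, X) -> np.ndarray:
        Xf = _as_frame(X)
        if list(Xf.columns) != list(self.feature_names_in_):
            Xf = Xf[list(self.feature_names_in_)]
        return (Xf.to_numpy(float) - self.x_mean_) / self.x_sd_

    def predict_standardized(self, X) -> np.ndarray:
        return self.model_.predict(self._transform_X(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_standardized(X) * self.y_sd_ + self.y_mean_


class ShadowFeatureSelector(SelectorMixin, BaseEstimator):
    """Shadow-feature (Boruta-style) confirmation of forest predictors.

    Every candidate is duplicated with its values permuted; a forest is fit
    on real plus shadow columns and a candidate scores a hit when its
    importance exceeds the maximum shadow importance.  Over ``n_rounds``
    re-permutations a candidate is confirmed (rejected) when its hit count
    is significantly above (below) half by a binomial test at ``alpha``;
    rejected candidates are dropped and the procedure repeats until stable
    or ``max_iter`` iterations.  ``get_support()`` marks confirmed features.
    """

    def __init__(self, n_rounds: int = 20, alpha: float = 0.05,
                 max_iter: int = 10, n_trees: int = 100, seed: int = 0):
        self.n_rounds = n_rounds
        self.alpha = alpha
        self.max_iter = max_iter
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y) -> "ShadowFeatureSelector":
        Xf = _as_frame(X)
        y = np.asarray(y, float)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        rng = np.random.default_rng(self.seed)
        Xv = Xf.to_numpy(float)
        n, p = Xv.shape

        candidates = list(range(p))
        confirmed: set[int] = set()
        mean_importance = np.zeros(p)
        for _ in range(self.max_iter):
            if not candidates:
                break
            hits = np.zeros(len(candidates))
            imp_sum = np.zeros(len(candidates))
            sub = Xv[:, candidates]
            # keep at least 5 shadow columns so the max-shadow null stays
            # strict even when few candidates remain
            reps = max(1, int(np.ceil(5 / sub.shape[1])))
            shadow_base = np.tile(sub, (1, reps))
            for _round in range(self.n_rounds):
                shadow = rng.permuted(shadow_base, axis=0)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees, random_state=int(
                        rng.integers(0, 2**31 - 1)), n_jobs=1)
                rf.fit(np.hstack([sub, shadow]), y)
                imp = rf.feature_importances_
                real, sh = imp[:len(candidates)], imp[len(candidates):]
                hits += real > sh.max()
                imp_sum += real
            keep: list[int] = []
            changed = False
            for k, j in enumerate(candidates):
                mean_importance[j] = imp_sum[k] / self.n_rounds
                p_hi = stats.binomtest(int(hits[k]), self.n_rounds, 0.5,
                                       alternative="greater").pvalue
                p_lo = stats.binomtest(int(hits[k]), self.n_rounds, 0.5,
                                       alternative="less").pvalue
                if p_hi < self.alpha:
                    confirmed.add(j)
                    keep.append(j)
                elif p_lo < self.alpha:
                    changed = True  # rejected: drop
                else:
                    keep.append(j)
            if not changed:
                break
            candidates = keep
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[sorted(confirmed)] = True
        self.importances_ = pd.Series(mean_importance,
                                      index=self.feature_names_in_)
        if not confirmed:
            warnings.warn("shadow selection confirmed no features")
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    @property
    def selected_names_(self) -> list[str]:
        return [str(n) for n, s in zip(self.feature_names_in_, self.support_)
                if s]


# --------------------------------------------------------------------------
# orchestration

@dataclass(frozen=True)
class BlendConfig:
    test_fraction: float = 0.25
    cv_folds: int = 10
    model: str = "both"              # elastic_net | random_forest | both
    scope: str = "across_ages"       # per_window | across_ages
    nutrient_set: str = "untargeted_63"
    include_age: bool | None = None  # default: True for across_ages
    use_shadow_selection: bool = True
    n_trees: int = 500
    shadow_trees: int = 100
    shadow_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.model not in ("elastic_net", "random_forest", "both"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.scope not in ("per_window", "across_ages"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.nutrient_set not in NUTRIENT_SETS:
            raise ValueError(f"unknown nutrient_set {self.nutrient_set!r}")

    @property
    def age_included(self) -> bool:
        if self.include_age is None:
            return self.scope == "across_ages"
        return bool(self.include_age)

    @property
    def models(self) -> tuple[str, ...]:
        return (("elastic_net", "random_forest") if self.model == "both"
                else (self.model,))


@dataclass
class BlendResult:
    scope: str
    nutrient_set: str
    model: str
    window: str                      # "all" or "start-end"
    selected: list = field(default_factory=list)  # ranked, age first if used
    rho: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    rmse: float = float("nan")
    n_train: int = 0
    n_test: int = 0
    note: str = ""

    def to_row(self) -> dict:
        d = asdict(self)
        d["selected"] = "; ".join(d["selected"])
        return d


def candidate_nutrients(table: CohortTable, config: BlendConfig,
                        window: AgeWindow | None = None) -> list[str]:
    if config.nutrient_set == "window_preselected":
        if window is None:
            raise ValueError(
                "window_preselected candidates need a window with selections")
        in_table = set(table.nutrients)
        return [name for name, sign, _ in window.selected_nutrients
                if sign > 0 and name in in_table]
    if config.nutrient_set == "untargeted_63":
        return [n for n in table.nutrients
                if n in set(table.dictionary.included_names)]
    cats = _SET_CATEGORIES[config.nutrient_set]
    allowed = set(table.dictionary.names_in_categories(cats))
    return [n for n in table.nutrients if n in allowed]


def _design_frame(table: CohortTable, candidates: list[str],
                  with_age: bool) -> pd.DataFrame:
    cols = ([AGE_COLUMN] if with_age else []) + list(candidates)
    return table.data[cols].copy()


def fit_blend(train: CohortTable, candidates: list[str],
              config: BlendConfig, model: str,
              window: AgeWindow | None = None) -> BlendRegressor:
    """Fit one blend model on training rows only."""
    if not candidates:
        raise ValueError("candidate set is empty")
    X = _design_frame(train, candidates, config.age_included)
    reg = BlendRegressor(model=model, cv_folds=config.cv_folds,
                         n_trees=config.n_trees, seed=config.seed)
    reg.fit(X, train.mwf)
    return reg


def select_features_shadow(train: CohortTable, candidates: list[str],
                           config: BlendConfig) -> list[str]:
    """Shadow-feature selection on the training rows; returns the confirmed
    subset of ``candidates`` (age never enters the shadow pool)."""
    X = train.data[list(candidates)]
    sel = ShadowFeatureSelector(n_rounds=config.shadow_rounds,
                                n_trees=config.shadow_trees,
                                seed=config.seed)
    sel.fit(X, train.mwf)
    return sel.selected_names_


def _ranked_selection(reg: BlendRegressor, model: str) -> list[str]:
    imp = reg.importances_
    if model == "elastic_net":
        kept = imp[imp > 1e-10]
    else:
        kept = imp[imp > 0]
    names = list(kept.index)
    if AGE_COLUMN in names:  # age listed first when selected
        names.remove(AGE_COLUMN)
        names = ["Age"] + names
    return names


def run_blend_analysis(table: CohortTable,
                       windows: list[AgeWindow] | None = None,
                       config: BlendConfig | None = None) -> list[BlendResult]:
    """Split -> (optional shadow selection) -> fit -> held-out evaluation
    for each requested scope/model, emitting report-shaped rows."""
    config = config or BlendConfig()
    results: list[BlendResult] = []

    def one(scope_table: CohortTable, window: AgeWindow | None,
            label: str) -> None:
        try:
            candidates = candidate_nutrients(scope_table, config, window)
        except ValueError:
            candidates = []
        if not candidates:
            for model in config.models:
                results.append(BlendResult(
                    scope=config.scope, nutrient_set=config.nutrient_set,
                    model=model, window=label,
                    note="no combination identified"))
            return
        train, test = split_train_test(scope_table, config.test_fraction,
                                       config.seed)
        for model in config.models:
            chosen = candidates
            if (model == "random_forest" and config.use_shadow_selection
                    and config.scope == "across_ages"):
                confirmed = select_features_shadow(train, candidates, config)
                if confirmed:
                    chosen = confirmed
            reg = fit_blend(train, chosen, config, model, window)
            pred = reg.predict_standardized(
                _design_frame(test, chosen, config.age_included))
            obs = (test.mwf - reg.y_mean_) / reg.y_sd_
            ev = evaluate_predictions(pred, obs)
            results.append(BlendResult(
                scope=config.scope, nutrient_set=config.nutrient_set,
                model=model, window=label,
                selected=_ranked_selection(reg, model),
                rho=ev.rho, ci_low=ev.ci_low, ci_high=ev.ci_high,
                rmse=ev.rmse, n_train=train.n, n_test=test.n))

    if config.scope == "across_ages":
        one(table, None, "all")
    else:
        if not windows:
            raise ValueError("per_window scope needs detected windows")
        ages = table.ages
        for w in windows:
            mask = np.array([w.contains_age(a) for a in ages])
            label = f"{w.start_month}-{w.end_month}"
            sub_df = table.data.loc[mask]
            if mask.sum() < 8:
                for model in config.models:
                    results.append(BlendResult(
                        scope=config.scope, nutrient_set=config.nutrient_set,
                        model=model, window=label,
                        note="too few children in window"))
                continue
            one(CohortTable(sub_df, table.dictionary), w, label)
    return results


def results_to_frame(results: list[BlendResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
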