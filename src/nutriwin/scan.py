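"""Sliding-window GLM scan of nutrient-myelin association across age.

The cohort is sorted by age and refit in consecutive windows of
``window_size`` children (default 25, stepping by ``stride``).  In each
window and for each nutrient the model

    MWF ~ b0 + b1*log(age) + b2*intake + b3*intake*log(age)

is fit by ordinary least squares, and the two-sided t-test p-value of the
nutrient main effect b2 is recorded together with its sign.  The resulting
windows x nutrients p-value map is the input to edge detection.

Within a 25-child window log(age) is nearly constant, which makes the
intake and interaction columns almost collinear; by default log(age) is
therefore centered at the window median, so that b2 measures the
association at the window's age rather than an extrapolation to age = 1
month.  Centering changes neither the fitted values nor the interaction
term; the uncentered design is available via ``center_log_age=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

_N_PARAMS = 4


@dataclass(frozen=True)
class ScanConfig:
    window_size: int = 25
    stride: int = 1
    alpha: float = 0.05
    center_log_age: bool = True

    def __post_init__(self) -> None:
        if self.window_size < _N_PARAMS + 1:
            raise ValueError(
                f"window_size must be >= {_N_PARAMS + 1}, got {self.window_size}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class WindowGLMFit:
    """One window x nutrient OLS fit.  ``p2`` is NaN for degenerate fits."""

    window_index: int
    age_min: float
    age_mid: float
    age_max: float
    nutrient: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    p2: float
    n: int
    degenerate: bool = False


@dataclass
class PValueMap:
    """Windows x nutrients map of nutrient-term p-values and signs."""

    p2: np.ndarray            # (n_windows, n_nutrients), NaN where degenerate
    sign: np.ndarray          # (n_windows, n_nutrients) in {-1, 0, +1}
    beta2: np.ndarray         # (n_windows, n_nutrients)
    age_mid: np.ndarray       # (n_windows,)
    age_min: np.ndarray
    age_max: np.ndarray
    nutrients: list[str]
    config: ScanConfig = field(default_factory=ScanConfig)

    @property
    def n_windows(self) -> int:
        return self.p2.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per window x nutrient."""
        nw, nn = self.p2.shape
        idx = np.repeat(np.arange(nw), nn)
        return pd.DataFrame({
            "window_index": idx,
            "age_mid": np.repeat(self.age_mid, nn),
            "nutrient": np.tile(np.asarray(self.nutrients, dtype=object), nw),
            "beta2": self.beta2.ravel(),
            "p2": self.p2.ravel(),
            "sign": self.sign.ravel().astype(int),
        })


def _ols_beta_p2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS via lstsq; returns coefficients and the b2 two-sided t-test
    p-value with n - 4 residual degrees of freedom."""
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    dof = n - X.shape[1]
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se2 = s2 * xtx_inv[2, 2]
    if se2 <= 0:
        # numerically exact fit: infinitely strong evidence
        return beta, 0.0
    t = beta[2] / np.sqrt(se2)
    p2 = 2.0 * stats.t.sf(abs(t), dof)
    return beta, float(p2)


def _design(age: np.ndarray, intake: np.ndarray, center: bool) -> np.ndarray:
    log_age = np.log(age)
    if center:
        log_age = log_age - np.median(log_age)
    return np.column_stack(
        [np.ones_like(log_age), log_age, intake, intake * log_age])


def fit_window_glm(observations, nutrient: str,
                   config: ScanConfig | None = None,
                   window_index: int = 0) -> WindowGLMFit:
    """Fit the four-term GLM on one window of observations.

    ``observations`` is a CohortTable, a DataFrame slice with age_months /
    mwf / nutrient columns, or a list of mappings with those keys.
    """
    config = config or ScanConfig()
    age, mwf, intake = _extract(observations, nutrient)
    if len(age) != config.window_size:
        raise ValueError(
            f"window must contain exactly {config.window_size} observations, "
            f"got {len(age)}")
    return _fit_one(age, mwf, intake, nutrient, config, window_index)


def _fit_one(age, mwf, intake, nutrient, config, window_index) -> WindowGLMFit:
    common = dict(
        window_index=window_index,
        age_min=float(age.min()), age_mid=float(np.median(age)),
        age_max=float(age.max()), nutrient=nutrient, n=len(age))
    if np.ptp(intake) == 0 or np.ptp(age) == 0:
        return WindowGLMFit(beta0=np.nan, beta1=np.nan, beta2=np.nan,
                            beta3=np.nan, p2=np.nan, degenerate=True, **common)
    X = _design(age, intake, config.center_log_age)
    try:
        beta, p2 = _ols_beta_p2(X, mwf)
    except np.linalg.LinAlgError:
        return WindowGLMFit(beta0=np.nan, beta1=np.nan, beta2=np.nan,
                            beta3=np.nan, p2=np.nan, degenerate=True, **common)
    return WindowGLMFit(beta0=float(beta[0]), beta1=float(beta[1]),
                        beta2=float(beta[2]), beta3=float(beta[3]),
                        p2=p2, **common)


def _extract(observations, nutrient):
    if isinstance(observations, CohortTable):
        df = observations.data
    elif isinstance(observations, pd.DataFrame):
        df = observations
    else:
        df = pd.DataFrame(list(observations))
    return (df["age_months"].to_numpy(float), df["mwf"].to_numpy(float),
            df[nutrient].to_numpy(float))


class SlidingWindowScan:
    """Estimator-style wrapper: fit on a CohortTable, exposes ``map_``.

    Parameters mirror ScanConfig.  The cohort is re-sorted by age
    internally, so the scan is invariant to input row order.
    """

    def __init__(self, window_size: int = 25, stride: int = 1,
                 alpha: float = 0.05, center_log_age: bool = True):
        self.window_size = window_size
        self.stride = stride
        self.alpha = alpha
        self.center_log_age = center_log_age

    def get_params(self, deep: bool = True) -> dict:
        return {"window_size": self.window_size, "stride": self.stride,
                "alpha": self.alpha, "center_log_age": self.center_log_age}

    def set_params(self, **params) -> "SlidingWindowScan":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def config(self) -> ScanConfig:
        return ScanConfig(self.window_size, self.stride, self.alpha,
                          self.center_log_age)

    def fit(self, table: CohortTable) -> "SlidingWindowScan":
        config = self.config
        n = table.n
        if n < config.window_size:
            raise ValueError(
                f"cohort has {n} children; the scan needs at least "
                f"{config.window_size}")
        nutrients = table.nutrients
        if not nutrients:
            raise ValueError("cohort has no nutrient columns")
        ages = table.ages
        mwf = table.mwf
        intakes = {nu: table.intake(nu) for nu in nutrients}

        starts = np.arange(0, n - config.window_size + 1, config.stride)
        nw, nn = len(starts), len(nutrients)
        p2 = np.full((nw, nn), np.nan)
        sign = np.zeros((nw, nn))
        beta2 = np.full((nw, nn), np.nan)
        age_mid = np.empty(nw)
        age_min = np.empty(nw)
        age_max = np.empty(nw)
        for i, s in enumerate(starts):
            sl = slice(s, s + config.window_size)
            a, y = ages[sl], mwf[sl]
            age_mid[i], age_min[i], age_max[i] = np.median(a), a.min(), a.max()
            for j, nu in enumerate(nutrients):
                f = _fit_one(a, y, intakes[nu][sl], nu, config, i)
                if not f.degenerate:
                    p2[i, j] = f.p2
                    beta2[i, j] = f.beta2
                    sign[i, j] = np.sign(f.beta2)
        self.map_ = PValueMap(p2=p2, sign=sign, beta2=beta2, age_mid=age_mid,
                              age_min=age_min, age_max=age_max,
                              nutrients=list(nutrients), config=config)
        self.n_windows_ = nw
        return self


def build_pvalue_map(table: CohortTable,
                     config: ScanConfig | None = None) -> PValueMap:
    """Run the full scan: one GLM per window x nutrient."""
    config = config or ScanConfig()
    scan = SlidingWindowScan(**config.__dict__)
    return scan.fit(table).map_


def expected_n_windows(n: int, config: ScanConfig) -> int:
    return (n - config.window_size) // config.stride + 1
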