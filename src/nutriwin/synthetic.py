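"""Synthetic cohort generator with exported ground truth.

Emulates the statistical structure the analysis assumes: cross-sectional
ages, MWF growing with log(age), per-age-window nutrient intake
distributions matching a printed reference table (mean, SD, min, max per
window), and window-gated nutrient effects on MWF.  Intakes are drawn from
[min, max]-truncated normals whose pre-truncation (mu, sigma) are solved so
the truncated moments reproduce the reference mean and SD; when no SD
solution exists inside the bounds (SD/mean near or above 1 with min = 0 is
mathematically unreachable for a truncated normal) the calibration falls
back, with a warning, to matching the mean exactly and approaching the SD
as closely as possible.

Every replicate exports a SyntheticTruth (planted boundaries, per-window
effective nutrient sets, coefficients, baseline and noise parameters) so
downstream window detection and blend selection can be scored.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy import optimize, stats
from scipy.special import erfcx, ndtr

from .cohort import CohortTable, default_dictionary


# --------------------------------------------------------------------------
# truncated-normal moments and calibration

def _standard_truncated_moments(a: float, b: float) -> tuple[float, float]:
    """Mean and variance of a standard normal truncated to [a, b].

    Uses erfcx-scaled expressions so the formulas stay finite even when
    [a, b] lies deep in a tail (where plain CDF differences underflow).
    """
    if a > 0:  # reflect the upper tail onto the lower one
        m, v = _standard_truncated_moments(-b, -a)
        return -m, v
    # now a <= 0
    sq2 = np.sqrt(2.0)
    c = 2.0 / np.sqrt(2.0 * np.pi)
    if b <= 0:
        # both tails below zero: scale by exp(b^2/2) via erfcx at -a, -b
        d = np.exp((b * b - a * a) / 2.0)           # phi(a)/phi(b) <= 1
        ea = erfcx(-a / sq2)
        eb = erfcx(-b / sq2)
        denom = eb - d * ea
        r1 = c * (d - 1.0) / denom                  # (phi(a)-phi(b))/Z
        r2 = c * (a * d - b) / denom                # (a phi(a)-b phi(b))/Z
    else:
        # interval straddles zero: plain formulas are stable
        Z = ndtr(b) - ndtr(a)
        pa = np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi)
        pb = np.exp(-0.5 * b * b) / np.sqrt(2 * np.pi)
        r1 = (pa - pb) / Z
        r2 = (a * pa - b * pb) / Z
    var = 1.0 + r2 - r1 * r1
    return float(r1), float(max(var, 0.0))


def truncated_normal_moments(mu: float, sigma: float, lo: float,
                             hi: float) -> tuple[float, float]:
    """Mean and SD of a normal(mu, sigma) truncated to [lo, hi]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m, v = _standard_truncated_moments((lo - mu) / sigma, (hi - mu) / sigma)
    return mu + sigma * m, sigma * float(np.sqrt(v))


@dataclass(frozen=True)
class TruncatedNormalCalibration:
    mu: float
    sigma: float
    lo: float
    hi: float
    achieved_mean: float
    achieved_sd: float
    exact: bool  # False when only the mean could be matched


def _solve_mu(sigma: float, target_mean: float, lo: float, hi: float) -> float:
    """Mu such that the [lo,hi]-truncated mean equals target.

    Solved in standardized space: with a = (lo - mu)/sigma and
    b = a + (hi - lo)/sigma the truncated mean is strictly decreasing in a,
    running from hi (a -> -inf) to lo (a -> +inf); the bracket is expanded
    until it straddles the target.
    """
    w = (hi - lo) / sigma
    m_std = (target_mean - lo) / sigma  # target for mean - lo in sigma units

    def f(a):
        r1, _ = _standard_truncated_moments(a, a + w)
        return (r1 - a) - m_std         # E[x]-lo in sigma units, minus target

    half = 8.0
    while f(-half) * f(half) > 0:
        half *= 4.0
        if half > 1e12:
            raise RuntimeError(
                f"could not bracket the mean equation for sigma={sigma}")
    a = optimize.brentq(f, -half, half, xtol=1e-13, rtol=1e-14)
    return lo - a * sigma


@lru_cache(maxsize=4096)
def _calibrate_cached(target_mean: float, target_sd: float, lo: float,
                      hi: float) -> TruncatedNormalCalibration:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return calibrate_truncated_normal(target_mean, target_sd, lo, hi,
                                          detail=True)


def calibrate_truncated_normal(target_mean: float, target_sd: float,
                               lo: float, hi: float,
                               detail: bool = False):
    """Pre-truncation (mu, sigma) reproducing the target truncated moments.

    Nested solve: for each sigma the mean equation is solved exactly for mu
    (the truncated mean is monotone in mu), leaving a 1-D problem in sigma
    for the SD.  If the SD equation has no root the sigma with the closest
    achievable SD is used and a warning is issued (mean still exact).

    Returns (mu, sigma), or a TruncatedNormalCalibration when
    ``detail=True``.
    """
    if not lo < hi:
        raise ValueError(f"need min < max, got [{lo}, {hi}]")
    if not lo < target_mean < hi:
        raise ValueError(
            f"target mean {target_mean} infeasible for bounds [{lo}, {hi}]")
    if target_sd <= 0:
        raise ValueError(f"target SD must be positive, got {target_sd}")

    span = hi - lo

    def sd_at(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = _solve_mu(sigma, target_mean, lo, hi)
        return truncated_normal_moments(mu, sigma, lo, hi)[1]

    g_lo = min(1e-3 * span, 0.3 * target_sd)
    g_hi = max(30 * span, 3 * target_sd)
    grid = np.linspace(np.log(g_lo), np.log(g_hi), 60)
    sds = np.array([sd_at(g) for g in grid])
    diffs = sds - target_sd
    exact = True
    idx = np.where(np.sign(diffs[:-1]) * np.sign(diffs[1:]) <= 0)[0]
    if len(idx) and np.any(diffs != 0):
        i = int(idx[0])
        log_sigma = optimize.brentq(
            lambda g: sd_at(g) - target_sd, grid[i], grid[i + 1],
            xtol=1e-13)
    else:
        # no root: take the closest achievable SD (mean stays exact)
        exact = False
        i = int(np.argmin(np.abs(diffs)))
        lo_g = grid[max(i - 1, 0)]
        hi_g = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: abs(sd_at(g) - target_sd), bounds=(lo_g, hi_g),
            method="bounded")
        log_sigma = float(res.x)
        warnings.warn(
            f"target SD {target_sd} unreachable on [{lo}, {hi}] with mean "
            f"{target_mean}; matching the mean only (closest SD "
            f"{sd_at(log_sigma):.4g})", RuntimeWarning, stacklevel=2)

    sigma = float(np.exp(log_sigma))
    mu = _solve_mu(sigma, target_mean, lo, hi)
    m, s = truncated_normal_moments(mu, sigma, lo, hi)
    # tolerate tiny residuals from the root find itself
    if exact and abs(s - target_sd) > 1e-6 * max(1.0, target_sd):
        exact = False
    cal = TruncatedNormalCalibration(mu=mu, sigma=sigma, lo=lo, hi=hi,
                                     achieved_mean=m, achieved_sd=s,
                                     exact=exact)
    return cal if detail else (mu, sigma)


def sample_truncated_normal(cal: TruncatedNormalCalibration, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    a = (cal.lo - cal.mu) / cal.sigma
    b = (cal.hi - cal.mu) / cal.sigma
    return stats.truncnorm.rvs(a, b, loc=cal.mu, scale=cal.sigma,
                               size=size, random_state=rng)


# --------------------------------------------------------------------------
# reference intake table and specs

@dataclass(frozen=True)
class IntakeSpec:
    """Target intake distribution of one nutrient in one age window."""

    nutrient: str
    window: int               # 1-based window number
    target_mean: float
    target_sd: float
    lo: float
    hi: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.lo <= self.target_mean <= self.hi:
            raise ValueError(
                f"{self.nutrient} window {self.window}: mean "
                f"{self.target_mean} outside [{self.lo}, {self.hi}]")
        if self.target_sd <= 0:
            raise ValueError(
                f"{self.nutrient} window {self.window}: SD must be > 0")

    def calibrate(self) -> TruncatedNormalCalibration:
        # cached: the same printed row is calibrated once per process
        return _calibrate_cached(self.target_mean, self.target_sd,
                                 self.lo, self.hi)


def load_intake_reference() -> pd.DataFrame:
    """The packaged per-window intake reference table (transcribed printed
    means/SDs/ranges; three windows 6-20, 21-30, 31-60 months)."""
    ref = importlib.resources.files("nutriwin.data") / "intake_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_intake_specs() -> list[IntakeSpec]:
    table = load_intake_reference()
    return [IntakeSpec(nutrient=r.nutrient, window=int(r.window),
                       target_mean=float(r.mean), target_sd=float(r.sd),
                       lo=float(r.min), hi=float(r.max), unit=r.unit)
            for r in table.itertuples()]


def reference_spec(nutrient: str, window: int) -> IntakeSpec:
    for spec in reference_intake_specs():
        if spec.nutrient == nutrient and spec.window == window:
            return spec
    raise KeyError(f"no reference row for {nutrient!r} in window {window}")


# Default generator panel: the first 30 nutrients of the reference table in
# order of first appearance.  Nutrients without a printed row in a window
# reuse the nearest printed window's parameters.
DEFAULT_NUTRIENTS: tuple[str, ...] = (
    "Copper", "Folate", "Histidine", "Iron", "Isoleucine", "Leucine",
    "Magnesium", "Phosphorus", "Potassium", "Selenium", "Valine",
    "Vitamin A", "Vitamin B1", "Vitamin B2", "Vitamin B6", "3'SL", "Zinc",
    "alpha_lactalbumin", "Cryptoxanthin", "Gangliosides", "Oligofructose",
    "PFA 18:4", "PFA 20:4", "PFA 22:5", "Phosphatidylcholine",
    "Phosphatidylinositol", "Sphingomyelin", "6'SL", "Alpha-carotene",
    "Alpha tocopherol",
)


def default_intake_specs(nutrients=DEFAULT_NUTRIENTS,
                         n_windows: int = 3) -> dict[tuple[str, int], IntakeSpec]:
    """Per (nutrient, window) specs, filling unprinted windows from the
    nearest printed one."""
    ref = {(s.nutrient, s.window): s for s in reference_intake_specs()}
    out: dict[tuple[str, int], IntakeSpec] = {}
    for nutrient in nutrients:
        printed = sorted(w for (n, w) in ref if n == nutrient)
        if not printed:
            raise KeyError(f"nutrient {nutrient!r} not in the reference table")
        for w in range(1, n_windows + 1):
            nearest = min(printed, key=lambda p: abs(p - w))
            src = ref[(nutrient, nearest)]
            out[(nutrient, w)] = IntakeSpec(
                nutrient=nutrient, window=w, target_mean=src.target_mean,
                target_sd=src.target_sd, lo=src.lo, hi=src.hi, unit=src.unit)
    return out


# --------------------------------------------------------------------------
# generator configuration and truth

@dataclass(frozen=True)
class EffectSpec:
    """A window-gated nutrient effect: MWF shifts by ``effect`` per 1 SD of
    intake for children inside the active windows."""

    nutrient: str
    windows: tuple[int, ...]
    effect: float


DEFAULT_EFFECT_SIZE = 0.015

# Effect sets follow the field's narrative: micronutrients early, polar
# lipids and milk oligosaccharides in the middle window, lipids plus amino
# acids later.
DEFAULT_EFFECTS: tuple[EffectSpec, ...] = tuple(
    [EffectSpec(n, (1,), DEFAULT_EFFECT_SIZE)
     for n in ("Copper", "Iron", "Zinc", "Folate", "Vitamin B6")]
    + [EffectSpec(n, (2,), DEFAULT_EFFECT_SIZE)
       for n in ("Gangliosides", "Sphingomyelin", "Phosphatidylcholine",
                 "Phosphatidylinositol", "3'SL")]
    + [EffectSpec(n, (3,), DEFAULT_EFFECT_SIZE)
       for n in ("Alpha tocopherol", "PFA 22:5", "6'SL", "Valine", "Leucine")]
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_children: int = 293
    age_min: float = 6.0
    age_max: float = 60.0
    boundaries: tuple[float, ...] = (20.0, 30.0)
    baseline_a: float = 0.10
    baseline_b: float = 0.045
    noise_sd: float = 0.004
    nutrients: tuple[str, ...] = DEFAULT_NUTRIENTS
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS
    equicorrelation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("need age_min < age_max")
        bs = tuple(self.boundaries)
        if list(bs) != sorted(bs) or len(set(bs)) != len(bs):
            raise ValueError("boundaries must be strictly increasing")
        if any(b <= self.age_min or b >= self.age_max for b in bs):
            raise ValueError("boundaries must lie inside the age range")
        if not 0 <= self.equicorrelation < 1:
            raise ValueError("equicorrelation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = set(self.nutrients)
        for e in self.effects:
            if e.nutrient not in names:
                raise ValueError(
                    f"effect on {e.nutrient!r} but nutrient not generated")
            bad = [w for w in e.windows if not 1 <= w <= len(bs) + 1]
            if bad:
                raise ValueError(
                    f"effect on {e.nutrient!r} names windows {bad} outside "
                    f"1..{len(bs) + 1}")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries) + 1


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to score recovery of a generated cohort."""

    boundaries: tuple[float, ...]
    active: dict[int, dict[str, float]]  # window -> {nutrient: coeff}
    baseline_a: float
    baseline_b: float
    noise_sd: float
    seed: int
    nutrients: tuple[str, ...]

    def active_set(self, window: int) -> set[str]:
        return set(self.active.get(window, {}))


def _child_windows(ages: np.ndarray, boundaries) -> np.ndarray:
    """1-based window index per child; the boundary month belongs to the
    earlier window, judged on the age rounded to the nearest month."""
    months = np.round(ages)
    return np.searchsorted(np.asarray(boundaries, float), months,
                           side="left") + 1


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a cohort and its ground truth.  ``seed`` overrides config.seed."""
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n = config.n_children
    ages = np.sort(rng.uniform(config.age_min, config.age_max, n))
    wins = _child_windows(ages, config.boundaries)

    specs = default_intake_specs(config.nutrients, config.n_windows)
    cals = {key: spec.calibrate() for key, spec in specs.items()}

    intakes = np.empty((n, len(config.nutrients)))
    for w in range(1, config.n_windows + 1):
        mask = wins == w
        k = int(mask.sum())
        if k == 0:
            continue
        if config.equicorrelation > 0:
            rho = config.equicorrelation
            shared = rng.standard_normal(k)
            for j, nutrient in enumerate(config.nutrients):
                own = rng.standard_normal(k)
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
                cal = cals[(nutrient, w)]
                a = (cal.lo - cal.mu) / cal.sigma
                b = (cal.hi - cal.mu) / cal.sigma
                u = ndtr(z)
                intakes[mask, j] = stats.truncnorm.ppf(
                    u, a, b, loc=cal.mu, scale=cal.sigma)
        else:
            for j, nutrient in enumerate(config.nutrients):
                intakes[mask, j] = sample_truncated_normal(
                    cals[(nutrient, w)], k, rng)

    active: dict[int, dict[str, float]] = {w: {} for w in
                                           range(1, config.n_windows + 1)}
    for e in config.effects:
        for w in e.windows:
            active[w][e.nutrient] = active[w].get(e.nutrient, 0.0) + e.effect

    mwf = config.baseline_a + config.baseline_b * np.log(ages)
    col = {nutrient: j for j, nutrient in enumerate(config.nutrients)}
    for w, effs in active.items():
        mask = wins == w
        if not mask.any():
            continue
        for nutrient, coeff in effs.items():
            cal = cals[(nutrient, w)]
            z = (intakes[mask, col[nutrient]] - cal.achieved_mean) / cal.achieved_sd
            mwf[mask] += coeff * z
    mwf = mwf + rng.normal(0.0, config.noise_sd, n)

    if np.any(mwf <= 0) or np.any(mwf >= 1):
        bad = float(mwf[np.argmin(np.minimum(mwf, 1 - mwf))])
        raise ValueError(
            f"generated mwf {bad:.4f} outside (0,1); adjust baseline_a="
            f"{config.baseline_a}, baseline_b={config.baseline_b}, "
            f"noise_sd={config.noise_sd} or the effect sizes")

    width = len(str(n))
    data = pd.DataFrame({
        "subject_id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
        "age_months": ages,
        "mwf": mwf,
    })
    for j, nutrient in enumerate(config.nutrients):
        data[nutrient] = intakes[:, j]

    table = CohortTable(data, default_dictionary())
    truth = SyntheticTruth(
        boundaries=tuple(float(b) for b in config.boundaries),
        active={w: dict(d) for w, d in active.items()},
        baseline_a=config.baseline_a, baseline_b=config.baseline_b,
        noise_sd=config.noise_sd, seed=seed,
        nutrients=tuple(config.nutrients))
    return table, truth


# --------------------------------------------------------------------------
# recovery scoring

def boundary_errors(truth: SyntheticTruth, detected: list[float]) -> list[float]:
    """Per planted boundary, distance (months) to the nearest detected one;
    NaN when nothing was detected."""
    if not detected:
        return [float("nan")] * len(truth.boundaries)
    det = np.asarray(detected, float)
    return [float(np.min(np.abs(det - b))) for b in truth.boundaries]


def _overlap(a_lo, a_hi, b_lo, b_hi) -> float:
    return max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))


def selection_scores(truth: SyntheticTruth, windows) -> pd.DataFrame:
    """Precision/recall of per-window nutrient selection against the
    planted sets.  Each true window is scored against the detected window
    with the largest age overlap.  Empty selections give precision NaN."""
    tb = [float("-inf")] + [float(b) for b in truth.boundaries] + [float("inf")]
    rows = []
    for w_idx in range(1, len(tb)):
        t_lo, t_hi = tb[w_idx - 1], tb[w_idx]
        best, best_ov = None, -1.0
        for dw in windows:
            ov = _overlap(t_lo, t_hi, dw.start_month - 0.5, dw.end_month + 0.5)
            if ov > best_ov:
                best, best_ov = dw, ov
        planted = truth.active_set(w_idx)
        selected = ({name for name, _, _ in best.selected_nutrients}
                    if best is not None else set())
        tp = len(planted & selected)
        rows.append({
            "window": w_idx,
            "n_planted": len(planted),
            "n_selected": len(selected),
            "tp": tp,
            "precision": tp / len(selected) if selected else float("nan"),
            "recall": tp / len(planted) if planted else float("nan"),
        })
    return pd.DataFrame(rows)


def planted_truth_report(truth: SyntheticTruth, windows,
                         blend_selected=None) -> pd.DataFrame:
    """Recovery metrics for one pipeline run on a synthetic cohort:
    boundary absolute errors, per-window selection precision/recall, and
    (optionally) blend-selection precision/recall against the union of
    planted nutrients."""
    rows = []
    detected = [float(w.end_month) for w in windows[:-1]]
    for b, err in zip(truth.boundaries, boundary_errors(truth, detected)):
        rows.append({"metric": "boundary_abs_error", "window": "",
                     "detail": f"planted@{b:g}", "value": err})
    for r in selection_scores(truth, windows).itertuples():
        rows.append({"metric": "selection_precision", "window": r.window,
                     "detail": f"{r.tp}/{r.n_selected}", "value": r.precision})
        rows.append({"metric": "selection_recall", "window": r.window,
                     "detail": f"{r.tp}/{r.n_planted}", "value": r.recall})
    if blend_selected is not None:
        planted_union = set().union(*(truth.active_set(w)
                                      for w in truth.active)) if truth.active else set()
        chosen = {s for s in blend_selected if s != "age_months"}
        tp = len(chosen & planted_union)
        rows.append({"metric": "blend_precision", "window": "",
                     "detail": f"{tp}/{len(chosen)}",
                     "value": tp / len(chosen) if chosen else float("nan")})
        rows.append({"metric": "blend_recall", "window": "",
                     "detail": f"{tp}/{len(planted_union)}",
                     "value": (tp / len(planted_union)
                               if planted_union else float("nan"))})
    return pd.DataFrame(rows)
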