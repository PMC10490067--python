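"""Edge detection on the significance map and age-window construction.

The scan's p-value map is binarized (1 where the nutrient term is
significant and positive), convolved with a 3x3 Sobel kernel oriented along
the age axis, and the nutrient-summed gradient magnitude gives an edge
profile over window positions.  Peaks of the profile (non-maximum
suppression, mean + 1 SD threshold, or a forced top-k) become window
boundaries, rounded to whole months; abutting closed month ranges are the
detected age windows.  A nutrient is assigned to a window when at least
``fraction_threshold`` (default 50%) of the scan windows inside it are
significant-positive for that nutrient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import CohortTable
from .scan import PValueMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeProfile:
    """Edge strength per scan-window position plus detected boundaries."""

    strength: np.ndarray          # (n_windows,), >= 0
    boundary_indices: np.ndarray  # strictly increasing window indices
    boundary_ages: np.ndarray     # months, same length


@dataclass
class AgeWindow:
    """A detected age segment (closed month range)."""

    start_month: int
    end_month: int
    n_children: int = 0
    # list of (nutrient, sign, significant_fraction)
    selected_nutrients: list = field(default_factory=list)

    def contains_age(self, age: float) -> bool:
        return self.start_month - 0.5 <= age < self.end_month + 0.5


def binarize_map(pmap: PValueMap, alpha: float = 0.05,
                 mode: str = "positive_only") -> np.ndarray:
    """Threshold the p-value map.

    positive_only: 1 where p2 < alpha and beta2 > 0, else 0 (NaN -> 0).
    signed: additionally -1 where p2 < alpha and beta2 < 0.
    """
    if mode not in ("positive_only", "signed"):
        raise ValueError(f"mode must be 'positive_only' or 'signed', got {mode!r}")
    with np.errstate(invalid="ignore"):
        sig = pmap.p2 < alpha
    out = np.where(sig & (pmap.sign > 0), 1, 0)
    if mode == "signed":
        out = np.where(sig & (pmap.sign < 0), -1, out)
    return out.astype(int)


SOBEL_AGE_KERNEL = np.array([[-1, -2, -1],
                             [0, 0, 0],
                             [1, 2, 1]], dtype=float)


def sobel_edge_profile(binary_map: np.ndarray, smooth: int = 0) -> EdgeProfile:
    """Sobel gradient along the window (age) axis, summed over nutrients.

    Borders are replicate-padded, so a constant map (all zero or all one)
    has zero strength everywhere.

    With ``smooth > 1`` the signed per-nutrient gradient is box-averaged
    over that many window positions before the magnitudes are summed.
    Under a stride-1 scan adjacent windows share all but one child, so a
    real transition is a ramp roughly one window wide while speckle
    produces alternating-sign micro-gradients; averaging the signed
    gradient cancels the speckle but preserves coherent ramps.  The
    default (0) is the plain nutrient-summed gradient magnitude.

    Boundary detection is left to ``segment_windows``; the returned
    profile has no boundaries set.
    """
    m = np.asarray(binary_map, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3:
        raise ValueError(
            "edge detection needs a 2-D map with at least 3 windows, got "
            f"shape {m.shape}")
    grad = ndimage.sobel(m, axis=0, mode="nearest")
    if smooth > 1:
        grad = ndimage.uniform_filter1d(grad, size=min(smooth, m.shape[0]),
                                        axis=0, mode="nearest")
    strength = np.abs(grad).sum(axis=1)
    return EdgeProfile(strength=strength,
                       boundary_indices=np.array([], dtype=int),
                       boundary_ages=np.array([], dtype=float))


def _local_maxima(strength: np.ndarray, min_gap: int) -> np.ndarray:
    """Indices of local maxima after non-maximum suppression with a minimum
    separation of ``min_gap`` positions; ties resolved to the earlier index."""
    order = np.argsort(strength, kind="stable")[::-1]
    kept: list[int] = []
    for idx in order:
        if strength[idx] <= 0:
            break
        if all(abs(idx - k) >= min_gap for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def _auto_scale(pmap: PValueMap) -> int:
    """Natural edge scale in profile positions: the overlap length of
    adjacent scan windows (window_size/stride), at least 1."""
    cfg = pmap.config
    return max(1, cfg.window_size // cfg.stride)


def segment_windows(profile: EdgeProfile, pmap: PValueMap,
                    k_boundaries: int | None = None,
                    min_gap: int | None = None,
                    table: CohortTable | None = None) -> list[AgeWindow]:
    """Turn the edge profile into abutting age windows.

    Boundaries are profile peaks (non-maximum suppression with minimum
    separation ``min_gap``, default the window overlap length) retained
    when stronger than mean + 1 SD of the profile, or the top-k peaks when
    ``k_boundaries`` is forced.  No qualifying peak yields a single window
    covering the cohort range.  Boundary ages are the scan-window
    ``age_mid`` at each peak, rounded to the nearest whole month; the
    boundary month belongs to the earlier window.  ``table`` (when given)
    fills per-window child counts.
    """
    if min_gap is None:
        min_gap = max(5, _auto_scale(pmap))
    s = profile.strength
    peaks = _local_maxima(s, min_gap)
    if k_boundaries is not None:
        if len(peaks) > k_boundaries:
            top = peaks[np.argsort(s[peaks], kind="stable")[::-1][:k_boundaries]]
            peaks = np.sort(top)
    else:
        thresh = s.mean() + s.std()
        peaks = peaks[s[peaks] > thresh]

    ages = pmap.age_mid
    age_lo = float(pmap.age_min.min())
    age_hi = float(pmap.age_max.max())
    if table is not None:
        age_lo = min(age_lo, float(table.ages.min()))
        age_hi = max(age_hi, float(table.ages.max()))
    start = int(round(age_lo))
    end = int(round(age_hi))

    boundary_months: list[int] = []
    for p in peaks:
        b = int(round(float(ages[p])))
        if start <= b < end and (not boundary_months or b > boundary_months[-1]):
            boundary_months.append(b)

    windows: list[AgeWindow] = []
    lo = start
    for b in boundary_months:
        windows.append(AgeWindow(start_month=lo, end_month=b))
        lo = b + 1
    windows.append(AgeWindow(start_month=lo, end_month=end))

    if table is not None:
        assign_children(windows, table)
    return windows


def assign_children(windows: list[AgeWindow], table: CohortTable) -> None:
    """Count children per window: a child belongs to the window whose closed
    month range contains its age rounded to the nearest month (earlier
    window on ties), so the counts partition the cohort."""
    ages = table.ages
    counts = np.zeros(len(windows), dtype=int)
    for a in ages:
        for i, w in enumerate(windows):
            if w.contains_age(a):
                counts[i] += 1
                break
        else:  # outside every window: clamp to nearest end
            counts[0 if a < windows[0].start_month else -1] += 1
    for w, c in zip(windows, counts):
        w.n_children = int(c)


def select_window_nutrients(pmap: PValueMap, windows: list[AgeWindow],
                            fraction_threshold: float = 0.5,
                            alpha: float | None = None,
                            mode: str = "positive_only") -> list[AgeWindow]:
    """Fill ``selected_nutrients`` by the 50%-significance rule.

    For each window and nutrient the significant fraction is the share of
    non-degenerate scan windows whose age_mid falls in the segment that are
    significant-positive (or significant of either sign in ``signed`` mode);
    the nutrient is selected when the fraction reaches the threshold.  The
    recorded sign is the majority sign among that nutrient's significant
    fits in the segment.
    """
    alpha = pmap.config.alpha if alpha is None else alpha
    binary = binarize_map(pmap, alpha=alpha, mode=mode)
    hit = binary > 0 if mode == "positive_only" else binary != 0
    ok = ~np.isnan(pmap.p2)
    for w in windows:
        inside = np.array([w.contains_age(a) for a in pmap.age_mid])
        w.selected_nutrients = []
        if not inside.any():
            logger.warning("window %d-%d months contains no scan windows",
                           w.start_month, w.end_month)
            continue
        for j, nutrient in enumerate(pmap.nutrients):
            denom = int((inside & ok[:, j]).sum())
            if denom == 0:
                continue
            hits = inside & hit[:, j]
            frac = hits.sum() / denom
            if frac >= fraction_threshold:
                signs = pmap.sign[hits, j]
                sign = 1 if (signs > 0).sum() >= (signs < 0).sum() else -1
                w.selected_nutrients.append((nutrient, int(sign), float(frac)))
    return windows


def merge_equivalent_windows(pmap: PValueMap, windows: list[AgeWindow],
                             fraction_threshold: float = 0.5,
                             alpha: float | None = None,
                             mode: str = "positive_only") -> list[AgeWindow]:
    """Merge adjacent windows whose 50%-rule selections coincide.

    A detected boundary only marks a real window transition when the
    nutrient associations differ on its two sides; adjacent segments with
    identical selected sets — in particular two empty ones, the generic
    outcome on a null cohort — are collapsed and the selection is
    recomputed, until stable.
    """
    windows = [AgeWindow(w.start_month, w.end_month) for w in windows]
    while True:
        select_window_nutrients(pmap, windows, fraction_threshold, alpha, mode)
        merged: list[AgeWindow] = []
        changed = False
        for w in windows:
            names = {n for n, _, _ in w.selected_nutrients}
            if merged and names == {n for n, _, _ in
                                    merged[-1].selected_nutrients}:
                merged[-1] = AgeWindow(merged[-1].start_month, w.end_month)
                select_window_nutrients(pmap, [merged[-1]],
                                        fraction_threshold, alpha, mode)
                changed = True
            else:
                merged.append(w)
        windows = merged
        if not changed:
            return windows


class SobelWindowDetector:
    """Estimator-style wrapper: fit on a PValueMap, exposes windows_.

    Fitted attributes: ``binary_map_``, ``edge_profile_``, ``boundaries_``
    (months), ``windows_`` (with selected nutrients filled).

    ``smooth`` and ``min_gap`` default to the scan's window overlap length
    (window_size/stride positions); ``merge_equal`` collapses adjacent
    windows with identical nutrient selections (disabled when
    ``k_boundaries`` is forced).
    """

    def __init__(self, alpha: float = 0.05, mode: str = "positive_only",
                 min_gap: int | None = None, k_boundaries: int | None = None,
                 fraction_threshold: float = 0.5, smooth: int | None = None,
                 merge_equal: bool = True):
        self.alpha = alpha
        self.mode = mode
        self.min_gap = min_gap
        self.k_boundaries = k_boundaries
        self.fraction_threshold = fraction_threshold
        self.smooth = smooth
        self.merge_equal = merge_equal

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "mode": self.mode,
                "min_gap": self.min_gap, "k_boundaries": self.k_boundaries,
                "fraction_threshold": self.fraction_threshold,
                "smooth": self.smooth, "merge_equal": self.merge_equal}

    def set_params(self, **params) -> "SobelWindowDetector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, pmap: PValueMap,
            table: CohortTable | None = None) -> "SobelWindowDetector":
        smooth = _auto_scale(pmap) if self.smooth is None else self.smooth
        self.binary_map_ = binarize_map(pmap, self.alpha, self.mode)
        profile = sobel_edge_profile(self.binary_map_, smooth=smooth)
        windows = segment_windows(profile, pmap, self.k_boundaries,
                                  self.min_gap, table)
        if self.merge_equal and self.k_boundaries is None:
            windows = merge_equivalent_windows(pmap, windows,
                                               self.fraction_threshold,
                                               self.alpha, self.mode)
        self.windows_ = windows
        if table is not None:
            assign_children(self.windows_, table)
        boundaries = [w.end_month for w in self.windows_[:-1]]
        idx = [int(np.argmin(np.abs(pmap.age_mid - b))) for b in boundaries]
        self.edge_profile_ = EdgeProfile(
            strength=profile.strength,
            boundary_indices=np.array(idx, dtype=int),
            boundary_ages=np.array(boundaries, dtype=float))
        self.boundaries_ = list(boundaries)
        select_window_nutrients(pmap, self.windows_, self.fraction_threshold,
                                self.alpha, self.mode)
        return self


def windows_to_frame(windows: list[AgeWindow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"start_month": w.start_month, "end_month": w.end_month,
         "n_children": w.n_children,
         "n_selected": len(w.selected_nutrients)}
        for w in windows])


def selection_to_frame(windows: list[AgeWindow],
                       nutrients: list[str]) -> pd.DataFrame:
    """Window x nutrient selection matrix: fraction, sign, selected flag."""
    rows = []
    for w in windows:
        sel = {name: (sign, frac) for name, sign, frac in w.selected_nutrients}
        for nutrient in nutrients:
            sign, frac = sel.get(nutrient, (0, np.nan))
            rows.append({
                "start_month": w.start_month, "end_month": w.end_month,
                "nutrient": nutrient, "fraction": frac, "sign": sign,
                "selected": nutrient in sel})
    return pd.DataFrame(rows)
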