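"""Image-based vitality quantification and water-use modelling.

Works on integer label maps (one class code per pixel) produced by an
upstream pixel classifier.  Class codes: 0 background, 1 vital tissue,
2 necrotic tissue, 3 the white scale label photographed in every image.
Vital and necrotic pixel counts are normalised by the measured pixel area
of the scale label so that counts are comparable across images taken at
different zoom levels; vital pixel count then serves as a proxy for plant
size, and the fraction vital/(vital+necrotic) quantifies drought-induced
senescence.  A line is called drought tolerant when its mean vital-area
percentage across replicates strictly exceeds 50%.

Pot water content is tracked by weighing: weights are piecewise-linearly
interpolated onto photo days, water content is weight minus oven-dry
weight, and cumulative water loss is modelled by ordinary least squares
with plant line, plant size and their interaction as predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "CLASS_CODES",
    "PixelCounts",
    "WaterModelFit",
    "count_class_pixels",
    "calibrate_area",
    "vitality_percent",
    "classify_tolerant",
    "compute_water_series",
    "fit_water_model",
    "disc_linearity_check",
]

CLASS_BACKGROUND = 0
CLASS_VITAL = 1
CLASS_NECROTIC = 2
CLASS_SCALE_LABEL = 3

CLASS_CODES: Mapping[int, str] = {
    CLASS_BACKGROUND: "background",
    CLASS_VITAL: "vital",
    CLASS_NECROTIC: "necrotic",
    CLASS_SCALE_LABEL: "scale_label",
}


@dataclass
class PixelCounts:
    """Per-class pixel counts of one image, optionally calibrated.

    ``calibration_factor`` is nominal label area divided by measured label
    pixels; normalised areas are raw counts times this factor, hence
    invariant to uniform rescaling of the image.
    """

    background: int
    vital: int
    necrotic: int
    scale_label: int
    calibration_factor: float | None = None
    vital_norm: float | None = None
    necrotic_norm: float | None = None

    @property
    def total(self) -> int:
        return self.background + self.vital + self.necrotic + self.scale_label


@dataclass
class WaterModelFit:
    """OLS fit of cumulative water loss on line, plant size and their
    interaction, plus the size-only reduced model."""

    r_squared: float
    f_pvalue: float
    term_pvalues: dict[str, float]
    params: pd.Series
    reduced_slope: float
    reduced_intercept: float
    reduced_r_squared: float
    reduced_slope_ci: tuple[float, float]
    reduced_pvalue: float


def count_class_pixels(image: np.ndarray) -> PixelCounts:
    """Histogram a label image over the four known class codes.

    Raises ``ValueError`` (reporting the offending code) if the image
    contains a value outside the code set.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("label image must contain integer class codes")
        arr = arr.astype(np.int64)
    counts = np.bincount(arr.ravel(), minlength=len(CLASS_CODES))
    if len(counts) > len(CLASS_CODES) and counts[len(CLASS_CODES):].any():
        bad = int(np.nonzero(counts[len(CLASS_CODES):])[0][0]) + len(CLASS_CODES)
        raise ValueError(f"unknown class code {bad} in label image")
    if arr.min() < 0:
        raise ValueError(f"unknown class code {int(arr.min())} in label image")
    return PixelCounts(
        background=int(counts[CLASS_BACKGROUND]),
        vital=int(counts[CLASS_VITAL]),
        necrotic=int(counts[CLASS_NECROTIC]),
        scale_label=int(counts[CLASS_SCALE_LABEL]),
    )


def calibrate_area(
    raw: PixelCounts,
    nominal_label_area: float = 1.0,
    label_pixels: int | None = None,
) -> PixelCounts:
    """Normalise vital/necrotic counts by the measured scale-label area.

    ``label_pixels`` defaults to the label count of the image itself; pass
    a value from a paired calibrator image when the label is photographed
    separately.  Normalised area = raw count x nominal_label_area /
    label_pixels, so the same scene photographed at a different zoom yields
    identical normalised areas.
    """
    if label_pixels is None:
        label_pixels = raw.scale_label
    if label_pixels <= 0:
        raise ValueError("no scale-label pixels found; cannot calibrate")
    if nominal_label_area <= 0:
        raise ValueError("nominal_label_area must be positive")
    factor = nominal_label_area / label_pixels
    return PixelCounts(
        background=raw.background,
        vital=raw.vital,
        necrotic=raw.necrotic,
        scale_label=raw.scale_label,
        calibration_factor=factor,
        vital_norm=raw.vital * factor,
        necrotic_norm=raw.necrotic * factor,
    )


def vitality_percent(vital: float, necrotic: float) -> float:
    """Percentage of plant tissue that is vital, 100*vital/(vital+necrotic).

    Background is excluded on purpose: it dominates top-view pot images.
    Returns NaN (with a warning) when no plant tissue is present at all.
    """
    if vital < 0 or necrotic < 0:
        raise ValueError("areas must be non-negative")
    total = vital + necrotic
    if total == 0:
        warnings.warn("no plant tissue detected; vitality undefined", stacklevel=2)
        return float("nan")
    return 100.0 * vital / total


def classify_tolerant(per_replicate_percents: Sequence[float]) -> bool:
    """Drought-tolerance call for a line: mean vital percentage across
    replicates strictly greater than 50%.  Ties at exactly 50% are called
    non-tolerant."""
    vals = [v for v in per_replicate_percents if not np.isnan(v)]
    if not vals:
        raise ValueError("no replicate vitality values provided")
    return float(np.mean(vals)) > 50.0


def compute_water_series(
    weights_by_day: Mapping[float, float],
    dry_weight: float,
    target_days: Sequence[float],
) -> pd.DataFrame:
    """Interpolate pot weights onto photo days and derive water content.

    Weights between measurement days are piecewise-linearly interpolated;
    days outside the measured range are linearly extrapolated from the two
    nearest measurements (weights and photos were taken on successive
    days, so extrapolation spans at most about one day in practice — a
    warning is issued beyond one inter-measurement interval).  Water
    content is weight minus dry weight; cumulative water loss on a day is
    the initial (saturated) weight minus the interpolated weight.
    """
    if len(weights_by_day) < 2:
        raise ValueError("need at least two weighings to interpolate")
    days = np.array(sorted(weights_by_day))
    weights = np.array([weights_by_day[d] for d in days], dtype=float)
    if dry_weight > weights.min():
        raise ValueError("dry weight exceeds a measured weight")

    def interp(day: float) -> float:
        if day <= days[0]:
            lo, hi = 0, 1
        elif day >= days[-1]:
            lo, hi = -2, -1
        else:
            return float(np.interp(day, days, weights))
        slope = (weights[hi] - weights[lo]) / (days[hi] - days[lo])
        return float(weights[lo] + slope * (day - days[lo]))

    max_gap = float(np.diff(days).max())
    rows = []
    saturated = float(weights[0])
    for day in target_days:
        if day < days[0] - max_gap or day > days[-1] + max_gap:
            warnings.warn(
                f"day {day} is far outside the weighing range "
                f"[{days[0]}, {days[-1]}]; extrapolation is unreliable",
                stacklevel=2,
            )
        w = interp(day)
        rows.append(
            {
                "day": day,
                "weight": w,
                "water_content": max(w - dry_weight, 0.0),
                "cumulative_water_loss": saturated - w,
            }
        )
    return pd.DataFrame(rows)


def fit_water_model(table: pd.DataFrame) -> WaterModelFit:
    """Model cumulative water loss from plant line and size.

    Full model: ``water_loss ~ C(line) * vital_pixels`` by OLS with
    treatment coding; per-term significance by Type-II (marginal) F tests.
    Reduced model: ``water_loss ~ vital_pixels``.  The reduced model is the
    relevant summary when neither the line factor nor the interaction is
    significant, i.e. when all lines share one water-use-per-size law.
    """
    required = {"line", "vital_pixels", "water_loss"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.dropna(subset=list(required)).copy()
    n_lines = df["line"].nunique()
    if n_lines < 2:
        raise ValueError("need at least two lines for the full model")
    if (df.groupby("line").size() < 2).any():
        raise ValueError("need at least two observations per line")
    full = smf.ols("water_loss ~ C(line) * vital_pixels", data=df).fit()
    if full.df_resid <= 0 or np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient design for C(line) * vital_pixels")
    anova = sm.stats.anova_lm(full, typ=2)
    term_pvalues = {
        term.strip(): float(p)
        for term, p in anova["PR(>F)"].items()
        if term.strip() != "Residual"
    }
    reduced = smf.ols("water_loss ~ vital_pixels", data=df).fit()
    ci = reduced.conf_int().loc["vital_pixels"]
    return WaterModelFit(
        r_squared=float(full.rsquared),
        f_pvalue=float(full.f_pvalue),
        term_pvalues=term_pvalues,
        params=full.params,
        reduced_slope=float(reduced.params["vital_pixels"]),
        reduced_intercept=float(reduced.params["Intercept"]),
        reduced_r_squared=float(reduced.rsquared),
        reduced_slope_ci=(float(ci[0]), float(ci[1])),
        reduced_pvalue=float(reduced.pvalues["vital_pixels"]),
    )


def disc_linearity_check(
    disc_counts: pd.DataFrame,
) -> dict[str, dict[str, float]]:
    """Regress measured pixel counts on the known number of leaf discs.

    ``disc_counts`` must have columns ``k_vital, k_necrotic, vital,
    necrotic`` (one row per image).  For each tissue class, pixel counts
    are regressed on the disc count; a reliable classifier gives slope
    close to the single-disc area, intercept close to 0 and R^2 near 1.
    """
    out: dict[str, dict[str, float]] = {}
    for cls, kcol in (("vital", "k_vital"), ("necrotic", "k_necrotic")):
        k = disc_counts[kcol].to_numpy(dtype=float)
        y = disc_counts[cls].to_numpy(dtype=float)
        if np.unique(k).size < 2:
            raise ValueError(f"cannot regress {cls}: only one disc count present")
        res = scipy.stats.linregress(k, y)
        out[cls] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "pvalue": float(res.pvalue),
        }
    return out
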