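"""Weighted calibration-curve regression and back-calculation statistics.

Bioanalytical calibration relates the analyte/internal-standard peak-area
ratio (y) to nominal concentration x through a straight line ``y = a x + b``.
Because replicate variance grows with concentration, the fit is usually
weighted by ``1/x``; detection and quantification limits follow from the
intercept's standard error and the slope::

    LOD = 3.3 * SD(b) / a        LOQ = 10 * SD(b) / a

Back-calculated standards are then summarised per level (mean, SD, %RSD,
accuracy as %RE, recovery) the way validation reports tabulate them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from microstab.validation import accuracy_re, precision_rsd

Weighting = Literal["none", "one_over_x"]

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    """A single calibration observation: nominal level and response ratio."""

    nominal: float
    response: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError(f"nominal concentration must be > 0, got {self.nominal}")


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted calibration line with its sensitivity limits.

    ``r_squared`` is the weighted coefficient of determination
    (1 − weighted RSS / weighted TSS); ``sd_intercept`` is the standard
    error of the intercept from the same fit, unless overridden by the
    multi-curve mode of :func:`fit_weighted_line`.
    """

    slope: float
    intercept: float
    r_squared: float
    weighting: Weighting
    sd_intercept: float
    lod: float
    loq: float
    n_levels: int = 0

    def predict(self, nominal: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(nominal, dtype=float) + self.intercept


def _as_arrays(points: Iterable[CalibrationPoint] | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        x = points["nominal"].to_numpy(dtype=float)
        y = points["response"].to_numpy(dtype=float)
    else:
        pts = list(points)
        x = np.array([p.nominal for p in pts], dtype=float)
        y = np.array([p.response for p in pts], dtype=float)
    if (x <= 0).any():
        raise ValueError("nominal concentrations must be strictly positive")
    return x, y


def fit_weighted_line(
    points: Iterable[CalibrationPoint] | pd.DataFrame,
    weighting: Weighting = "one_over_x",
    sd_intercept_override: float | None = None,
) -> CalibrationFit:
    """Fit ``y = a x + b`` by (optionally 1/x-weighted) least squares.

    Parameters
    ----------
    points
        Calibration observations, or a DataFrame with ``nominal`` and
        ``response`` columns.
    weighting
        ``"one_over_x"`` (default, the usual choice when replicate SD grows
        with concentration) or ``"none"`` for ordinary least squares.
    sd_intercept_override
        Replaces the single-fit intercept standard error, e.g. with the SD
        of intercepts across replicate calibration curves (see
        :func:`intercept_sd_across_fits`); the LOD/LOQ are recomputed from it.

    Raises
    ------
    ValueError
        Fewer than 3 distinct nominal levels, or a singular design (all
        levels identical).
    """
    x, y = _as_arrays(points)
    if np.unique(x).size < 3:
        raise ValueError(f"need >= 3 distinct nominal levels, got {np.unique(x).size}")
    if weighting not in ("none", "one_over_x"):
        raise ValueError(f"unknown weighting {weighting!r}")
    w = 1.0 / x if weighting == "one_over_x" else np.ones_like(x)
    design = sm.add_constant(x)
    res = sm.WLS(y, design, weights=w).fit()
    intercept, slope = res.params
    sd_b = float(res.bse[0]) if sd_intercept_override is None else float(sd_intercept_override)
    lod, loq = lod_loq(sd_b, slope) if slope > 0 else (float("nan"), float("nan"))
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        weighting=weighting,
        sd_intercept=sd_b,
        lod=lod,
        loq=loq,
        n_levels=int(np.unique(x).size),
    )


def intercept_sd_across_fits(fits: Sequence[CalibrationFit]) -> float:
    """Sample SD of the intercepts of replicate calibration curves.

    Twelve-set calibration designs permit estimating intercept variability
    across curves instead of from a single curve's standard error; pass the
    result back through ``sd_intercept_override``.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to estimate intercept SD")
    return float(np.std([f.intercept for f in fits], ddof=1))


def back_calculate(fit: CalibrationFit, response: float | np.ndarray) -> np.ndarray | float:
    """Invert the calibration line: ``(response - b) / a``.

    Negative results are returned as-is (flagging is the caller's concern);
    clipping them would bias low-level statistics.
    """
    if fit.slope == 0:
        raise ValueError("cannot back-calculate with zero slope")
    out = (np.asarray(response, dtype=float) - fit.intercept) / fit.slope
    return float(out) if out.ndim == 0 else out


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from intercept SD and slope."""
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if sd_intercept < 0:
        raise ValueError(f"sd_intercept must be >= 0, got {sd_intercept}")
    return LOD_MULTIPLIER * sd_intercept / slope, LOQ_MULTIPLIER * sd_intercept / slope


def per_level_statistics(back_calculated: pd.DataFrame, nominals: Sequence[float] | None = None) -> pd.DataFrame:
    """Per-level back-calculation summary plus the overall mean recovery.

    Parameters
    ----------
    back_calculated
        Long table with columns ``nominal`` and ``value`` (back-calculated
        ng/mL), one row per replicate.
    nominals
        Levels expected in the run; levels absent from the data are reported
        with NaN statistics rather than imputed.

    Returns
    -------
    DataFrame indexed by level with columns ``mean``, ``sd``, ``rsd_percent``,
    ``accuracy_percent`` (%RE), ``recovery_percent`` and ``n``; the overall
    arithmetic mean of per-level recoveries is stored in
    ``df.attrs["overall_recovery_percent"]`` (with its SD under
    ``"overall_recovery_sd"``).
    """
    expected = sorted(set(nominals)) if nominals is not None else sorted(back_calculated["nominal"].unique())
    rows = []
    for level in expected:
        vals = back_calculated.loc[back_calculated["nominal"] == level, "value"].to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"nominal": level, "mean": np.nan, "sd": np.nan, "rsd_percent": np.nan,
                         "accuracy_percent": np.nan, "recovery_percent": np.nan, "n": 0})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rows.append(
            {
                "nominal": level,
                "mean": mean,
                "sd": sd,
                "rsd_percent": precision_rsd(sd, mean) if vals.size > 1 else np.nan,
                "accuracy_percent": accuracy_re(mean, level),
                "recovery_percent": accuracy_re(mean, level) + 100.0,
                "n": int(vals.size),
            }
        )
    table = pd.DataFrame(rows).set_index("nominal")
    recoveries = table["recovery_percent"].dropna()
    table.attrs["overall_recovery_percent"] = float(recoveries.mean()) if len(recoveries) else np.nan
    table.attrs["overall_recovery_sd"] = float(recoveries.std(ddof=1)) if len(recoveries) > 1 else np.nan
    return table
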