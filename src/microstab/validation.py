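"""FDA-style bioanalytical validation metrics.

Accuracy is reported as percent relative error (%RE), precision as percent
relative standard deviation (%RSD), extraction recovery as the extracted /
neat response ratio, and matrix effect (ME) as the matrix / neat response
ratio, all on the percent scale:

    %RE       = 100 * (mean - nominal) / nominal
    %RSD      = 100 * SD / mean
    recovery% = 100 * extracted / neat
    ME%       = 100 * matrix-group mean / neat-group mean

The internal-standard-normalised matrix effect divides the analyte's ME by
the internal standard's (a value near 1 means the matrix shifts both alike).
Stability of QC samples across storage conditions passes when both |%RE| and
%RSD stay within configurable limits (±15% by convention, ±20% at the LLOQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_RE_LIMIT = 15.0
DEFAULT_RSD_LIMIT = 15.0
DEFAULT_LLOQ_LIMIT = 20.0


@dataclass(frozen=True)
class QCBatch:
    """Replicate back-calculated measurements of one QC level."""

    level: float
    measurements: tuple[float, ...]
    scope: str = "intra_day"

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise ValueError(f"QC level must be > 0, got {self.level}")
        if len(self.measurements) == 0:
            raise ValueError("QCBatch requires at least one measurement")


@dataclass(frozen=True)
class ValidationMetrics:
    """Summary metrics for one QC level; recovery% = %RE + 100 by construction."""

    mean: float
    sd: float
    rsd_percent: float
    re_percent: float
    recovery_percent: float
    pass_flag: bool


@dataclass(frozen=True)
class MatrixEffectResult:
    me_analyte_percent: float
    me_is_percent: float
    is_normalized_me: float


@dataclass(frozen=True)
class AcceptanceRules:
    """Pass/fail limits; the LLOQ level gets the wider limit."""

    re_limit: float = DEFAULT_RE_LIMIT
    rsd_limit: float = DEFAULT_RSD_LIMIT
    lloq_re_limit: float = DEFAULT_LLOQ_LIMIT
    lloq_rsd_limit: float = DEFAULT_LLOQ_LIMIT
    lloq_level: float | None = None
    blank_signal_fraction: float = 0.2

    def limits_for(self, level: float) -> tuple[float, float]:
        if self.lloq_level is not None and np.isclose(level, self.lloq_level):
            return self.lloq_re_limit, self.lloq_rsd_limit
        return self.re_limit, self.rsd_limit


def accuracy_re(mean: float, nominal: float) -> float:
    """Percent relative error of a measured mean against its nominal value."""
    if nominal <= 0:
        raise ValueError(f"nominal must be > 0, got {nominal}")
    return 100.0 * (mean - nominal) / nominal


def precision_rsd(sd: float, mean: float) -> float:
    """Percent relative standard deviation (coefficient of variation x 100)."""
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    return 100.0 * sd / mean


def recovery_percent(extracted_mean: float, neat_mean: float) -> float:
    """Extraction recovery: extracted response as a percentage of the neat response."""
    if neat_mean <= 0:
        raise ValueError(f"neat mean must be > 0, got {neat_mean}")
    return 100.0 * extracted_mean / neat_mean


def matrix_effect(group1_mean: float, group2_mean: float) -> float:
    """Matrix effect: matrix-cohort mean response ratio over neat-cohort, x 100."""
    if group2_mean <= 0:
        raise ValueError(f"neat-group mean must be > 0, got {group2_mean}")
    return 100.0 * group1_mean / group2_mean


def is_normalized_me(me_analyte: float, me_is: float) -> float:
    """Analyte matrix effect normalised by the internal standard's."""
    if me_is <= 0:
        raise ValueError(f"internal-standard ME must be > 0, got {me_is}")
    return me_analyte / me_is


def summarize_batch(batch: QCBatch, rules: AcceptanceRules | None = None) -> ValidationMetrics:
    """Mean/SD/%RSD/%RE for one QC batch with its pass flag."""
    rules = rules or AcceptanceRules()
    vals = np.asarray(batch.measurements, dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    re = accuracy_re(mean, batch.level)
    rsd = precision_rsd(sd, mean) if mean > 0 else float("inf")
    re_limit, rsd_limit = rules.limits_for(batch.level)
    return ValidationMetrics(
        mean=mean,
        sd=sd,
        rsd_percent=rsd,
        re_percent=re,
        recovery_percent=re + 100.0,
        pass_flag=bool(abs(re) <= re_limit and rsd <= rsd_limit),
    )


def stability_assess(
    batches: Sequence[QCBatch],
    re_limit: float = DEFAULT_RE_LIMIT,
    rsd_limit: float = DEFAULT_RSD_LIMIT,
) -> pd.DataFrame:
    """Stability table across storage conditions.

    Each batch's ``scope`` names its condition (freeze-thaw, short-term,
    long-term, auto-sampler ...).  A condition/level passes when |%RE| <=
    ``re_limit`` and %RSD <= ``rsd_limit``.
    """
    if re_limit <= 0 or rsd_limit <= 0:
        raise ValueError("acceptance limits must be > 0")
    if not batches:
        raise ValueError("no batches supplied")
    rules = AcceptanceRules(re_limit=re_limit, rsd_limit=rsd_limit)
    rows = []
    for b in batches:
        m = summarize_batch(b, rules)
        rows.append(
            {
                "condition": b.scope,
                "level": b.level,
                "mean": m.mean,
                "sd": m.sd,
                "rsd_percent": m.rsd_percent,
                "accuracy_percent": m.re_percent,
                "pass": m.pass_flag,
            }
        )
    return pd.DataFrame(rows)


def specificity_check(blank_response: float, lloq_response: float, max_fraction: float = 0.2) -> bool:
    """Carryover/specificity gate: blank signal must stay below a fraction of the LLOQ response."""
    if lloq_response <= 0:
        raise ValueError("LLOQ response must be > 0")
    return blank_response <= max_fraction * lloq_response


@dataclass
class ValidationReport:
    """Consolidated validation outcome; every metric is traceable to its operation."""

    qc_metrics: Mapping[str, ValidationMetrics]
    out_of_range_levels: tuple[float, ...] = ()
    matrix: MatrixEffectResult | None = None
    stability: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(m.pass_flag for m in self.qc_metrics.values()) and not self.out_of_range_levels


def validate_run(
    qc_batches: Sequence[QCBatch],
    rules: AcceptanceRules | None = None,
    calibration_range: tuple[float, float] | None = None,
) -> ValidationReport:
    """Aggregate QC batches into one consolidated report.

    QC levels outside the calibration range are flagged (quantification is
    extrapolation there), not silently accepted.
    """
    rules = rules or AcceptanceRules()
    metrics: dict[str, ValidationMetrics] = {}
    out_of_range: list[float] = []
    for b in qc_batches:
        key = f"{b.scope}:{b.level:g}"
        metrics[key] = summarize_batch(b, rules)
        if calibration_range is not None and not (calibration_range[0] <= b.level <= calibration_range[1]):
            out_of_range.append(b.level)
    return ValidationReport(qc_metrics=metrics, out_of_range_levels=tuple(out_of_range))
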