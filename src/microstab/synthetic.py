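"""Seeded generators for virtual bioanalytical experiments.

These emulate the data products of an LC-MS/MS microsomal-stability study:
calibration plates (analyte and internal-standard peak responses at a ladder
of nominal concentrations), QC batches, matrix-effect cohorts, and
substrate-depletion time courses.  Replicate scatter follows a two-component
noise model — a proportional (constant-CV) term plus an additive floor —
truncated at zero, which matches the symmetric per-level SDs bioanalytical
tables report.

Every generator takes an explicit :class:`NoiseModel` carrying the seed; the
same (configuration, seed) pair always reproduces the identical table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default quench/sampling grid for depletion incubations, in minutes.
DEFAULT_TIME_GRID = (0.0, 2.5, 7.5, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-scatter model: ``value * (1 + eps_prop) + eps_add``, floored at 0.

    Parameters
    ----------
    proportional_cv
        Coefficient of variation of the multiplicative Gaussian term
        (fraction, e.g. ``0.03`` for 3%).
    additive_sd
        Standard deviation of the additive Gaussian term, in response units.
    seed
        Seed for the generator stream.  Mandatory — there is no hidden
        global random state.
    """

    proportional_cv: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0:
            raise ValueError(f"proportional_cv must be >= 0, got {self.proportional_cv}")
        if self.additive_sd < 0:
            raise ValueError(f"additive_sd must be >= 0, got {self.additive_sd}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb expected values; negative results are truncated to zero."""
        expected = np.asarray(expected, dtype=float)
        noisy = expected * (1.0 + rng.normal(0.0, self.proportional_cv, expected.shape))
        noisy = noisy + rng.normal(0.0, self.additive_sd, expected.shape)
        return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class DepletionModel:
    """First-order depletion with an optional metabolism-resistant floor.

    The expected concentration at time ``t`` (minutes) is::

        C(t) = c0 * (resistant_fraction + (1 - resistant_fraction) * exp(-k t))

    ``resistant_fraction`` reproduces the late-incubation plateau real
    depletion curves show (enzyme exhaustion / a non-metabolised pool);
    downstream analysis handles it by restricting the log-linear fit window
    rather than by modelling it.
    """

    c0: float = 466.85
    k: float = 0.0297
    resistant_fraction: float = 0.0
    time_points: tuple[float, ...] = DEFAULT_TIME_GRID

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError(f"resistant_fraction must be in [0, 1], got {self.resistant_fraction}")
        if len(self.time_points) == 0:
            raise ValueError("time_points must not be empty")

    def concentration(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0 * (self.resistant_fraction + (1.0 - self.resistant_fraction) * np.exp(-self.k * t))


@dataclass(frozen=True)
class AssayDesign:
    """Layout of a calibration/QC plate and its true response line.

    Default levels follow a seven-point ladder spanning 1–3,000 ng/mL with
    four QC levels (LLOQ, low, mid, high); ``true_slope``/``true_intercept``
    define the noiseless analyte response ``a * level + b`` and
    ``is_nominal`` the internal-standard spiking concentration.  The default
    intercept is small and positive so the lowest standard keeps a physical
    (non-negative) response under the zero-floor noise truncation.
    """

    calibration_levels: tuple[float, ...] = (1.0, 15.0, 50.0, 300.0, 500.0, 1500.0, 3000.0)
    qc_levels: tuple[float, ...] = (1.0, 3.0, 900.0, 2400.0)
    replicates: int = 6
    true_slope: float = 1.4212
    true_intercept: float = 0.5
    is_nominal: float = 1000.0
    is_response: float = 1.0

    def __post_init__(self) -> None:
        for name, levels in (("calibration_levels", self.calibration_levels), ("qc_levels", self.qc_levels)):
            arr = np.asarray(levels, dtype=float)
            if arr.size and (arr <= 0).any():
                raise ValueError(f"{name} must be strictly positive, got {levels}")
            if arr.size > 1 and (np.diff(arr) <= 0).any():
                raise ValueError(f"{name} must be strictly increasing, got {levels}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def _response_table(levels: np.ndarray, design: AssayDesign, noise: NoiseModel, rng: np.random.Generator) -> pd.DataFrame:
    levels = np.asarray(levels, dtype=float)
    if (levels <= 0).any():
        raise ValueError("concentration levels must be strictly positive")
    level_col = np.repeat(levels, design.replicates)
    rep_col = np.tile(np.arange(1, design.replicates + 1), levels.size)
    expected = design.true_slope * level_col + design.true_intercept
    analyte = noise.apply(expected, rng)
    is_resp = noise.apply(np.full_like(level_col, design.is_response), rng)
    return pd.DataFrame(
        {
            "level_ng_per_ml": level_col,
            "replicate": rep_col,
            "analyte_response": analyte,
            "is_response": is_resp,
        }
    )


def generate_calibration_run(design: AssayDesign, noise: NoiseModel) -> pd.DataFrame:
    """One calibration plate: one row per (level, replicate).

    Returns a table with columns ``level_ng_per_ml``, ``replicate``,
    ``analyte_response`` and ``is_response``.  With zero noise the analyte
    responses fall exactly on ``true_slope * level + true_intercept``.
    """
    return _response_table(np.asarray(design.calibration_levels), design, noise, noise.rng())


def generate_qc_run(design: AssayDesign, noise: NoiseModel) -> pd.DataFrame:
    """A QC batch at the design's QC levels, same schema as the calibration run."""
    return _response_table(np.asarray(design.qc_levels), design, noise, noise.rng())


def generate_depletion_timecourse(model: DepletionModel, noise: NoiseModel, replicates: int = 3) -> "pd.DataFrame":
    """Replicate depletion measurements on the model's time grid.

    Returns a long table (``time_min``, ``replicate``, ``conc_ng_per_ml``);
    with zero noise every replicate equals the model curve.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    times = np.asarray(model.time_points, dtype=float)
    rng = noise.rng()
    expected = np.repeat(model.concentration(times), replicates)
    return pd.DataFrame(
        {
            "time_min": np.repeat(times, replicates),
            "replicate": np.tile(np.arange(1, replicates + 1), times.size),
            "conc_ng_per_ml": noise.apply(expected, rng),
        }
    )


def generate_matrix_effect_groups(
    design: AssayDesign, me_factor: float, noise: NoiseModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two cohorts for a matrix-effect experiment.

    Group 1 (biological matrix) has expected responses ``me_factor`` times
    those of group 2 (neat solvent), so the downstream matrix-effect ratio
    recovers ``100 * me_factor`` in expectation.
    """
    if me_factor <= 0:
        raise ValueError(f"me_factor must be > 0, got {me_factor}")
    rng = noise.rng()
    levels = np.asarray(design.qc_levels)
    neat = _response_table(levels, design, noise, rng)
    matrix = _response_table(levels, design, noise, rng)
    matrix["analyte_response"] *= me_factor
    return matrix, neat
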