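import numpy as np
import pytest

from microstab import datasets
from microstab.kinetics import DepletionTimeCourse


@pytest.fixture(scope="session")
def depletion_course() -> DepletionTimeCourse:
    """Worked-example depletion course (mean of three incubations, 0-70 min)."""
    return DepletionTimeCourse.from_replicates(datasets.load_depletion_timecourse())


@pytest.fixture(scope="session")
def level_summary():
    """Seven-level calibration back-calculation summary (nominal, mean, SD)."""
    return datasets.load_calibration_level_summary()


@pytest.fixture(scope="session")
def greenness_table():
    return datasets.load_greenness_scores()


def ols_normal_equations(x, y, w=None):
    """Independent least-squares oracle: solve the normal equations on sqrt(w)-scaled data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    b, a = np.linalg.solve(design.T @ design, design.T @ (sw * y))
    return float(a), float(b)
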