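"""Worked-example datasets from a published HLM metabolic-stability study.

The tables transcribe the reported results for CEP-37440, an ALK/FAK2
inhibitor, quantified by LC-MS/MS in human liver microsomes: per-level
calibration back-calculation summaries, QC precision/accuracy batches,
storage-stability summaries, the twelve analytical-greenness criterion
scores, and the substrate-depletion time course (mean of three replicate
incubations at each quench time).  They serve as compact end-to-end inputs
for examples and regression tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from microstab.io import (
    GREENNESS_SCHEMA,
    LEVEL_SUMMARY_SCHEMA,
    TIMECOURSE_SCHEMA,
    TableSchema,
    read_table,
)

_QC_SUMMARY_SCHEMA = TableSchema(
    name="qc_summary",
    numeric_columns=("level_ng_per_ml", "mean_ng_per_ml", "sd_ng_per_ml"),
    other_columns=("scope",),
)

_STABILITY_SCHEMA = TableSchema(
    name="stability_summary",
    numeric_columns=("level_ng_per_ml", "mean_ng_per_ml", "sd_ng_per_ml"),
    other_columns=("condition",),
)


def _path(name: str):
    return resources.files("microstab.data").joinpath(name)


def load_depletion_timecourse() -> pd.DataFrame:
    """Depletion course 0-70 min: mean concentration (ng/mL) per quench time."""
    with resources.as_file(_path("depletion_timecourse.csv")) as p:
        return read_table(p, TIMECOURSE_SCHEMA)


def load_calibration_level_summary() -> pd.DataFrame:
    """Seven-level calibration back-calculation summary (nominal, mean, SD in ng/mL)."""
    with resources.as_file(_path("calibration_level_summary.csv")) as p:
        return read_table(p, LEVEL_SUMMARY_SCHEMA)


def load_qc_precision_accuracy() -> pd.DataFrame:
    """Intra-/inter-day QC summaries at the four QC levels."""
    with resources.as_file(_path("qc_precision_accuracy.csv")) as p:
        return read_table(p, _QC_SUMMARY_SCHEMA)


def load_stability_summary() -> pd.DataFrame:
    """QC mean/SD summaries across four storage conditions at LQC and HQC."""
    with resources.as_file(_path("stability_summary.csv")) as p:
        return read_table(p, _STABILITY_SCHEMA)


def load_greenness_scores() -> pd.DataFrame:
    """Twelve greenness criterion scores and weights (the unreported weight defaults to 1)."""
    with resources.as_file(_path("greenness_scores.csv")) as p:
        return read_table(p, GREENNESS_SCHEMA)
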