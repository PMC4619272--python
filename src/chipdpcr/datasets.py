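"""Bundled reference tables from the validation experiments this package models.

See ``chipdpcr/data/README.md`` for transcription notes. Each loader
returns a pandas DataFrame; :func:`load_reference_results` can also
return parsed :class:`~chipdpcr.poisson_quant.ChipResult` objects.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_results_csv
from .poisson_quant import ChipResult

_DATASETS = {
    "plasma": "plasma_results.csv",
    "cells": "cell_results.csv",
    "pdx": "pdx_results.csv",
}


def _data_path(name: str):
    return resources.files("chipdpcr.data") / name


def load_detection_efficiency() -> pd.DataFrame:
    """Serial-dilution detection-efficiency table (six five-fold points).

    Columns: ``dilution``, ``expected_copies_per_ul``,
    ``observed_copies_per_ul``, ``reported_efficiency_pct`` (the source's
    printed integer percentages).
    """
    with resources.as_file(_data_path("detection_efficiency.csv")) as p:
        return pd.read_csv(p)


def load_reference_results(
    which: str, as_objects: bool = False
) -> pd.DataFrame | list[ChipResult]:
    """Per-chip result tables for ``"plasma"``, ``"cells"`` or ``"pdx"``."""
    if which not in _DATASETS:
        raise KeyError(f"unknown dataset {which!r}; choose from {sorted(_DATASETS)}")
    with resources.as_file(_data_path(_DATASETS[which])) as p:
        if as_objects:
            return read_results_csv(p)
        return pd.read_csv(p)


def load_replicate_cv() -> pd.DataFrame:
    """Per-sample intra-run and inter-run CVs of miR-16-5p duplicates."""
    with resources.as_file(_data_path("replicate_cv.csv")) as p:
        return pd.read_csv(p)
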