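"""CSV input/output.

Two dialects cross the package boundary:

* Partition exports — one row per reaction well:
  ``chip_id, well_index, fam, vic, quality`` (0-based well order). The
  call writer appends a ``call`` column with the exact strings ``FAM``,
  ``VIC``, ``FAM+VIC``, ``NOT_AMPLIFIED``, ``EXCLUDED``.
* Result tables — one row per chip, mirroring the published result
  tables: ``sample, assay, spike_copies_per_ul, spike_ci_low,
  spike_ci_high, target_copies_per_ul, target_ci_low, target_ci_high,
  valid_points, total_points[, qc_pass, dilution_factor, chip_id]``.

Decimal commas (the convention of the source tables) are accepted on
input and normalized to decimal points on output. Dilution bookkeeping
embedded in sample labels — ``(1:5)``, ``1:10``, and their combination —
is parsed into a single multiplicative factor.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip_model import (
    DEFAULT_MIN_VALID_PARTITIONS,
    Chip,
    ClassificationResult,
    QCResult,
)
from .exceptions import SchemaError
from .poisson_quant import ChipResult, ConcentrationEstimate, NormalizedResult

PARTITION_COLUMNS = ["chip_id", "well_index", "fam", "vic", "quality"]
RESULT_COLUMNS = [
    "sample",
    "assay",
    "spike_copies_per_ul",
    "spike_ci_low",
    "spike_ci_high",
    "target_copies_per_ul",
    "target_ci_low",
    "target_ci_high",
    "valid_points",
    "total_points",
]

_DILUTION_RE = re.compile(r"\(?1\s*:\s*(\d+(?:[.,]\d+)?)\)?")


def parse_dilution_factor(sample_label: str) -> float:
    """Multiply every ``1:N`` dilution step found in a sample label.

    ``"PL 0 (1:5) 1:10"`` -> 50; a label with no step -> 1.
    """
    factor = 1.0
    for m in _DILUTION_RE.finditer(sample_label):
        factor *= float(m.group(1).replace(",", "."))
    return factor


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    """Coerce a column to float, tolerating decimal commas; report bad rows."""
    s = df[column]
    if s.dtype == object:
        s = s.astype(str).str.strip().str.replace(",", ".", regex=False)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        lines = [i + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise SchemaError(
            f"{path}: column {column!r} has non-numeric values at line(s) {lines}"
        )
    return out.astype(float)


def read_partition_csv(
    path: str | Path,
    sample_id: str | None = None,
    target_assay: str = "target",
    spike_assay: str = "cel-mir-39",
    dilution_factor: float | None = None,
) -> Chip:
    """Load one chip's partition export.

    Chip metadata beyond ``chip_id`` is not part of the export; supply it
    via the keyword arguments (the dilution factor defaults to whatever
    :func:`parse_dilution_factor` finds in ``sample_id``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PARTITION_COLUMNS, path)
    if len(df) == 0:
        raise SchemaError(f"{path}: no partition rows")
    chip_ids = df["chip_id"].unique()
    if len(chip_ids) != 1:
        raise SchemaError(f"{path}: expected one chip_id, found {list(chip_ids)}")
    idx = _numeric(df, "well_index", path).astype(int)
    order = np.argsort(idx.to_numpy(), kind="stable")
    sample = sample_id if sample_id is not None else str(chip_ids[0])
    if dilution_factor is None:
        dilution_factor = parse_dilution_factor(sample)
    return Chip(
        chip_id=str(chip_ids[0]),
        sample_id=sample,
        target_assay=target_assay,
        spike_assay=spike_assay,
        dilution_factor=dilution_factor,
        fam=_numeric(df, "fam", path).to_numpy()[order],
        vic=_numeric(df, "vic", path).to_numpy()[order],
        quality=_numeric(df, "quality", path).to_numpy()[order],
    )


def write_partition_csv(chip: Chip, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chip_id": chip.chip_id,
            "well_index": np.arange(len(chip)),
            "fam": chip.fam,
            "vic": chip.vic,
            "quality": chip.quality,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_calls_csv(
    chip: Chip, classification: ClassificationResult, path: str | Path
) -> None:
    """Partition export plus the per-well ``call`` column."""
    df = pd.DataFrame(
        {
            "chip_id": chip.chip_id,
            "well_index": np.arange(len(chip)),
            "fam": chip.fam,
            "vic": chip.vic,
            "quality": chip.quality,
            "call": classification.labels(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_results_csv(results: Iterable[ChipResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample_id,
                "assay": r.target_assay,
                "spike_copies_per_ul": r.spike.copies_per_ul,
                "spike_ci_low": r.spike.ci_low,
                "spike_ci_high": r.spike.ci_high,
                "target_copies_per_ul": r.target.copies_per_ul,
                "target_ci_low": r.target.ci_low,
                "target_ci_high": r.target.ci_high,
                "valid_points": r.spike.n_valid,
                "total_points": r.total_points
                if r.total_points is not None
                else r.spike.n_valid,
                "qc_pass": r.qc.passed,
                "dilution_factor": r.dilution_factor,
                "chip_id": r.chip_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_results_csv(
    path: str | Path,
    min_valid: int = DEFAULT_MIN_VALID_PARTITIONS,
    spike_assay: str = "cel-mir-39",
) -> list[ChipResult]:
    """Load a per-chip result table into :class:`ChipResult` objects.

    ``qc_pass`` and ``dilution_factor`` are recomputed/parsed when absent
    (published tables do not print them). Positive-partition counts are
    not recoverable from a result table, so the estimates carry ``None``
    there.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, RESULT_COLUMNS, path)
    numeric_cols = RESULT_COLUMNS[2:]
    for c in numeric_cols:
        df[c] = _numeric(df, c, path)
    out: list[ChipResult] = []
    for i, row in df.iterrows():
        sample = str(row["sample"])
        assay = str(row["assay"])
        n_valid = int(row["valid_points"])
        if "dilution_factor" in df.columns and pd.notna(row["dilution_factor"]):
            dilution = float(row["dilution_factor"])
        else:
            dilution = parse_dilution_factor(sample)
        chip_id = (
            str(row["chip_id"])
            if "chip_id" in df.columns and pd.notna(row["chip_id"])
            else f"{sample}/{assay}"
        )
        try:
            spike = ConcentrationEstimate(
                channel="VIC",
                n_valid=n_valid,
                copies_per_ul=float(row["spike_copies_per_ul"]),
                ci_low=float(row["spike_ci_low"]),
                ci_high=float(row["spike_ci_high"]),
            )
            target = ConcentrationEstimate(
                channel="FAM",
                n_valid=n_valid,
                copies_per_ul=float(row["target_copies_per_ul"]),
                ci_low=float(row["target_ci_low"]),
                ci_high=float(row["target_ci_high"]),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: line {i + 2}: {e}") from e
        out.append(
            ChipResult(
                chip_id=chip_id,
                sample_id=sample,
                target_assay=assay,
                spike_assay=spike_assay,
                dilution_factor=dilution,
                spike=spike,
                target=target,
                qc=QCResult(n_valid=n_valid, threshold=min_valid),
                total_points=int(row["total_points"]),
            )
        )
    return out


def results_to_frame(results: Sequence[ChipResult]) -> pd.DataFrame:
    """Tabular view of chip results (the results-CSV schema as a DataFrame)."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample": r.sample_id,
                "assay": r.target_assay,
                "spike_copies_per_ul": r.spike.copies_per_ul,
                "spike_ci_low": r.spike.ci_low,
                "spike_ci_high": r.spike.ci_high,
                "target_copies_per_ul": r.target.copies_per_ul,
                "target_ci_low": r.target.ci_low,
                "target_ci_high": r.target.ci_high,
                "valid_points": r.spike.n_valid,
                "total_points": r.total_points
                if r.total_points is not None
                else r.spike.n_valid,
                "qc_pass": r.qc.passed,
                "dilution_factor": r.dilution_factor,
                "chip_id": r.chip_id,
            }
        )
    return pd.DataFrame(rows)


def write_normalized_csv(
    results: Iterable[NormalizedResult], path: str | Path
) -> None:
    rows = [
        {
            "chip_id": n.chip_id,
            "sample": n.sample_id,
            "assay": n.target_assay,
            "raw_copies_per_ul": n.raw_copies_per_ul,
            "normalization_factor": n.normalization_factor,
            "dilution_factor": n.dilution_factor,
            "normalized_copies_per_ul": n.normalized_copies_per_ul,
        }
        for n in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def write_truth_csv(truths, path: str | Path) -> None:
    """Ground-truth sidecar for simulated chips."""
    rows = []
    for t in truths:
        rows.append(
            {
                "chip_id": t.chip_id,
                "channel": "FAM",
                "true_copies_per_ul": t.true_target_copies_per_ul,
                "seed": t.seed,
            }
        )
        rows.append(
            {
                "chip_id": t.chip_id,
                "channel": "VIC",
                "true_copies_per_ul": t.true_spike_copies_per_ul,
                "seed": t.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
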