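"""Method-validation statistics for a digital PCR assay.

Covers the four checks used to validate chip dPCR against expectation:
detection efficiency along a serial dilution, linearity of a fold
dilution, replicate precision as a coefficient of variation, and the
Pearson correlation between qPCR Ct values and absolute dPCR copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ChipDPCRError


@dataclass(frozen=True)
class DilutionSeriesSpec:
    """A geometric serial dilution: ``start / fold**k`` for k = 0..n-1."""

    start_copies_per_ul: float
    fold: float
    n_points: int

    def __post_init__(self):
        if self.start_copies_per_ul <= 0:
            raise ValueError("start concentration must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.n_points < 2:
            raise ValueError("a series needs >= 2 points")


@dataclass(frozen=True)
class EfficiencyRow:
    """One dilution point: expected vs observed copies/ul and efficiency %."""

    dilution_label: str
    expected_copies_per_ul: float
    observed_copies_per_ul: float
    efficiency_pct: int

    def __post_init__(self):
        if self.expected_copies_per_ul <= 0 or self.observed_copies_per_ul <= 0:
            raise ValueError("expected and observed must be > 0")


@dataclass(frozen=True)
class LinearityResult:
    """Undiluted/diluted ratios of a fold-dilution check."""

    assay: str
    pair_ratios: tuple[float, ...]
    mean_fold: float
    sd_fold: float
    nominal_fold: float
    sd_defined: bool = True


@dataclass(frozen=True)
class PrecisionResult:
    """Replicate precision: per-sample CVs and their average."""

    per_sample_cv: tuple[float, ...]
    average_cv: float
    mode: str  # "intra_run" | "inter_run"

    @property
    def average_cv_pct(self) -> int:
        """Average CV as an integer percent."""
        return round(self.average_cv * 100)


def expected_series(spec: DilutionSeriesSpec) -> np.ndarray:
    """Expected concentrations of a geometric serial dilution."""
    k = np.arange(spec.n_points)
    return spec.start_copies_per_ul / spec.fold**k


def detection_efficiency(expected: float, observed: float) -> int:
    """Integer percent relating theoretical input copies to measured copies.

    Computed as ``round(100 * expected / observed)`` — the direction that
    reproduces the published efficiency tables row by row (the conventional
    observed/expected does not).
    """
    if expected <= 0:
        raise ValueError("expected copies must be > 0")
    if observed <= 0:
        raise ChipDPCRError("no detected copies; efficiency undefined")
    return round(100.0 * expected / observed)


def efficiency_table(
    expected: Sequence[float],
    observed: Sequence[float],
    labels: Sequence[str] | None = None,
) -> list[EfficiencyRow]:
    """Apply :func:`detection_efficiency` along a dilution series."""
    if len(expected) != len(observed):
        raise ValueError("expected and observed must have equal length")
    if labels is None:
        labels = [f"D{i + 1}" for i in range(len(expected))]
    return [
        EfficiencyRow(
            dilution_label=lab,
            expected_copies_per_ul=float(e),
            observed_copies_per_ul=float(o),
            efficiency_pct=detection_efficiency(e, o),
        )
        for lab, e, o in zip(labels, expected, observed)
    ]


def dilution_linearity(
    pairs: Sequence[tuple[float, float]],
    nominal_fold: float,
    assay: str = "",
) -> LinearityResult:
    """Measured fold between undiluted and diluted runs of the same samples.

    Each pair contributes the ratio undiluted/diluted; the mean and the
    sample (n-1) standard deviation of those ratios summarize how close the
    dilution behaved to its nominal fold. A single pair has no spread; its
    sd is reported as 0 with ``sd_defined=False``.
    """
    if not pairs:
        raise ValueError("need >= 1 pair")
    ratios = []
    for undiluted, diluted in pairs:
        if diluted <= 0 or undiluted <= 0:
            raise ChipDPCRError("non-positive concentration; ratio undefined")
        ratios.append(undiluted / diluted)
    arr = np.asarray(ratios)
    sd_defined = arr.size >= 2
    return LinearityResult(
        assay=assay,
        pair_ratios=tuple(float(r) for r in ratios),
        mean_fold=float(arr.mean()),
        sd_fold=float(arr.std(ddof=1)) if sd_defined else 0.0,
        nominal_fold=float(nominal_fold),
        sd_defined=sd_defined,
    )


def coefficient_of_variation(replicates: Sequence[float]) -> float:
    """Sample (n-1) standard deviation over the mean of replicate measurements."""
    arr = np.asarray(replicates, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 replicates for a CV")
    mean = arr.mean()
    if mean == 0:
        raise ChipDPCRError("mean of replicates is 0; CV undefined")
    return float(arr.std(ddof=1) / mean)


def average_cv(
    per_sample: Sequence[float], mode: str = "intra_run"
) -> PrecisionResult:
    """Arithmetic mean of per-sample CVs, the assay-level precision figure."""
    if not len(per_sample):
        raise ValueError("need >= 1 per-sample CV")
    arr = np.asarray(per_sample, dtype=float)
    if (arr < 0).any():
        raise ValueError("CVs must be >= 0")
    return PrecisionResult(
        per_sample_cv=tuple(float(c) for c in arr),
        average_cv=float(arr.mean()),
        mode=mode,
    )


def ct_copy_correlation(
    ct_values: Sequence[float], copies: Sequence[float]
) -> float:
    """Pearson r between qPCR Ct values and dPCR absolute copies.

    Computed on the values as given (linear scale). Ct falls by one cycle
    per doubling of template, so against absolute copies the correlation is
    expected to be strongly negative. Reported by the CLI as a signed
    integer percent.
    """
    ct = np.asarray(ct_values, dtype=float)
    cp = np.asarray(copies, dtype=float)
    if ct.shape != cp.shape or ct.ndim != 1:
        raise ValueError("ct_values and copies must be equal-length 1-D")
    if ct.size < 3:
        raise ValueError("need >= 3 points for a correlation")
    if np.ptp(ct) == 0 or np.ptp(cp) == 0:
        raise ChipDPCRError("correlation undefined: constant input vector")
    r, _ = stats.pearsonr(ct, cp)
    return float(r)
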