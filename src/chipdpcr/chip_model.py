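"""Domain model for chip-based digital PCR data.

A chip carries ~20,000 fixed reaction wells ("partitions"). Each partition
reports end-point fluorescence on two channels — FAM for the target miRNA
assay and VIC for the cel-miR-39 spike-in — plus a per-well quality score in
[0, 1] assigned by the instrument. Partitions below the quality threshold
(0.5 by convention) are excluded; the rest are classified into four call
types by comparing each channel against a fluorescence threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import (
    EmptyChipError,
    NonFiniteIntensityError,
    ThresholdError,
)

#: Fixed well count of the chip geometry this package models.
NOMINAL_CHIP_WELLS = 20_000

#: Instrument convention: wells scoring below this are excluded.
DEFAULT_QUALITY_THRESHOLD = 0.5

#: Valid-partition count required for a chip to pass quality control.
DEFAULT_MIN_VALID_PARTITIONS = 10_000


class CallType(enum.IntEnum):
    """Four-way call for a valid partition, plus EXCLUDED for low quality."""

    NOT_AMPLIFIED = 0
    FAM_ONLY = 1
    VIC_ONLY = 2
    FAM_VIC = 3
    EXCLUDED = 4

    @property
    def label(self) -> str:
        """Exact string used in call-output CSVs and plot legends."""
        return _CALL_LABELS[self]


_CALL_LABELS = {
    CallType.NOT_AMPLIFIED: "NOT_AMPLIFIED",
    CallType.FAM_ONLY: "FAM",
    CallType.VIC_ONLY: "VIC",
    CallType.FAM_VIC: "FAM+VIC",
    CallType.EXCLUDED: "EXCLUDED",
}

LABEL_TO_CALL = {v: k for k, v in _CALL_LABELS.items()}


@dataclass(frozen=True)
class Partition:
    """One reaction well: two-channel fluorescence plus a quality score."""

    fam_intensity: float
    vic_intensity: float
    quality: float

    def __post_init__(self):
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"quality {self.quality} outside [0, 1]")
        for name, v in (("fam", self.fam_intensity), ("vic", self.vic_intensity)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} intensity must be finite and >= 0, got {v}")


@dataclass
class Chip:
    """A full chip: per-well arrays plus sample/assay/dilution metadata.

    ``fam``, ``vic`` and ``quality`` are equal-length 1-D arrays in well
    order. ``dilution_factor`` is the total multiplicative dilution applied
    to the specimen before loading (e.g. 50 for a 1:5 step followed by a
    1:10 step).
    """

    chip_id: str
    sample_id: str
    target_assay: str
    spike_assay: str
    dilution_factor: float
    fam: np.ndarray
    vic: np.ndarray
    quality: np.ndarray

    def __post_init__(self):
        self.fam = np.asarray(self.fam, dtype=float)
        self.vic = np.asarray(self.vic, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not (self.fam.shape == self.vic.shape == self.quality.shape):
            raise ValueError("fam, vic and quality must have identical shapes")
        if self.fam.ndim != 1:
            raise ValueError("partition arrays must be 1-D")
        if len(self.fam) > NOMINAL_CHIP_WELLS:
            raise ValueError(
                f"{len(self.fam)} partitions exceed chip capacity {NOMINAL_CHIP_WELLS}"
            )
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        q = self.quality
        finite_q = q[np.isfinite(q)]
        if finite_q.size and (finite_q.min() < 0 or finite_q.max() > 1):
            raise ValueError("quality scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.fam)

    @property
    def n_partitions(self) -> int:
        return len(self.fam)

    def partition(self, i: int) -> Partition:
        return Partition(float(self.fam[i]), float(self.vic[i]), float(self.quality[i]))

    def partitions(self) -> Iterator[Partition]:
        for i in range(len(self)):
            yield self.partition(i)

    @classmethod
    def from_partitions(
        cls,
        partitions: Sequence[Partition],
        *,
        chip_id: str = "chip",
        sample_id: str = "sample",
        target_assay: str = "target",
        spike_assay: str = "cel-mir-39",
        dilution_factor: float = 1.0,
    ) -> "Chip":
        return cls(
            chip_id=chip_id,
            sample_id=sample_id,
            target_assay=target_assay,
            spike_assay=spike_assay,
            dilution_factor=dilution_factor,
            fam=np.array([p.fam_intensity for p in partitions], dtype=float),
            vic=np.array([p.vic_intensity for p in partitions], dtype=float),
            quality=np.array([p.quality for p in partitions], dtype=float),
        )


@dataclass(frozen=True)
class CallSummary:
    """Counts of each call type on one chip.

    Invariants: the four valid call types sum to ``n_valid`` and
    ``n_valid + n_excluded == n_total``.
    """

    n_total: int
    n_valid: int
    n_fam_only: int
    n_vic_only: int
    n_fam_vic: int
    n_not_amplified: int
    n_excluded: int

    def __post_init__(self):
        if (
            self.n_fam_only + self.n_vic_only + self.n_fam_vic + self.n_not_amplified
            != self.n_valid
        ):
            raise ValueError("valid call counts do not sum to n_valid")
        if self.n_valid + self.n_excluded != self.n_total:
            raise ValueError("n_valid + n_excluded != n_total")

    @property
    def n_fam_positive(self) -> int:
        """Partitions positive on the FAM (target) channel."""
        return self.n_fam_only + self.n_fam_vic

    @property
    def n_vic_positive(self) -> int:
        """Partitions positive on the VIC (spike-in) channel."""
        return self.n_vic_only + self.n_fam_vic


@dataclass(frozen=True)
class QCResult:
    """Chip-level quality control: enough valid partitions for quantification?"""

    n_valid: int
    threshold: int = DEFAULT_MIN_VALID_PARTITIONS
    passed: bool = field(init=False, default=False)

    def __post_init__(self):
        object.__setattr__(self, "passed", self.n_valid >= self.threshold)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-partition calls plus the summary and the thresholds that produced them."""

    calls: np.ndarray  # int8 array of CallType codes, one per well
    summary: CallSummary
    fam_threshold: float
    vic_threshold: float
    quality_threshold: float

    def labels(self) -> list[str]:
        return [CallType(int(c)).label for c in self.calls]


def auto_threshold(intensities) -> float:
    """Split a 1-D intensity distribution into two modes.

    Returns the cut minimizing the total within-group sum of squares over
    all candidate cuts (midpoints between consecutive distinct sorted
    values) — the exact two-class 1-D split, evaluated on the raw values
    rather than a binned histogram. Deterministic for fixed input.

    Raises
    ------
    ThresholdError
        If fewer than two distinct values are present, so no two
        populations can be separated and a manual threshold is needed.
    """
    x = np.sort(np.asarray(intensities, dtype=float).ravel())
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ThresholdError("cannot separate populations: need >= 2 finite values")
    if x[0] == x[-1]:
        raise ThresholdError(
            "cannot separate populations: all intensities equal; set a manual threshold"
        )
    n = x.size
    # Prefix sums give each split's within-group SSE in O(1).
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # low group = x[:k]
    sse_low = csq[k - 1] - csum[k - 1] ** 2 / k
    sum_hi = csum[-1] - csum[k - 1]
    sq_hi = csq[-1] - csq[k - 1]
    sse_high = sq_hi - sum_hi**2 / (n - k)
    sse = sse_low + sse_high
    # Only splits between distinct neighbours are real cuts.
    valid = x[k] > x[k - 1]
    sse[~valid] = np.inf
    best = int(np.argmin(sse))
    return float((x[best] + x[best + 1]) / 2.0)


def classify_partitions(
    chip: Chip,
    fam_threshold: float | None = None,
    vic_threshold: float | None = None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> ClassificationResult:
    """Label every partition with one of the five call types.

    Wells with ``quality < quality_threshold`` are EXCLUDED. Each remaining
    well is positive on a channel iff its intensity strictly exceeds that
    channel's threshold (a tie counts as negative), giving FAM+VIC, FAM,
    VIC, or NOT AMPLIFIED.

    When a fluorescence threshold is ``None`` it is computed by
    :func:`auto_threshold` on the valid partitions of that channel,
    mirroring the instrument's automatic thresholding.
    """
    if len(chip) == 0:
        raise EmptyChipError("no partitions")
    if not np.isfinite(quality_threshold):
        raise ValueError("quality_threshold must be finite")
    for name, arr in (("FAM", chip.fam), ("VIC", chip.vic)):
        bad = ~np.isfinite(arr)
        if bad.any():
            raise NonFiniteIntensityError(name, int(np.flatnonzero(bad)[0]))

    valid = chip.quality >= quality_threshold
    if fam_threshold is None:
        fam_threshold = auto_threshold(chip.fam[valid])
    if vic_threshold is None:
        vic_threshold = auto_threshold(chip.vic[valid])
    if not (np.isfinite(fam_threshold) and np.isfinite(vic_threshold)):
        raise ValueError("fluorescence thresholds must be finite")

    fam_pos = chip.fam > fam_threshold
    vic_pos = chip.vic > vic_threshold

    calls = np.full(len(chip), CallType.EXCLUDED, dtype=np.int8)
    calls[valid & fam_pos & vic_pos] = CallType.FAM_VIC
    calls[valid & fam_pos & ~vic_pos] = CallType.FAM_ONLY
    calls[valid & ~fam_pos & vic_pos] = CallType.VIC_ONLY
    calls[valid & ~fam_pos & ~vic_pos] = CallType.NOT_AMPLIFIED

    summary = summarize_calls(calls)
    return ClassificationResult(
        calls=calls,
        summary=summary,
        fam_threshold=float(fam_threshold),
        vic_threshold=float(vic_threshold),
        quality_threshold=float(quality_threshold),
    )


def summarize_calls(calls: np.ndarray) -> CallSummary:
    """Tally an array of CallType codes into a :class:`CallSummary`."""
    counts = np.bincount(np.asarray(calls, dtype=np.int64), minlength=5)
    n_excluded = int(counts[CallType.EXCLUDED])
    n_total = int(counts.sum())
    return CallSummary(
        n_total=n_total,
        n_valid=n_total - n_excluded,
        n_fam_only=int(counts[CallType.FAM_ONLY]),
        n_vic_only=int(counts[CallType.VIC_ONLY]),
        n_fam_vic=int(counts[CallType.FAM_VIC]),
        n_not_amplified=int(counts[CallType.NOT_AMPLIFIED]),
        n_excluded=n_excluded,
    )


def chip_qc(
    summary: CallSummary | int, min_valid: int = DEFAULT_MIN_VALID_PARTITIONS
) -> QCResult:
    """Pass a chip iff its valid-partition count reaches ``min_valid``.

    Accepts either a :class:`CallSummary` or a bare valid-partition count.
    """
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    n_valid = summary.n_valid if isinstance(summary, CallSummary) else int(summary)
    return QCResult(n_valid=n_valid, threshold=int(min_valid))
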