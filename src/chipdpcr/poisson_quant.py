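"""Poisson quantification for digital PCR.

Template molecules distribute over partitions approximately as a Poisson
process, so the fraction of negative valid partitions estimates
``exp(-lambda)`` where lambda is the mean copies per partition:

    p_hat      = n_positive / n_valid
    lambda_hat = -ln(1 - p_hat)
    copies/ul  = lambda_hat / partition_volume

No standard curve is needed; the chip geometry (partition volume) converts
copies-per-partition into an absolute concentration in the reaction mix.

Confidence intervals are computed on the lambda scale. The default is the
delta-method normal interval with

    se(lambda_hat) = sqrt( p_hat / ((1 - p_hat) * n_valid) )

which is narrow and symmetric at the occupancies typical of a well-loaded
chip. An exact Clopper-Pearson option transforms a binomial interval for p
through -ln(1 - p) and is preferable at very low positive counts.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .chip_model import (
    DEFAULT_MIN_VALID_PARTITIONS,
    DEFAULT_QUALITY_THRESHOLD,
    Chip,
    QCResult,
    chip_qc,
    classify_partitions,
)
from .exceptions import (
    NoValidPartitionsError,
    SaturatedChipError,
    SpikeInError,
)

#: Well volume in microliters of the fixed 20,000-well chip geometry.
DEFAULT_PARTITION_VOLUME_UL = 8.09e-4


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute concentration for one fluorescence channel of one chip.

    ``n_positive``, ``p_hat`` and ``lambda_hat`` are ``None`` when the
    estimate was loaded from a results table that only prints the
    concentration and its interval.
    """

    channel: Literal["FAM", "VIC"]
    n_valid: int
    copies_per_ul: float
    ci_low: float
    ci_high: float
    n_positive: int | None = None
    p_hat: float | None = None
    lambda_hat: float | None = None
    confidence_level: float = 0.95

    def __post_init__(self):
        if self.n_positive is not None and not (
            0 <= self.n_positive <= self.n_valid
        ):
            raise ValueError("n_positive must lie in [0, n_valid]")
        if not (self.ci_low <= self.copies_per_ul <= self.ci_high):
            raise ValueError("point estimate must lie inside its interval")
        if self.ci_low < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def ci_halfwidth_relative(self) -> float:
        """Half the CI width divided by the point estimate."""
        if self.copies_per_ul == 0:
            return math.inf
        return (self.ci_high - self.ci_low) / 2.0 / self.copies_per_ul


@dataclass(frozen=True)
class ChipResult:
    """One chip's quantification: spike and target estimates plus QC."""

    chip_id: str
    sample_id: str
    target_assay: str
    spike_assay: str
    dilution_factor: float
    spike: ConcentrationEstimate
    target: ConcentrationEstimate
    qc: QCResult
    total_points: int | None = None  # valid + excluded wells, when known

    def __post_init__(self):
        if self.spike.n_valid != self.target.n_valid:
            raise ValueError("spike and target must share n_valid")
        if self.total_points is not None and self.total_points < self.spike.n_valid:
            raise ValueError("total_points must be >= valid points")


@dataclass(frozen=True)
class NormalizedResult:
    """A target concentration rescaled by the spike-in and dilution."""

    chip_id: str
    sample_id: str
    target_assay: str
    raw_copies_per_ul: float
    normalization_factor: float
    dilution_factor: float
    normalized_copies_per_ul: float

    def __post_init__(self):
        if self.normalization_factor <= 0:
            raise ValueError("normalization_factor must be > 0")
        expected = (
            self.raw_copies_per_ul * self.normalization_factor * self.dilution_factor
        )
        if not math.isclose(self.normalized_copies_per_ul, expected, rel_tol=1e-9):
            raise ValueError("normalized value inconsistent with its factors")


def estimate_concentration(
    n_valid: int,
    n_positive: int,
    partition_volume: float = DEFAULT_PARTITION_VOLUME_UL,
    confidence_level: float = 0.95,
    channel: Literal["FAM", "VIC"] = "FAM",
    ci_method: Literal["delta", "binomial"] = "delta",
) -> ConcentrationEstimate:
    """Turn a positive-partition count into copies per microliter with a CI.

    Parameters
    ----------
    n_valid
        Valid (quality-passing) partitions on the chip.
    n_positive
        Channel-positive partitions among them.
    partition_volume
        Well volume in microliters.
    confidence_level
        Two-sided coverage of the interval (default 0.95).
    ci_method
        ``"delta"`` for the normal interval on the lambda scale (default);
        ``"binomial"`` for an exact Clopper-Pearson interval on p mapped
        through ``-ln(1 - p)``.

    Raises
    ------
    NoValidPartitionsError
        If ``n_valid`` is 0.
    SaturatedChipError
        If every valid partition is positive (lambda undefined; dilute).
    """
    if n_valid < 1:
        raise NoValidPartitionsError("no valid partitions")
    if not 0 <= n_positive <= n_valid:
        raise ValueError("n_positive must lie in [0, n_valid]")
    if partition_volume <= 0:
        raise ValueError("partition_volume must be > 0")
    if not 0 < confidence_level < 1:
        raise ValueError("confidence_level must lie in (0, 1)")
    if n_positive == n_valid:
        raise SaturatedChipError(
            f"saturated chip: all {n_valid} valid partitions positive; "
            "lambda undefined — dilute the sample and rerun"
        )

    p_hat = n_positive / n_valid
    lam = -math.log1p(-p_hat)

    if n_positive == 0:
        # Rule of three: 95% upper bound on lambda for an all-negative chip.
        if confidence_level == 0.95:
            lam_high = 3.0 / n_valid
        else:
            lam_high = -math.log(1.0 - confidence_level) / n_valid
        lam_low = 0.0
    elif ci_method == "delta":
        z = stats.norm.ppf(0.5 + confidence_level / 2.0)
        se = math.sqrt(p_hat / ((1.0 - p_hat) * n_valid))
        lam_low = max(0.0, lam - z * se)
        lam_high = lam + z * se
    elif ci_method == "binomial":
        alpha = 1.0 - confidence_level
        p_low = stats.beta.ppf(alpha / 2.0, n_positive, n_valid - n_positive + 1)
        p_high = stats.beta.ppf(
            1.0 - alpha / 2.0, n_positive + 1, n_valid - n_positive
        )
        lam_low = -math.log1p(-float(p_low))
        lam_high = -math.log1p(-min(float(p_high), 1.0 - 1e-15))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return ConcentrationEstimate(
        channel=channel,
        n_valid=int(n_valid),
        n_positive=int(n_positive),
        p_hat=p_hat,
        lambda_hat=lam,
        copies_per_ul=lam / partition_volume,
        ci_low=lam_low / partition_volume,
        ci_high=lam_high / partition_volume,
        confidence_level=confidence_level,
    )


def quantify_chip(
    chip: Chip,
    fam_threshold: float | None = None,
    vic_threshold: float | None = None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    min_valid: int = DEFAULT_MIN_VALID_PARTITIONS,
    partition_volume: float = DEFAULT_PARTITION_VOLUME_UL,
    confidence_level: float = 0.95,
    ci_method: Literal["delta", "binomial"] = "delta",
) -> ChipResult:
    """Classify a chip and estimate both channels' concentrations.

    A chip that fails QC still reports estimates — the QC flag, not an
    exception, records that the valid-partition count fell short.
    """
    cls = classify_partitions(
        chip,
        fam_threshold=fam_threshold,
        vic_threshold=vic_threshold,
        quality_threshold=quality_threshold,
    )
    s = cls.summary
    if s.n_valid == 0:
        raise NoValidPartitionsError("no valid partitions")
    qc = chip_qc(s, min_valid=min_valid)
    common = dict(
        partition_volume=partition_volume,
        confidence_level=confidence_level,
        ci_method=ci_method,
    )
    target = estimate_concentration(
        s.n_valid, s.n_fam_positive, channel="FAM", **common
    )
    spike = estimate_concentration(
        s.n_valid, s.n_vic_positive, channel="VIC", **common
    )
    return ChipResult(
        chip_id=chip.chip_id,
        sample_id=chip.sample_id,
        target_assay=chip.target_assay,
        spike_assay=chip.spike_assay,
        dilution_factor=chip.dilution_factor,
        spike=spike,
        target=target,
        qc=qc,
        total_points=s.n_total,
    )


def spikein_normalize(
    results: Sequence[ChipResult],
    scope: Literal["project", "per-sample"] = "project",
) -> list[NormalizedResult]:
    """Normalize target concentrations by the spike-in, per chip.

    The reference is the arithmetic mean of cel-miR-39 (spike) copies/ul
    over the chips in the averaging set — the whole collection for
    ``scope="project"``, or each sample's chips for ``scope="per-sample"``.
    Each chip's target is multiplied by ``reference / spike`` and by its
    dilution factor, putting all chips on a common whole-process-efficiency
    and specimen-concentration scale.

    Raises
    ------
    SpikeInError
        If any chip's spike concentration is 0: the whole-process control
        failed and nothing on that chip is interpretable.
    """
    if not results:
        raise ValueError("no chip results to normalize")
    for r in results:
        if r.spike.copies_per_ul <= 0:
            raise SpikeInError(
                f"chip {r.chip_id}: spike-in {r.spike_assay} not detected; "
                "whole-process control invalid"
            )

    if scope == "project":
        groups: dict[str, list[ChipResult]] = {"": list(results)}
    elif scope == "per-sample":
        groups = defaultdict(list)
        for r in results:
            groups[r.sample_id].append(r)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    out: list[NormalizedResult] = []
    by_id = {id(r): None for r in results}  # preserve input order
    for members in groups.values():
        reference = float(np.mean([r.spike.copies_per_ul for r in members]))
        for r in members:
            factor = reference / r.spike.copies_per_ul
            by_id[id(r)] = NormalizedResult(
                chip_id=r.chip_id,
                sample_id=r.sample_id,
                target_assay=r.target_assay,
                raw_copies_per_ul=r.target.copies_per_ul,
                normalization_factor=factor,
                dilution_factor=r.dilution_factor,
                normalized_copies_per_ul=r.target.copies_per_ul
                * factor
                * r.dilution_factor,
            )
    out = [by_id[id(r)] for r in results]
    return out
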