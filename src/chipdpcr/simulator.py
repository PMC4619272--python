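"""Synthetic chip generator with known ground truth.

Emulates just enough of the instrument to exercise the analysis chain:
per-well template counts are Poisson with mean ``concentration x
partition_volume``; occupied and empty wells draw end-point fluorescence
from separated Gaussian regimes (amplitude carries no copy-number
information, as in end-point PCR); the per-well quality score is a mixture
of a "filled" regime above 0.5 and an "unfilled" regime below it, so the
valid-partition count fluctuates the way real chips' do. FAM and VIC
occupancies are independent by default; a cross-talk coefficient exists
for robustness checks only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chip_model import NOMINAL_CHIP_WELLS, Chip
from .poisson_quant import DEFAULT_PARTITION_VOLUME_UL

#: Above this mean occupancy the negative count is tiny and the estimate
#: unstable; the practical remedy is a pre-dilution.
SATURATION_LAMBDA = 7.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and instrument model for one simulated chip.

    Intensity units are arbitrary fluorescence counts; the defaults put
    the negative and positive clouds ~11 SDs apart per channel, so calls
    are limited by loading statistics, not by the optics model.
    """

    true_target_copies_per_ul: float = 500.0
    true_spike_copies_per_ul: float = 250.0
    n_partitions: int = NOMINAL_CHIP_WELLS
    partition_volume: float = DEFAULT_PARTITION_VOLUME_UL
    neg_intensity_mean: float = 500.0
    pos_intensity_mean: float = 4000.0
    intensity_sd: float = 300.0
    fill_rate: float = 0.9
    quality_good_range: tuple[float, float] = (0.6, 1.0)
    quality_bad_range: tuple[float, float] = (0.0, 0.4)
    misclassification_rate: float = 0.0
    crosstalk: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pos_intensity_mean <= self.neg_intensity_mean:
            raise ValueError("positive regime must sit above the negative regime")
        if not 0 <= self.fill_rate <= 1:
            raise ValueError("fill_rate must lie in [0, 1]")
        lo, hi = self.quality_good_range
        blo, bhi = self.quality_bad_range
        if not (0 <= blo <= bhi <= 0.5 <= lo <= hi <= 1):
            raise ValueError("quality regimes must straddle 0.5 without overlap")
        if self.true_target_copies_per_ul < 0 or self.true_spike_copies_per_ul < 0:
            raise ValueError("true concentrations must be >= 0")
        if not 0 <= self.misclassification_rate < 1:
            raise ValueError("misclassification_rate must lie in [0, 1)")
        if self.n_partitions < 1 or self.n_partitions > NOMINAL_CHIP_WELLS:
            raise ValueError(
                f"n_partitions must lie in [1, {NOMINAL_CHIP_WELLS}]"
            )


@dataclass(frozen=True)
class ChipTruth:
    """Sidecar record of what a simulated chip actually contained."""

    chip_id: str
    true_target_copies_per_ul: float
    true_spike_copies_per_ul: float
    lambda_target: float
    lambda_spike: float
    seed: int


def _channel_occupancy(
    rng: np.random.Generator, lam: float, n: int, misclassification: float
) -> np.ndarray:
    counts = rng.poisson(lam, n)
    occupied = counts > 0
    if misclassification > 0:
        flips = rng.random(n) < misclassification
        occupied = occupied ^ flips
    return occupied


def simulate_chip(
    config: SimulationConfig,
    chip_id: str = "sim",
    sample_id: str = "sim-sample",
    target_assay: str = "target",
    spike_assay: str = "cel-mir-39",
    dilution_factor: float = 1.0,
) -> tuple[Chip, ChipTruth]:
    """Draw one chip from the instrument model. Identical seed, identical chip."""
    lam_t = config.true_target_copies_per_ul * config.partition_volume
    lam_s = config.true_spike_copies_per_ul * config.partition_volume
    for name, lam in (("target", lam_t), ("spike", lam_s)):
        if lam > SATURATION_LAMBDA:
            warnings.warn(
                f"{name} occupancy lambda={lam:.2f} is near saturation; "
                "dilute the sample (a rough prior estimate of concentration "
                "is needed to stay on the quantifiable range)",
                stacklevel=2,
            )

    rng = np.random.default_rng(config.seed)
    n = config.n_partitions
    occ_t = _channel_occupancy(rng, lam_t, n, config.misclassification_rate)
    occ_s = _channel_occupancy(rng, lam_s, n, config.misclassification_rate)

    def intensities(occupied: np.ndarray, leak_from: np.ndarray) -> np.ndarray:
        mean = np.where(
            occupied, config.pos_intensity_mean, config.neg_intensity_mean
        )
        x = rng.normal(mean, config.intensity_sd)
        if config.crosstalk > 0:
            # Bleed-through: a fraction of the other channel's signal span.
            span = config.pos_intensity_mean - config.neg_intensity_mean
            x = x + config.crosstalk * span * leak_from
        return np.clip(x, 0.0, None)

    fam = intensities(occ_t, occ_s)
    vic = intensities(occ_s, occ_t)

    filled = rng.random(n) < config.fill_rate
    q_good = rng.uniform(*config.quality_good_range, n)
    q_bad = rng.uniform(*config.quality_bad_range, n)
    quality = np.where(filled, q_good, q_bad)

    chip = Chip(
        chip_id=chip_id,
        sample_id=sample_id,
        target_assay=target_assay,
        spike_assay=spike_assay,
        dilution_factor=dilution_factor,
        fam=fam,
        vic=vic,
        quality=quality,
    )
    truth = ChipTruth(
        chip_id=chip_id,
        true_target_copies_per_ul=config.true_target_copies_per_ul,
        true_spike_copies_per_ul=config.true_spike_copies_per_ul,
        lambda_target=lam_t,
        lambda_spike=lam_s,
        seed=config.seed,
    )
    return chip, truth


def derive_seed(base_seed: int, k: int) -> int:
    """Deterministic child seed for dilution point k (stable across runs)."""
    return int(
        np.random.SeedSequence([int(base_seed), int(k)]).generate_state(1)[0]
        % (2**31)
    )


def simulate_dilution_series(
    base_config: SimulationConfig,
    start_copies_per_ul: float,
    fold: float,
    n_points: int,
) -> list[tuple[Chip, ChipTruth]]:
    """One chip per point of a geometric dilution of the target.

    The spike-in concentration is held constant across the series (it is
    added at a fixed amount per reaction); only the target is diluted.
    Seeds derive deterministically from the base config's seed and the
    point index.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if start_copies_per_ul <= 0:
        raise ValueError("start concentration must be > 0")
    if n_points < 2:
        raise ValueError("a series needs >= 2 points")
    out = []
    for k in range(n_points):
        conc = start_copies_per_ul / fold**k
        cfg = replace(
            base_config,
            true_target_copies_per_ul=conc,
            seed=derive_seed(base_config.seed, k),
        )
        out.append(
            simulate_chip(
                cfg,
                chip_id=f"D{k + 1}",
                sample_id=f"dilution-{k + 1}",
                dilution_factor=1.0,
            )
        )
    return out
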