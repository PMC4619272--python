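import numpy as np
import pytest

from chipdpcr import Chip, ChipResult, ConcentrationEstimate, QCResult

#: Midpoint between the simulator's default negative (500) and positive
#: (4000) fluorescence regimes; used where automatic thresholding is not
#: applicable (e.g. trace-level chips with almost no positive wells).
MID_THRESHOLD = 2250.0


def make_chip(fam, vic, quality=None, **kwargs):
    fam = np.asarray(fam, dtype=float)
    if quality is None:
        quality = np.ones_like(fam)
    defaults = dict(
        chip_id="chip-1",
        sample_id="sample-1",
        target_assay="mir-16-5p",
        spike_assay="cel-mir-39",
        dilution_factor=1.0,
    )
    defaults.update(kwargs)
    return Chip(fam=fam, vic=np.asarray(vic, dtype=float),
                quality=np.asarray(quality, dtype=float), **defaults)


def make_result(spike_copies, target_copies, dilution=1.0, sample="S",
                chip_id=None, n_valid=15000):
    """ChipResult with hand-set concentrations (CIs are +/-10%)."""
    spike = ConcentrationEstimate(
        channel="VIC", n_valid=n_valid, copies_per_ul=spike_copies,
        ci_low=spike_copies * 0.9, ci_high=spike_copies * 1.1,
    )
    target = ConcentrationEstimate(
        channel="FAM", n_valid=n_valid, copies_per_ul=target_copies,
        ci_low=target_copies * 0.9, ci_high=target_copies * 1.1,
    )
    return ChipResult(
        chip_id=chip_id or f"chip-{sample}",
        sample_id=sample,
        target_assay="mir-16-5p",
        spike_assay="cel-mir-39",
        dilution_factor=dilution,
        spike=spike,
        target=target,
        qc=QCResult(n_valid=n_valid),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
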