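"""Exception hierarchy for chipdpcr."""


class ChipDPCRError(Exception):
    """Base class for all chipdpcr errors."""


class EmptyChipError(ChipDPCRError):
    """A chip with no partitions was passed where partitions are required."""


class NonFiniteIntensityError(ChipDPCRError):
    """A partition carries a NaN or infinite fluorescence value."""

    def __init__(self, channel: str, well_index: int):
        self.channel = channel
        self.well_index = well_index
        super().__init__(
            f"non-finite {channel} intensity at well index {well_index}"
        )


class ThresholdError(ChipDPCRError):
    """Automatic thresholding cannot separate two populations."""


class SaturatedChipError(ChipDPCRError):
    """Every valid partition is positive; lambda is undefined.

    The remedy is to dilute the sample and rerun the chip.
    """


class NoValidPartitionsError(ChipDPCRError):
    """No partition passed the quality threshold; nothing to estimate."""


class SpikeInError(ChipDPCRError):
    """The spike-in channel shows no signal; the whole-process control failed."""


class SchemaError(ChipDPCRError):
    """A CSV or config file does not match the expected schema."""
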