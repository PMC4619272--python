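"""Call-type scatter plot (FAM vs VIC fluorescence)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .chip_model import CallType, Chip, ClassificationResult

#: Conventional call-type colours: FAM blue, VIC red, FAM+VIC green,
#: NOT AMPLIFIED yellow; excluded wells grey.
CALL_COLORS = {
    CallType.FAM_ONLY: "#1f77b4",
    CallType.VIC_ONLY: "#d62728",
    CallType.FAM_VIC: "#2ca02c",
    CallType.NOT_AMPLIFIED: "#ffd92f",
    CallType.EXCLUDED: "#bbbbbb",
}


def plot_calls(
    chip: Chip,
    classification: ClassificationResult,
    path: str | Path | None = None,
    ax=None,
):
    """Scatter each partition in fluorescence space, coloured by call type."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for call, color in CALL_COLORS.items():
        mask = classification.calls == call
        if mask.any():
            ax.scatter(
                chip.vic[mask],
                chip.fam[mask],
                s=3,
                c=color,
                label=f"{call.label} ({int(mask.sum())})",
                alpha=0.6,
                linewidths=0,
            )
    ax.axhline(classification.fam_threshold, color="k", lw=0.5, ls="--")
    ax.axvline(classification.vic_threshold, color="k", lw=0.5, ls="--")
    ax.set_xlabel("VIC fluorescence (a.u.)")
    ax.set_ylabel("FAM fluorescence (a.u.)")
    ax.set_title(f"{chip.chip_id}: {chip.target_assay} / {chip.spike_assay}")
    ax.legend(markerscale=3, fontsize=8, loc="upper right")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
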