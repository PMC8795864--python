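"""Channel naming for the 32-electrode 10-20 recording cap.

The cap layout mirrors a typical 32-channel TMS-compatible montage:
the 19 classic 10-20 positions, the intermediate 10-10 fronto-central /
centro-parietal ring, both earlobes and FCz. ``T3/T4/T5/T6`` (older
10-20 names for T7/T8/P7/P8) are kept because they are the names used
on clinical caps of this type.
"""

from __future__ import annotations

#: Default 32-channel montage. Order is fixed and is the channel order of
#: every synthetic recording produced by :mod:`tvnet.synthetic`.
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T3", "C3", "Cz", "C4", "T4",
    "CP5", "CP1", "CP2", "CP6",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
    "A1", "A2",
)

#: Scalp site over the right dorsolateral prefrontal cortex, the
#: single-pulse stimulation target.
STIMULATION_SITE = "F4"


def channel_index(label: str, labels=MONTAGE_32) -> int:
    """Index of ``label`` in the montage, raising a clear error if absent."""
    try:
        return list(labels).index(label)
    except ValueError:
        raise KeyError(f"channel {label!r} not in montage {tuple(labels)}") from None
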