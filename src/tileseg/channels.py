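"""The fixed multi-label channel vocabulary.

Masks everywhere in this package are 4-channel boolean stacks; the channel
order below is part of the on-disk file-format contract and must not change.
A pixel may belong to several channels at once (overlapping annotations).
"""

from __future__ import annotations

from dataclasses import dataclass

CLASS_NAMES: tuple[str, ...] = ("filling", "crown", "root_canal", "implant")
N_CLASSES: int = len(CLASS_NAMES)

# mask file suffix per channel, in channel order
MASK_SUFFIXES: tuple[str, ...] = ("_filling", "_crown", "_rootcanal", "_implant")


@dataclass(frozen=True)
class ClassChannel:
    """One of the four restoration classes, identified by index and name."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.index < N_CLASSES):
            raise ValueError(f"channel index must be in [0, {N_CLASSES}), got {self.index}")
        if CLASS_NAMES[self.index] != self.name:
            raise ValueError(
                f"channel {self.index} is named {CLASS_NAMES[self.index]!r}, got {self.name!r}"
            )


CHANNELS: tuple[ClassChannel, ...] = tuple(
    ClassChannel(i, name) for i, name in enumerate(CLASS_NAMES)
)
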