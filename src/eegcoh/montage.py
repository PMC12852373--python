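"""Electrode montages of the 10-20 / 10-10 scalp placement systems.

The 19-channel clinical montage is kept in a fixed canonical order so that
channel-pair feature indices are stable and auditable across runs.  The
64-channel 10-10 montage uses modern labels; the four temporal/posterior
electrodes renamed between the systems (T3/T4/T5/T6 vs T7/T8/P7/P8) are
resolved through an explicit equivalence table.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Canonical 19-channel 10-20 order used for all pairwise feature indexing.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: A standard 64-channel 10-10 layout (modern labels).
TEN_TEN_64 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Legacy 10-20 label -> modern 10-10 label (and its inverse below).
LEGACY_TO_MODERN = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}
MODERN_TO_LEGACY = {v: k for k, v in LEGACY_TO_MODERN.items()}


@dataclass(frozen=True)
class MontageSpec:
    """An ordered, named set of electrode labels."""

    name: str
    channel_names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("montage channel names must be unique")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.channel_names)}
        )

    @classmethod
    def ten_twenty_19(cls) -> "MontageSpec":
        return cls("ten_twenty_19", TEN_TWENTY_19)

    @classmethod
    def ten_ten_64(cls) -> "MontageSpec":
        return cls("ten_ten_64", TEN_TEN_64)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        """Index of ``channel``, resolving legacy/modern label equivalences."""
        if channel in self._index:
            return self._index[channel]
        for table in (LEGACY_TO_MODERN, MODERN_TO_LEGACY):
            alias = table.get(channel)
            if alias is not None and alias in self._index:
                return self._index[alias]
        raise KeyError(f"channel {channel!r} not in montage {self.name!r}")

    def __contains__(self, channel: str) -> bool:
        try:
            self.index(channel)
        except KeyError:
            return False
        return True


def channel_pairs(n_channels: int) -> list[tuple[int, int]]:
    """All unordered channel index pairs (i, j) with i < j, lexicographic."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]
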