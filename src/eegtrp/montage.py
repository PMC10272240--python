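"""Fixed 14-electrode consumer-headset montage and its anatomical partitions.

The montage follows the international 10-20 placement scheme: odd-numbered
labels sit over the left hemisphere (LH), even-numbered over the right (RH).
For area-level contrasts the electrodes split into a frontal area (FA, 8
electrodes) and a rear area (RA, 6 electrodes covering occipital, parietal
and temporal sites); the headset has dense frontal coverage but only two
electrodes in each posterior region, so a finer parcellation is not
statistically meaningful at this channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

__all__ = ["Montage", "default_montage", "ELECTRODES"]

#: Channel order used throughout the package (acquisition order of the headset).
ELECTRODES: Tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

_FRONTAL = frozenset({"AF3", "F7", "F3", "F4", "F8", "AF4", "FC5", "FC6"})

_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"), ("FC5", "FC6"),
    ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
)


def _hemisphere(label: str) -> str:
    # 10-20 convention: odd site number = left hemisphere, even = right.
    digits = "".join(ch for ch in label if ch.isdigit())
    return "LH" if int(digits) % 2 == 1 else "RH"


@dataclass(frozen=True)
class Montage:
    """Electrode set with hemisphere/area partitions and homologous pairs."""

    electrodes: Tuple[str, ...]
    hemisphere_of: Mapping[str, str]
    area_of: Mapping[str, str]
    homologous_pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = set(self.electrodes)
        if set(self.hemisphere_of) != labels or set(self.area_of) != labels:
            raise ValueError("hemisphere/area maps must be total over the electrodes")
        for lh, rh in self.homologous_pairs:
            if self.hemisphere_of[lh] != "LH" or self.hemisphere_of[rh] != "RH":
                raise ValueError(f"pair ({lh}, {rh}) is not an LH/RH pair")

    @property
    def n_channels(self) -> int:
        return len(self.electrodes)

    def labels(self, hemisphere: str | None = None, area: str | None = None) -> Tuple[str, ...]:
        """Electrode labels, optionally restricted to one hemisphere and/or area."""
        out = []
        for e in self.electrodes:
            if hemisphere is not None and self.hemisphere_of[e] != hemisphere:
                continue
            if area is not None and self.area_of[e] != area:
                continue
            out.append(e)
        return tuple(out)

    def index_of(self, label: str) -> int:
        return self.electrodes.index(label)


def default_montage() -> Montage:
    """The 14-electrode montage (AF3 ... AF4) with LH/RH and FA/RA partitions."""
    return Montage(
        electrodes=ELECTRODES,
        hemisphere_of={e: _hemisphere(e) for e in ELECTRODES},
        area_of={e: ("FA" if e in _FRONTAL else "RA") for e in ELECTRODES},
        homologous_pairs=_PAIRS,
    )
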