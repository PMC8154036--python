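"""Channel layouts for 10-20 style EEG montages.

The built-in montage is an idealized spherical 10-20 subset: electrodes sit on
a unit sphere, mirror-symmetric about the sagittal plane, with the posterior
and temporal ring at a polar angle of 72 degrees from the vertex.  Only the
geometry that the analyses consume matters here — left/right lateralization,
homologous pairing, frontal membership, and plausible nearest-neighbour
adjacency — not anatomical fidelity.

Label conventions follow the extended 10-20 system: a trailing odd digit marks
a left-hemisphere site, an even digit a right-hemisphere site, and a trailing
``z`` the midline (Fz, Cz, ...).  Homologous pairs are same-prefix labels with
digits ``d`` (odd, left) and ``d + 1`` (right): F3-F4, F7-F8, AF3-AF4, ...
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelLayout",
    "channel_side",
    "homologous_partner",
    "make_standard_layout",
    "PAIR_ALIASES",
]

#: Editable correspondence table for montages whose labels are not 10-20
#: (e.g. EGI sensor nets): maps a vendor label to the 10-20 label whose role
#: it plays in channel-pair analyses.  The built-in montage needs no aliases.
PAIR_ALIASES: dict[str, str] = {}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+|z)$")

# (label, polar angle from vertex [deg], azimuth [deg]; azimuth 0 = nose,
# positive = left hemisphere).  Mirror symmetry is by construction.
_STANDARD_ANGLES: list[tuple[str, float, float]] = [
    ("Fp1", 72, 18), ("Fp2", 72, -18),
    ("AF3", 61, 23), ("AF4", 61, -23), ("AFz", 63, 0),
    ("F7", 72, 54), ("F3", 50, 32), ("Fz", 45, 0), ("F4", 50, -32), ("F8", 72, -54),
    ("T7", 72, 90), ("C3", 45, 90), ("Cz", 0, 0), ("C4", 45, -90), ("T8", 72, -90),
    ("P7", 72, 126), ("P3", 50, 148), ("Pz", 45, 180), ("P4", 50, -148), ("P8", 72, -126),
    ("O1", 72, 162), ("Oz", 72, 180), ("O2", 72, -162),
]

_FRONTAL_PREFIXES = ("Fp", "AF", "F")


def channel_side(name: str) -> str:
    """Classify a 10-20 label as 'left', 'right', or 'midline'.

    Odd trailing digit -> left, even -> right, 'z' -> midline.
    """
    m = _LABEL_RE.match(name)
    if m is None:
        raise ValueError(f"not a 10-20 style channel label: {name!r}")
    suffix = m.group(2)
    if suffix == "z":
        return "midline"
    return "left" if int(suffix) % 2 == 1 else "right"


def homologous_partner(name: str) -> str | None:
    """Return the mirror-image label of a lateral channel (F3 -> F4), or None."""
    m = _LABEL_RE.match(name)
    if m is None or m.group(2) == "z":
        return None
    prefix, digit = m.group(1), int(m.group(2))
    partner = digit + 1 if digit % 2 == 1 else digit - 1
    return f"{prefix}{partner}"


def _is_frontal(name: str) -> bool:
    # Fp*, AF*, F* but not fronto-central/temporal rows (FC, FT).
    return bool(re.match(r"^(Fp|AF|F)(\d+|z)$", name))


@dataclass(frozen=True)
class ChannelLayout:
    """Montage geometry plus the derived structure the asymmetry analyses use.

    Attributes
    ----------
    names : channel labels.
    positions : (n_channels, 3) unit-sphere coordinates (x right, y front, z up).
    sides : 'left' / 'right' / 'midline' per channel.
    homologous_pairs : (left_name, right_name) tuples, both present in `names`.
    frontal_subset : frontal channels (Fp*, AF*, F*), midline included.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    sides: tuple[str, ...] = field(init=False)
    homologous_pairs: tuple[tuple[str, str], ...] = field(init=False)
    frontal_subset: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate channel names in layout")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        object.__setattr__(self, "positions", pos)
        sides = tuple(channel_side(n) for n in self.names)
        object.__setattr__(self, "sides", sides)
        pairs = []
        for n in self.names:
            if channel_side(n) != "left":
                continue
            partner = homologous_partner(n)
            if partner is not None and partner in self.names:
                pairs.append((n, partner))
        object.__setattr__(self, "homologous_pairs", tuple(pairs))
        object.__setattr__(
            self, "frontal_subset", tuple(n for n in self.names if _is_frontal(n))
        )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout") from None

    def frontal_pairs(self) -> tuple[tuple[str, str], ...]:
        """Homologous pairs whose members are both frontal (cluster search space)."""
        frontal = set(self.frontal_subset)
        return tuple(p for p in self.homologous_pairs if p[0] in frontal and p[1] in frontal)

    def subset(self, names: list[str] | tuple[str, ...]) -> "ChannelLayout":
        idx = [self.index(n) for n in names]
        return ChannelLayout(tuple(names), self.positions[idx])


def make_standard_layout(names: list[str] | None = None) -> ChannelLayout:
    """Build the built-in idealized 10-20 montage (23 channels), or a subset.

    Parameters
    ----------
    names : optional subset of labels to keep, in the given order.
    """
    table = {lab: (polar, az) for lab, polar, az in _STANDARD_ANGLES}
    if names is None:
        names = [lab for lab, _, _ in _STANDARD_ANGLES]
    missing = [n for n in names if n not in table]
    if missing:
        raise KeyError(f"labels not in the built-in montage: {missing}")
    pos = np.empty((len(names), 3))
    for i, n in enumerate(names):
        polar, az = np.deg2rad(table[n][0]), np.deg2rad(table[n][1])
        pos[i] = (-np.sin(polar) * np.sin(az), np.sin(polar) * np.cos(az), np.cos(polar))
    return ChannelLayout(tuple(names), pos)
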