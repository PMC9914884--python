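"""MaZda-style texture feature names.

A co-occurrence feature name reads ``[channel][direction][distance]S[bits][Feature]``,
e.g. ``CZ1S6Entropy``: grey channel ``C``, 45-degree direction ``Z``,
inter-pixel distance 1, ``S`` for mu +/- 3 sigma normalization, 6-bit
(64-level) quantization, GLCM Entropy. Direction letters are ``H`` (0
degrees), ``V`` (90), ``Z`` (45), ``N`` (135).

Non-GLCM families drop the parts that do not apply: run-length features
keep the direction but have no distance (``CHS6RLNonUni``); histogram,
gradient and wavelet features keep only channel/normalization/bits
(``CS6Mean``, ``CS6GrMean``, ``CS6WavEnLL1``); autoregressive-model
parameters are conventionally reported bare (``Teta1`` .. ``Teta4``,
``SigmaAR``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "FeatureKey",
    "FeatureNameError",
    "parse_feature_name",
    "serialize_feature_name",
    "DIRECTIONS",
    "AR_FEATURES",
]

#: In-plane (row, col) unit offsets for the four direction codes.
#: Rows grow downward, so 45 degrees (Z) points up-right.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "H": (0, 1),
    "V": (1, 0),
    "Z": (-1, 1),
    "N": (-1, -1),
}

AR_FEATURES = ("Teta1", "Teta2", "Teta3", "Teta4", "SigmaAR")


class FeatureNameError(ValueError):
    """A feature name does not match the grammar; carries the failing position."""

    def __init__(self, name: str, position: int, message: str):
        self.name = name
        self.position = position
        super().__init__(f"cannot parse feature name {name!r} at position {position}: {message}")


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Parsed feature identity: channel, direction, distance, normalization, bits, feature."""

    feature: str
    channel: str = "C"
    direction: str | None = None
    distance: int | None = None
    normalization: str = "S"
    bits: int | None = None

    def __str__(self) -> str:
        return serialize_feature_name(self)


_GLCM_RE = re.compile(
    r"^(?P<channel>C)"
    r"(?P<direction>[HVZN])?"
    r"(?P<distance>[1-9][0-9]*)?"
    r"(?P<norm>S)"
    r"(?P<bits>[0-9])"
    r"(?P<feature>[A-Za-z][A-Za-z0-9]*)$"
)


def serialize_feature_name(key: FeatureKey) -> str:
    """Render a :class:`FeatureKey` in the name grammar."""
    if key.feature in AR_FEATURES:
        return key.feature
    parts = [key.channel]
    if key.direction is not None:
        parts.append(key.direction)
    if key.distance is not None:
        parts.append(str(key.distance))
    parts.append(key.normalization)
    parts.append(str(key.bits))
    parts.append(key.feature)
    return "".join(parts)


def parse_feature_name(name: str) -> FeatureKey:
    """Parse a feature name back into a :class:`FeatureKey`.

    Round-trips with :func:`serialize_feature_name`:
    ``parse(serialize(k)) == k`` for any key produced by the extraction
    grid.
    """
    if name in AR_FEATURES:
        return FeatureKey(feature=name)
    m = _GLCM_RE.match(name)
    if m is None:
        # locate the first offending character for the error message
        pos = 0
        if not name.startswith("C"):
            pos = 0
        else:
            probe = "C"
            pos = 1
            for i in range(1, len(name) + 1):
                if _could_prefix(name[:i]):
                    pos = i
                else:
                    pos = i - 1
                    break
        raise FeatureNameError(name, pos, "expected [C][HVZN]?[dist]?S[bits][Feature]")
    distance = m.group("distance")
    if distance is not None and m.group("direction") is None:
        raise FeatureNameError(name, 1, "distance digit requires a direction letter")
    return FeatureKey(
        feature=m.group("feature"),
        channel=m.group("channel"),
        direction=m.group("direction"),
        distance=int(distance) if distance is not None else None,
        normalization=m.group("norm"),
        bits=int(m.group("bits")),
    )


_PREFIX_RE = re.compile(r"^C([HVZN]([1-9][0-9]*)?)?(S([0-9]([A-Za-z][A-Za-z0-9]*)?)?)?$")


def _could_prefix(s: str) -> bool:
    return bool(_PREFIX_RE.match(s))
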