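"""Canonical EEG frequency-band definitions.

Bands are half-open intervals ``[f_low, f_high)``: a spectral bin whose centre
frequency equals ``f_high`` belongs to the next band up. The default set is the
eight-band scheme used throughout this package — delta 1–4, theta 4–7, low
alpha 8–10, high alpha 10–12, low beta 13–20, high beta 20–30, low gamma 30–45
and high gamma 45–70 Hz. Note the deliberate gaps at [7, 8) and [12, 13) Hz;
:func:`bridged_bands` extends theta and high alpha to close them for
sensitivity analyses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ParameterError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ParameterError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )

    def contains(self, freq: float) -> bool:
        return self.f_low <= freq < self.f_high

    @property
    def width(self) -> float:
        return self.f_high - self.f_low


PAPER_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 12.0),
    BandDefinition("beta_low", 13.0, 20.0),
    BandDefinition("beta_high", 20.0, 30.0),
    BandDefinition("gamma_low", 30.0, 45.0),
    BandDefinition("gamma_high", 45.0, 70.0),
)

#: Bands feeding the standard index numerator.
TI_NUMERATOR = ("theta", "alpha_low", "alpha_high")
#: Bands forming the combined-beta denominator.
TI_DENOMINATOR = ("beta_low", "beta_high")
#: Extra numerator band of the delta-augmented variant.
TI_DELTA = "delta"


def bridged_bands() -> tuple[BandDefinition, ...]:
    """The default set with theta extended to 8 Hz and high alpha to 13 Hz."""
    out = []
    for b in PAPER_BANDS:
        if b.name == "theta":
            b = BandDefinition("theta", b.f_low, 8.0)
        elif b.name == "alpha_high":
            b = BandDefinition("alpha_high", b.f_low, 13.0)
        out.append(b)
    return tuple(out)


def check_nonoverlapping(bands: Sequence[BandDefinition]) -> None:
    """Raise :class:`ParameterError` if any two bands overlap.

    Half-open semantics: adjacent bands sharing one edge do not overlap.
    """
    ordered = sorted(bands, key=lambda b: b.f_low)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.f_low < lo.f_high:
            raise ParameterError(
                f"bands {lo.name!r} and {hi.name!r} overlap: "
                f"[{lo.f_low}, {lo.f_high}) vs [{hi.f_low}, {hi.f_high})"
            )


def band_set_hash(bands: Iterable[BandDefinition]) -> str:
    """Short stable digest of a band set, used as a provenance tag."""
    canon = ";".join(
        f"{b.name}:{b.f_low:g}-{b.f_high:g}"
        for b in sorted(bands, key=lambda b: (b.f_low, b.name))
    )
    return hashlib.sha1(canon.encode()).hexdigest()[:8]


def bands_by_name(bands: Iterable[BandDefinition]) -> dict[str, BandDefinition]:
    return {b.name: b for b in bands}
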