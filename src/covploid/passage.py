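"""Serial-passage generation arithmetic.

Each subcultivation transfers ``transfer_volume`` of a saturated culture
into ``culture_volume`` of fresh medium; regrowth to the same density
takes log2(dilution factor) doublings. Cell death is ignored, so the
numbers are lower bounds on the true generation count.

With 0.75 mL into 200 mL (a 1:266 dilution), each cycle contributes
log2(200/0.75) = 8.06 generations, and 100 cycles give ~806 — at least
800 generations over the experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PassageScheme", "generations_per_transfer", "total_generations", "dilution_factor"]


@dataclass(frozen=True)
class PassageScheme:
    """A serial-transfer regime: volumes in mL, number of cycles."""

    transfer_volume: float
    culture_volume: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.transfer_volume < self.culture_volume:
            raise ValueError("need 0 < transfer_volume < culture_volume")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def generations_per_transfer(scheme: PassageScheme) -> float:
    """Doublings needed to regrow after one transfer:
    log2(culture_volume / transfer_volume)."""
    return math.log2(scheme.culture_volume / scheme.transfer_volume)


def total_generations(scheme: PassageScheme) -> float:
    """Generations over the whole experiment: cycles x per-transfer."""
    return scheme.n_cycles * generations_per_transfer(scheme)


def dilution_factor(scheme: PassageScheme) -> int:
    """The conventional 1:x dilution report, floor(culture / transfer)."""
    return math.floor(scheme.culture_volume / scheme.transfer_volume)
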