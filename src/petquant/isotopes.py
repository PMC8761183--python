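"""Radioisotope decay models.

The dual-isotope contrast trick at the heart of the phantom design: lesions
carry a long-lived emitter (²²Na, t½ = 2.6 y) whose activity is effectively
constant over a working day, while the background carries ¹⁸F (t½ = 109.7 min)
which decays visibly frame to frame — so the lesion-to-background ratio rises
monotonically during a single multi-hour acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class IsotopeModel:
    """An isotope identified by name with a half-life in minutes.

    ``half_life`` may be ``math.inf`` for an idealised stable source.
    """

    name: str
    half_life: float  # minutes

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"half_life must be positive, got {self.half_life}")

    @property
    def decay_constant(self) -> float:
        """λ = ln2 / t½ in 1/min (0 for a stable isotope)."""
        if math.isinf(self.half_life):
            return 0.0
        return math.log(2.0) / self.half_life


F18 = IsotopeModel("F-18", 109.7)
NA22 = IsotopeModel("Na-22", 2.6 * 365.25 * 24 * 60)
STABLE = IsotopeModel("stable", math.inf)

_REGISTRY = {iso.name.lower(): iso for iso in (F18, NA22, STABLE)}
_REGISTRY.update({"f18": F18, "18f": F18, "na22": NA22, "22na": NA22})


def get_isotope(name: str) -> IsotopeModel:
    """Look up a built-in isotope by name (case-insensitive)."""
    key = name.lower().replace("-", "").replace(" ", "")
    full = name.lower()
    if full in _REGISTRY:
        return _REGISTRY[full]
    if key in _REGISTRY:
        return _REGISTRY[key]
    raise KeyError(f"unknown isotope {name!r}; known: {sorted(set(_REGISTRY))}")


def decay_factor(isotope: IsotopeModel, dt: float) -> float:
    """Fraction of activity remaining after ``dt`` minutes: 2^(−dt/t½).

    ``dt`` may be negative to decay-correct backwards in time.
    """
    if math.isinf(isotope.half_life):
        return 1.0
    return 2.0 ** (-dt / isotope.half_life)
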