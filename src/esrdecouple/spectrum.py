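"""The in-memory container for a first-derivative cw-ESR spectrum.

A spectrum is a pair of equal-length arrays — magnetic field in Gauss on a
strictly increasing, uniformly spaced axis, and the field-modulated
(first-derivative) intensity in arbitrary units — plus the microwave
frequency in GHz, which is needed whenever field positions are converted to
g values, and a free-form provenance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field, replace as _replace
from typing import Any

import numpy as np

from .errors import InvalidInputError

#: relative tolerance on field-step uniformity (fraction of the mean step)
UNIFORMITY_RTOL = 1e-3


@dataclass
class Spectrum:
    field: np.ndarray
    intensity: np.ndarray
    mw_freq_GHz: float | None = None
    meta: dict[str, Any] = _field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.intensity.ndim != 1:
            raise InvalidInputError("field and intensity must be 1-D arrays")
        if self.field.size != self.intensity.size:
            raise InvalidInputError(
                f"length mismatch: {self.field.size} field vs "
                f"{self.intensity.size} intensity samples"
            )
        if self.field.size >= 2:
            steps = np.diff(self.field)
            if np.any(steps <= 0):
                raise InvalidInputError("field axis must be strictly increasing")
            mean = steps.mean()
            if np.max(np.abs(steps - mean)) > UNIFORMITY_RTOL * mean:
                raise InvalidInputError(
                    "field axis must be uniformly spaced "
                    f"(max deviation {np.max(np.abs(steps - mean)):.3g} G "
                    f"vs mean step {mean:.3g} G)"
                )

    @property
    def p(self) -> int:
        """Number of samples."""
        return self.field.size

    @property
    def step(self) -> float:
        """Field increment in Gauss."""
        if self.field.size < 2:
            raise InvalidInputError("step undefined for a <2-point spectrum")
        return float((self.field[-1] - self.field[0]) / (self.field.size - 1))

    def with_intensity(self, intensity: np.ndarray, **meta: Any) -> "Spectrum":
        """Copy of this spectrum with a new intensity array and extra meta keys."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return _replace(self, intensity=np.asarray(intensity, float), meta=new_meta)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.intensity**2)))
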