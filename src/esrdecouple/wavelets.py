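"""Undecimated (stationary / à-trous) discrete wavelet transform.

Every Detail and Approximation component keeps the full input length, so no
spectral resolution is lost — the property that makes component-level
selection usable for separating hyperfine from super-hyperfine structure.

Convention
----------
The analysis/synthesis pair is folded into a single zero-phase operation per
level: with the orthonormal low-/high-pass pair ``(h, g)`` upsampled by
``2**(j-1)`` at level ``j`` (the à-trous scheme), the level-``j`` transfer
functions applied to the running approximation are ``|H|^2 / 2`` and
``|G|^2 / 2``.  Because Daubechies filters satisfy the conjugate-quadrature
identity ``|H|^2 + |G|^2 = 2``, this makes the decomposition *additive*::

    A_0 = f,   A_{j-1} = A_j + D_j,   f = A_N + D_1 + ... + D_N

so that "subtracting the Detail at level j" and "keeping the level-j
Approximation" are the same operation, components are zero-phase aligned
with the input (peak positions do not shift between components), and the
inverse transform of a selection is simply the sum of the retained
components.  With the default periodic boundary the transform is exactly
circular-shift covariant and perfectly reconstructing; the symmetric option
transforms the even (mirror) extension of the signal and truncates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt

from .errors import InvalidInputError, LevelOverflowError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletFilter",
    "UDWTDecomposition",
    "max_levels",
    "udwt",
    "iudwt",
]


@dataclass(frozen=True)
class WaveletFilter:
    """An orthonormal two-channel filter bank (scaling + wavelet filter).

    ``lowpass`` sums to sqrt(2) and ``highpass`` is its quadrature mirror
    ``g[k] = (-1)**k h[L-1-k]`` (sum 0).
    """

    name: str
    lowpass: tuple[float, ...]
    highpass: tuple[float, ...]

    @property
    def n_taps(self) -> int:
        return len(self.lowpass)

    @classmethod
    def from_name(cls, name: str) -> "WaveletFilter":
        """Build from a PyWavelets orthogonal wavelet name (e.g. ``'db6'``)."""
        try:
            w = pywt.Wavelet(name)
        except ValueError as exc:
            raise InvalidInputError(f"unknown wavelet {name!r}") from exc
        if not w.orthogonal:
            raise InvalidInputError(f"wavelet {name!r} is not orthogonal")
        h = np.asarray(w.rec_lo, dtype=float)  # ascending-index form, sums to sqrt 2
        L = h.size
        g = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
        return cls(name=name, lowpass=tuple(h), highpass=tuple(g))

    def frequency_response(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """DTFT of the two filters at angular frequencies ``theta`` (rad/sample)."""
        m = np.arange(self.n_taps)
        e = np.exp(-1j * np.multiply.outer(np.asarray(theta, float), m))
        return e @ np.asarray(self.lowpass), e @ np.asarray(self.highpass)


@dataclass
class UDWTDecomposition:
    """Per-level full-length Detail and Approximation arrays.

    ``details[j-1]`` and ``approximations[j-1]`` hold D_j and A_j for
    j = 1..N, each of length ``p`` (the input length).  ``j0`` is the default
    reconstruction level (set to N).
    """

    p: int
    levels: int
    details: list[np.ndarray]
    approximations: list[np.ndarray]
    wavelet: str
    boundary: str
    j0: int

    def detail(self, j: int) -> np.ndarray:
        self._check_level(j)
        return self.details[j - 1]

    def approximation(self, j: int) -> np.ndarray:
        self._check_level(j)
        return self.approximations[j - 1]

    def _check_level(self, j: int) -> None:
        if not 1 <= j <= self.levels:
            raise LevelOverflowError(
                f"level {j} outside decomposition range 1..{self.levels}"
            )


def max_levels(p: int) -> int:
    """Maximum decomposition depth ``floor(log2 p)`` for a p-sample signal."""
    if p != int(p) or p < 1:
        raise InvalidInputError(f"signal length must be a positive integer, got {p!r}")
    return int(p).bit_length() - 1


def _as_filter(wavelet: str | WaveletFilter) -> WaveletFilter:
    if isinstance(wavelet, WaveletFilter):
        return wavelet
    return WaveletFilter.from_name(wavelet)


def udwt(
    signal: Sequence[float] | np.ndarray,
    wavelet: str | WaveletFilter = "db6",
    levels: int | None = None,
    boundary: str = "periodic",
) -> UDWTDecomposition:
    """Undecimated DWT of a 1-D signal.

    Parameters
    ----------
    signal : array-like
        Finite-valued 1-D signal (e.g. spectrum intensity).
    wavelet : str or WaveletFilter
        Orthogonal wavelet; default the 12-tap Daubechies wavelet with six
        vanishing moments (``db6``).
    levels : int, optional
        Decomposition depth; defaults to ``max_levels(len(signal))``.
        Requesting more raises :class:`LevelOverflowError`.
    boundary : {'periodic', 'symmetric'}
        Signal extension.  Periodic keeps every invariant (perfect
        reconstruction, telescoping, shift covariance) exact; symmetric
        avoids wrap-around artifacts for spectra whose ends do not match.
    """
    f = np.asarray(signal, dtype=float)
    if f.ndim != 1:
        raise InvalidInputError("signal must be 1-D")
    if f.size < 1:
        raise InvalidInputError("signal is empty")
    if not np.all(np.isfinite(f)):
        raise InvalidInputError("signal contains non-finite samples")
    p = f.size
    n_max = max_levels(p)
    if levels is None:
        levels = n_max
    if levels < 1:
        raise InvalidInputError(f"levels must be >= 1, got {levels}")
    if levels > n_max:
        raise LevelOverflowError(
            f"{levels} levels requested but max_levels({p}) = {n_max}"
        )
    wf = _as_filter(wavelet)

    if boundary == "periodic":
        work = f
    elif boundary == "symmetric":
        work = np.concatenate([f, f[::-1]])
    else:
        raise InvalidInputError(
            f"boundary must be 'periodic' or 'symmetric', got {boundary!r}"
        )
    q = work.size
    spectrum = np.fft.rfft(work)
    omega = 2.0 * np.pi * np.arange(spectrum.size) / q

    details: list[np.ndarray] = []
    approximations: list[np.ndarray] = []
    for j in range(1, levels + 1):
        theta = np.remainder(omega * (1 << (j - 1)), 2.0 * np.pi)
        H, G = wf.frequency_response(theta)
        lowpass_gain = (H.real**2 + H.imag**2) / 2.0
        highpass_gain = (G.real**2 + G.imag**2) / 2.0
        details.append(np.fft.irfft(highpass_gain * spectrum, n=q)[:p])
        spectrum = lowpass_gain * spectrum
        approximations.append(np.fft.irfft(spectrum, n=q)[:p])

    return UDWTDecomposition(
        p=p,
        levels=levels,
        details=details,
        approximations=approximations,
        wavelet=wf.name,
        boundary=boundary,
        j0=levels,
    )


def iudwt(
    decomp: UDWTDecomposition,
    keep_details: Iterable[int] | None = None,
    keep_approx: bool = True,
) -> np.ndarray:
    """Partial inverse: sum of the retained Details (and final Approximation).

    Under the additive convention the synthesis filters are already folded
    into the stored components, so reconstruction from a selection is their
    sum; keeping everything returns the input to float precision.  An empty
    selection returns the zero signal (logged as a warning, not an error).
    """
    if keep_details is None:
        selected = set(range(1, decomp.levels + 1))
    else:
        selected = {int(j) for j in keep_details}
        bad = selected - set(range(1, decomp.levels + 1))
        if bad:
            raise SelectionError(
                f"detail levels {sorted(bad)} outside 1..{decomp.levels}"
            )
    out = np.zeros(decomp.p)
    if not selected and not keep_approx:
        logger.warning("iudwt: empty component selection; returning zero signal")
        return out
    for j in selected:
        out += decomp.details[j - 1]
    if keep_approx:
        out += decomp.approximations[decomp.levels - 1]
    return out
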