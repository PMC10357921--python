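"""First-order cw-ESR spectrum simulation.

Two regimes are covered, both to first order in the hyperfine interaction:

* isotropic solution spectra — sticks at ``B0 + sum_k m_k A_k`` with
  multinomial weights from the equivalent-nucleus multiplets, convolved with
  a first-derivative Gaussian or Lorentzian line;
* axial frozen-powder spectra — an orientation average uniform in
  ``cos(theta)`` with the usual axial angular dependences
  ``g(θ) = sqrt(g∥² cos²θ + g⊥² sin²θ)`` and
  ``A(θ) = sqrt(A∥² g∥² cos²θ + A⊥² g⊥² sin²θ) / g(θ)``.

Nuclear Zeeman and second-order shifts are omitted throughout; line
positions are therefore splitting-faithful, which is all the downstream
peak-to-peak extraction uses.  Fields are in Gauss, frequencies in GHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import constants as _const

from .errors import (
    CombinatorialOverflowError,
    GridSpanError,
    InvalidInputError,
    UnsupportedSymmetryError,
)
from .spectrum import Spectrum

__all__ = [
    "NucleusGroup",
    "SpinSystem",
    "FieldGrid",
    "stick_pattern",
    "center_field",
    "g_from_field",
    "simulate_isotropic",
    "simulate_axial_powder",
    "add_noise",
]

_H_PLANCK = _const.h
_BOHR_MAGNETON = _const.physical_constants["Bohr magneton"][0]
#: hν/μB in Gauss per GHz at g = 1
_GAUSS_PER_GHZ = _H_PLANCK * 1e9 / _BOHR_MAGNETON * 1e4

#: default cap on the total first-order line count
DEFAULT_LINE_CAP = 10**6

_GAUSSIAN_FWHM = "gaussian-fwhm-of-absorption"
_PEAK_TO_PEAK = "peak-to-peak"
_LORENTZIAN_PP = "lorentzian-peak-to-peak"  # alias kept for config files


@dataclass(frozen=True)
class NucleusGroup:
    """``n`` equivalent nuclei of spin ``I`` with hyperfine coupling ``A`` (Gauss).

    ``A`` is either a scalar (isotropic) or an axial pair ``(A_perp, A_par)``.
    The group splits a line into ``2 n I + 1`` components with multinomial
    weights.
    """

    A: float | tuple[float, float]
    I: float
    n: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1 or self.n != int(self.n):
            raise InvalidInputError(f"nucleus count must be a positive integer: {self.n}")
        two_I = 2 * self.I
        if self.I <= 0 or abs(two_I - round(two_I)) > 1e-9:
            raise InvalidInputError(f"nuclear spin must be a positive half-integer: {self.I}")
        if isinstance(self.A, (tuple, list)):
            if len(self.A) == 3:
                ax, ay, az = self.A
                if abs(ax - ay) > 1e-9:
                    raise UnsupportedSymmetryError(
                        f"A tensor {self.A} is rhombic; only axial (Ax = Ay) is supported"
                    )
                object.__setattr__(self, "A", (float(ax), float(az)))
            elif len(self.A) != 2:
                raise UnsupportedSymmetryError(f"A must be scalar or (A_perp, A_par): {self.A}")

    @property
    def is_axial(self) -> bool:
        return isinstance(self.A, tuple)

    @property
    def multiplet_size(self) -> int:
        return int(round(2 * self.n * self.I)) + 1

    def a_components(self) -> tuple[float, float]:
        """(A_perp, A_par); an isotropic coupling is returned doubled up."""
        if self.is_axial:
            return self.A  # type: ignore[return-value]
        return (float(self.A), float(self.A))


@dataclass(frozen=True)
class SpinSystem:
    """A paramagnetic center: g value(s), nucleus groups, and the lineshape.

    ``g`` is a scalar for isotropic systems or ``(g_perp, g_par)`` for axial
    ones.  ``linewidth`` is in Gauss under the stated convention —
    ``'gaussian-fwhm-of-absorption'`` (FWHM of the absorption profile) or
    ``'peak-to-peak'`` (first-derivative peak-to-peak width).
    """

    g: float | tuple[float, float]
    nuclei: tuple[NucleusGroup, ...] = ()
    lineshape: str = "gaussian"
    linewidth: float = 1.0
    linewidth_convention: str = _GAUSSIAN_FWHM
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise InvalidInputError(f"lineshape must be gaussian|lorentzian: {self.lineshape}")
        if self.linewidth <= 0:
            raise InvalidInputError(f"linewidth must be positive: {self.linewidth}")
        conv = self.linewidth_convention
        if conv == _LORENTZIAN_PP:
            object.__setattr__(self, "linewidth_convention", _PEAK_TO_PEAK)
        elif conv not in (_GAUSSIAN_FWHM, _PEAK_TO_PEAK):
            raise InvalidInputError(f"unknown linewidth convention: {conv}")
        if isinstance(self.g, (tuple, list)):
            if len(self.g) == 3:
                gx, gy, gz = self.g
                if abs(gx - gy) > 1e-9:
                    raise UnsupportedSymmetryError("rhombic g tensors are not supported")
                object.__setattr__(self, "g", (float(gx), float(gz)))
            elif len(self.g) == 2:
                object.__setattr__(self, "g", (float(self.g[0]), float(self.g[1])))
            else:
                raise UnsupportedSymmetryError(f"g must be scalar or (g_perp, g_par): {self.g}")
            if any(v <= 0 for v in self.g):
                raise InvalidInputError("g values must be positive")
        elif self.g <= 0:
            raise InvalidInputError("g must be positive")

    @property
    def is_axial(self) -> bool:
        return isinstance(self.g, tuple)

    @property
    def n_lines(self) -> int:
        out = 1
        for grp in self.nuclei:
            out *= grp.multiplet_size
        return out


@dataclass(frozen=True)
class FieldGrid:
    """Uniform field axis specification in Gauss."""

    start_G: float
    stop_G: float
    points: int

    def __post_init__(self) -> None:
        if self.stop_G <= self.start_G:
            raise InvalidInputError("grid stop must exceed start")
        if self.points < 2:
            raise InvalidInputError("grid needs at least 2 points")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.start_G, self.stop_G, self.points)


def center_field(g: float, mw_freq_GHz: float) -> float:
    """Resonance field hν/(g μB) in Gauss."""
    if g <= 0 or mw_freq_GHz <= 0:
        raise InvalidInputError("g and microwave frequency must be positive")
    return _GAUSS_PER_GHZ * mw_freq_GHz / g


def g_from_field(field_G: float, mw_freq_GHz: float) -> float:
    """g value of a resonance at ``field_G`` Gauss; exact inverse of center_field."""
    if field_G <= 0:
        raise InvalidInputError(f"resonance field must be positive: {field_G}")
    if mw_freq_GHz is None or mw_freq_GHz <= 0:
        raise InvalidInputError("microwave frequency must be positive and known")
    return _GAUSS_PER_GHZ * mw_freq_GHz / field_G


def _group_multiplet(group: NucleusGroup) -> tuple[np.ndarray, np.ndarray]:
    """Total-m values and multinomial weights for one equivalent group."""
    size_single = int(round(2 * group.I)) + 1
    w = np.ones(size_single)
    for _ in range(group.n - 1):
        w = np.convolve(w, np.ones(size_single))
    m_max = group.n * group.I
    m = m_max - np.arange(w.size)  # descending m, symmetric
    return m, w


def _stick_table(
    nuclei: Sequence[NucleusGroup], cap: int = DEFAULT_LINE_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """(S, K) matrix of m-combinations and length-S weight vector."""
    total = 1
    for grp in nuclei:
        total *= grp.multiplet_size
    if total > cap:
        raise CombinatorialOverflowError(
            f"{total} first-order lines exceed the cap of {cap}"
        )
    weights = np.array([1.0])
    m_grids: list[np.ndarray] = []
    for grp in nuclei:
        m, w = _group_multiplet(grp)
        m_grids.append(m)
        weights = np.multiply.outer(weights, w).ravel()
    if nuclei:
        mesh = np.meshgrid(*m_grids, indexing="ij")
        m_matrix = np.stack([mm.ravel() for mm in mesh], axis=1)
    else:
        m_matrix = np.zeros((1, 0))
    return m_matrix, weights


def stick_pattern(
    nuclei: Sequence[NucleusGroup],
    normalize: bool = True,
    cap: int = DEFAULT_LINE_CAP,
) -> list[tuple[float, float]]:
    """First-order stick offsets (Gauss, relative to the line center) and weights.

    Offsets are all ``sum_k m_k A_k`` over nuclear magnetic quantum-number
    combinations; weights are products of the equivalent-group multiplicities,
    normalized to 1 by default.  Axial groups contribute via ``|A_par|``
    orientation handling happens in :func:`simulate_axial_powder`, which
    supplies effective scalar couplings per orientation.
    """
    m_matrix, weights = _stick_table(nuclei, cap=cap)
    a_vec = np.array(
        [grp.A if not grp.is_axial else grp.A[1] for grp in nuclei], dtype=float
    )
    offsets = m_matrix @ np.abs(a_vec) if nuclei else np.zeros(1)
    if normalize:
        weights = weights / weights.sum()
    order = np.argsort(offsets)
    return [(float(offsets[i]), float(weights[i])) for i in order]


def _sigma_gaussian(width: float, convention: str) -> float:
    if convention == _GAUSSIAN_FWHM:
        return width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # first-derivative peak-to-peak width of a Gaussian is 2 sigma
    return width / 2.0


def _gamma_lorentzian(width: float, convention: str) -> float:
    if convention == _PEAK_TO_PEAK:
        # derivative extrema of a Lorentzian sit at +/- gamma/sqrt(3)
        return np.sqrt(3.0) / 2.0 * width
    return width / 2.0  # FWHM of the absorption is 2 gamma


def _derivative_lineshape(
    x: np.ndarray, lineshape: str, width: float, convention: str
) -> np.ndarray:
    """First derivative of a unit-area absorption line at offsets ``x``."""
    if lineshape == "gaussian":
        s = _sigma_gaussian(width, convention)
        return -x / (s**3 * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * (x / s) ** 2)
    gamma = _gamma_lorentzian(width, convention)
    return -2.0 * gamma * x / (np.pi * (x**2 + gamma**2) ** 2)


def _accumulate_lines(
    field: np.ndarray,
    positions: np.ndarray,
    weights: np.ndarray,
    sys: SpinSystem,
    chunk: int = 512,
) -> np.ndarray:
    y = np.zeros_like(field)
    for i in range(0, positions.size, chunk):
        x = field[None, :] - positions[i : i + chunk, None]
        y += weights[i : i + chunk] @ _derivative_lineshape(
            x, sys.lineshape, sys.linewidth, sys.linewidth_convention
        )
    return y


def _resolve_grid(
    grid: FieldGrid | tuple | None,
    lo: float,
    hi: float,
    width: float,
    default_points: int = 4096,
) -> FieldGrid:
    if grid is None:
        return FieldGrid(lo - 10.0 * width, hi + 10.0 * width, default_points)
    if isinstance(grid, tuple):
        grid = FieldGrid(*grid)
    if grid.start_G > lo - 5.0 * width or grid.stop_G < hi + 5.0 * width:
        raise GridSpanError(
            f"grid [{grid.start_G:g}, {grid.stop_G:g}] G does not cover the "
            f"required span [{lo - 5.0 * width:g}, {hi + 5.0 * width:g}] G "
            "(resonances plus 5 linewidths)"
        )
    return grid


def simulate_isotropic(
    sys: SpinSystem,
    mw_freq_GHz: float,
    grid: FieldGrid | tuple | None = None,
) -> Spectrum:
    """Isotropic solution spectrum (first derivative) of ``sys`` at ``mw_freq_GHz``."""
    if sys.is_axial:
        raise UnsupportedSymmetryError("simulate_isotropic requires a scalar g")
    for grp in sys.nuclei:
        if grp.is_axial:
            raise UnsupportedSymmetryError(
                f"nucleus group {grp.label or grp.A} is axial; use simulate_axial_powder"
            )
    b0 = center_field(float(sys.g), mw_freq_GHz)
    sticks = stick_pattern(sys.nuclei)
    positions = b0 + np.array([s[0] for s in sticks])
    weights = np.array([s[1] for s in sticks])
    fg = _resolve_grid(grid, positions.min(), positions.max(), sys.linewidth)
    field = fg.axis
    y = _accumulate_lines(field, positions, weights, sys)
    return Spectrum(
        field=field,
        intensity=y,
        mw_freq_GHz=mw_freq_GHz,
        meta={
            "system": sys.name or "isotropic",
            "kind": "simulated-isotropic",
            "n_lines": len(sticks),
            "lineshape": sys.lineshape,
            "linewidth_G": sys.linewidth,
        },
    )


def _axial_angular(
    sys: SpinSystem, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Effective g and per-group effective A for cos(theta) values ``x``."""
    g_perp, g_par = sys.g  # type: ignore[misc]
    c2 = x**2
    s2 = 1.0 - c2
    g_eff = np.sqrt(g_par**2 * c2 + g_perp**2 * s2)
    a_eff = np.empty((x.size, len(sys.nuclei)))
    for k, grp in enumerate(sys.nuclei):
        a_perp, a_par = grp.a_components()
        a_eff[:, k] = (
            np.sqrt(a_par**2 * g_par**2 * c2 + a_perp**2 * g_perp**2 * s2) / g_eff
        )
    return g_eff, a_eff


def simulate_axial_powder(
    sys: SpinSystem,
    mw_freq_GHz: float,
    grid: FieldGrid | tuple | None = None,
    n_orient: int = 1024,
) -> Spectrum:
    """First-order axial frozen-powder spectrum.

    Orientations are Gauss–Legendre nodes in cos(theta) on [0, 1] (uniform
    solid-angle weighting for an axial system); per orientation the resonance
    fields are ``hν/(g(θ) μB) + sum_k m_k A_k(θ)`` and the derivative
    lineshape is accumulated with the quadrature weight.
    """
    if not sys.is_axial:
        raise UnsupportedSymmetryError("simulate_axial_powder requires axial g")
    if n_orient < 2:
        raise InvalidInputError("n_orient must be >= 2")
    nodes, quad_w = leggauss(n_orient)
    x = 0.5 * (nodes + 1.0)  # cos(theta) in (0, 1)
    quad_w = quad_w / quad_w.sum()

    m_matrix, stick_w = _stick_table(sys.nuclei)
    stick_w = stick_w / stick_w.sum()
    g_eff, a_eff = _axial_angular(sys, x)
    b0 = _GAUSS_PER_GHZ * mw_freq_GHz / g_eff

    if sys.nuclei:
        # per-orientation reach of the hyperfine offsets
        offset_reach = np.abs(m_matrix).max(axis=0) @ a_eff.T
        lo = float(np.min(b0 - offset_reach))
        hi = float(np.max(b0 + offset_reach))
    else:
        lo, hi = float(b0.min()), float(b0.max())
    fg = _resolve_grid(grid, float(lo), float(hi), sys.linewidth)
    field = fg.axis

    y = np.zeros_like(field)
    chunk = max(1, 65536 // max(1, m_matrix.shape[0]))
    for i in range(0, x.size, chunk):
        pos = b0[i : i + chunk, None] + a_eff[i : i + chunk] @ m_matrix.T
        w = quad_w[i : i + chunk, None] * stick_w[None, :]
        y += _accumulate_lines(field, pos.ravel(), w.ravel(), sys, chunk=4096)
    return Spectrum(
        field=field,
        intensity=y,
        mw_freq_GHz=mw_freq_GHz,
        meta={
            "system": sys.name or "axial-powder",
            "kind": "simulated-axial-powder",
            "n_orient": n_orient,
            "lineshape": sys.lineshape,
            "linewidth_G": sys.linewidth,
        },
    )


def add_noise(spec: Spectrum, sigma: float, seed: int) -> Spectrum:
    """Add white Gaussian noise of std ``sigma * max|intensity|`` (seeded)."""
    if sigma < 0:
        raise InvalidInputError(f"noise fraction must be >= 0: {sigma}")
    if sigma == 0:
        return spec.with_intensity(spec.intensity.copy(), noise_sigma=0.0)
    rng = np.random.default_rng(seed)
    scale = sigma * np.max(np.abs(spec.intensity))
    noisy = spec.intensity + rng.normal(0.0, scale, spec.p)
    return spec.with_intensity(noisy, noise_sigma=sigma, noise_seed=seed)
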