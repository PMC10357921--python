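"""Pseudo-decoupling: split a spectrum into hyperfine and super-hyperfine parts.

The procedure adapts a wavelet denoising scheme (component selection on an
undecimated DWT) to feature extraction: Details at the fine scales 1..j*-1
(noise plus unwanted fine structure) are discarded, the level-j* Detail is
taken as the super-hyperfine component, and the level-j* Approximation —
equivalently the original spectrum minus Details 1..j* — is taken as the
hyperfine component.  Because the transform is additive (see
:mod:`esrdecouple.wavelets`) the two phrasings "subtract the Details" and
"keep the Approximation" coincide exactly, and::

    hyperfine + superhyperfine + discarded == input

holds to float precision whenever the selections partition levels 1..j*.

The working level j* is a *user* choice, as in visual practice;
:func:`level_scan` provides the per-level diagnostics (line counts, spacing
regularity, residual energy) that inform it, and :func:`suggest_level` a
simple energy-gap heuristic for blind two-scale spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import LevelOverflowError, SelectionError
from .spectrum import Spectrum
from .wavelets import UDWTDecomposition, iudwt, max_levels, udwt

logger = logging.getLogger(__name__)

__all__ = [
    "DecoupleResult",
    "pseudo_decouple",
    "level_scan",
    "suggest_level",
    "denoise",
]


@dataclass
class DecoupleResult:
    """Outcome of a pseudo-decoupling run.

    ``hyperfine`` is the level-``j_star`` Approximation path (coarse
    structure: primary splittings, g anisotropy), ``superhyperfine`` the sum
    of the retained Detail levels (``shf_levels``, default ``{j_star}``),
    and ``discarded`` the sum of the removed Details.  With
    ``keep_approx=True`` the three components sum to the input exactly;
    with ``keep_approx=False`` (strict feature-from-Details reading) the
    hyperfine part omits the final Approximation, which is kept in
    ``baseline``.
    """

    j_star: int
    removed_levels: frozenset[int]
    shf_levels: frozenset[int]
    keep_approx: bool
    hyperfine: Spectrum
    superhyperfine: Spectrum
    discarded: Spectrum
    baseline: Spectrum | None
    decomposition: UDWTDecomposition
    input_ref: dict

    def components_sum(self) -> np.ndarray:
        """Sum of all parts; equals the input intensity to float precision."""
        total = (
            self.hyperfine.intensity
            + self.superhyperfine.intensity
            + self.discarded.intensity
        )
        if self.baseline is not None:
            total = total + self.baseline.intensity
        return total


def _component(spec: Spectrum, intensity: np.ndarray, role: str, j_star: int) -> Spectrum:
    return spec.with_intensity(intensity, component=role, j_star=j_star)


def pseudo_decouple(
    spec: Spectrum,
    j_star: int,
    removed_levels: Iterable[int] | None = None,
    shf_levels: Iterable[int] | None = None,
    wavelet: str = "db6",
    boundary: str = "periodic",
    keep_approx: bool = True,
) -> DecoupleResult:
    """Split ``spec`` at level ``j_star`` into hyperfine / super-hyperfine parts.

    Parameters
    ----------
    spec : Spectrum
        Input first-derivative spectrum.
    j_star : int
        Working decomposition level; must not exceed ``max_levels(p)``.
    removed_levels : iterable of int, optional
        Detail levels to discard.  Default: every level in ``1..j_star`` not
        claimed by ``shf_levels``.  Together with ``shf_levels`` they must
        partition ``{1..j_star}`` so the additivity invariant holds.
    shf_levels : iterable of int, optional
        Detail levels forming the super-hyperfine component (default
        ``{j_star}``; pass e.g. ``{4, 5}`` for multi-band structure).
    keep_approx : bool
        If True (default) the hyperfine component is the level-``j_star``
        Approximation; if False it is the sum of Details ``j_star+1..N``
        only, the final Approximation being returned as ``baseline``.
    """
    n_max = max_levels(spec.p)
    if not 1 <= j_star <= n_max:
        raise LevelOverflowError(
            f"j_star={j_star} outside 1..{n_max} for a {spec.p}-point spectrum"
        )
    shf = frozenset(int(j) for j in shf_levels) if shf_levels is not None else frozenset({j_star})
    if not shf or not shf <= set(range(1, j_star + 1)):
        raise SelectionError(
            f"super-hyperfine levels {sorted(shf)} must be a non-empty subset of 1..{j_star}"
        )
    if removed_levels is None:
        removed = frozenset(range(1, j_star + 1)) - shf
    else:
        removed = frozenset(int(j) for j in removed_levels)
    if not removed <= set(range(1, j_star + 1)) - shf:
        raise SelectionError(
            f"removed levels {sorted(removed)} must lie in 1..{j_star} and not "
            f"overlap the super-hyperfine selection {sorted(shf)}"
        )
    if removed | shf != set(range(1, j_star + 1)):
        raise SelectionError(
            "removed_levels and shf_levels together must cover every level in "
            f"1..{j_star} (got {sorted(removed | shf)}) so that the components "
            "sum back to the input"
        )

    decomp = udwt(spec.intensity, wavelet=wavelet, levels=n_max, boundary=boundary)
    approx_j = decomp.approximation(j_star)
    if keep_approx:
        hf = approx_j
        baseline = None
    else:
        hf = approx_j - decomp.approximation(n_max)
        baseline = _component(
            spec, decomp.approximation(n_max), "baseline", j_star
        )
    shf_arr = iudwt(decomp, keep_details=shf, keep_approx=False)
    disc = iudwt(decomp, keep_details=removed, keep_approx=False) if removed else np.zeros(spec.p)

    return DecoupleResult(
        j_star=j_star,
        removed_levels=removed,
        shf_levels=shf,
        keep_approx=keep_approx,
        hyperfine=_component(spec, hf, "hyperfine", j_star),
        superhyperfine=_component(spec, shf_arr, "superhyperfine", j_star),
        discarded=_component(spec, disc, "discarded", j_star),
        baseline=baseline,
        decomposition=decomp,
        input_ref=dict(spec.meta),
    )


def level_scan(
    spec: Spectrum,
    j_max: int | None = None,
    wavelet: str = "db6",
    boundary: str = "periodic",
    min_prominence: float = 0.02,
    cv_resolved: float = 0.25,
) -> pd.DataFrame:
    """Per-level diagnostics to guide the (visual) choice of j*.

    For each candidate level ``j`` the hyperfine candidate is the level-j
    Approximation and the super-hyperfine candidate the level-j Detail.
    The table reports the number of resolved derivative lines in each, the
    coefficient of variation of the hyperfine line spacings, and residual
    RMS fractions.  A candidate is flagged ``resolved`` when it shows at
    least two lines whose spacings are regular (CV below ``cv_resolved``);
    pure noise never earns the flag.  The scan does not itself choose j*.
    """
    from .extract import find_lines, splittings  # local import; extract imports us not

    n_max = max_levels(spec.p)
    if j_max is None:
        j_max = n_max
    if j_max > n_max:
        raise LevelOverflowError(f"j_max={j_max} exceeds max_levels({spec.p})={n_max}")
    decomp = udwt(spec.intensity, wavelet=wavelet, levels=j_max, boundary=boundary)
    rms_in = spec.rms() or 1.0

    rows = []
    for j in range(1, j_max + 1):
        row: dict = {"level": j}
        for role, arr in (
            ("hf", decomp.approximation(j)),
            ("shf", decomp.detail(j)),
        ):
            rel_rms = float(np.sqrt(np.mean(arr**2)) / rms_in)
            if rel_rms < 1e-8:
                # numerically empty component: counting its roundoff
                # wiggles as lines would be meaningless
                n, cv = 0, np.nan
            else:
                peaks = find_lines(spec.with_intensity(arr), min_prominence=min_prominence)
                n = peaks.n_lines
                cv = np.nan
                if n >= 3:
                    spac = splittings(peaks).spacings
                    mean = spac.mean()
                    cv = float(spac.std() / mean) if mean > 0 else np.nan
                elif n == 2:
                    cv = 0.0
            row[f"n_lines_{role}"] = n
            row[f"spacing_cv_{role}"] = cv
            row[f"rms_{role}"] = rel_rms
        removed = spec.intensity - decomp.approximation(j) - decomp.detail(j)
        row["rms_removed"] = float(np.sqrt(np.mean(removed**2)) / rms_in)
        rows.append(row)

    # a hyperfine candidate is resolved when its (regular) line count is
    # stable against the adjacent level — band-passed noise never is; a
    # super-hyperfine candidate when its comb is tightly regular
    for i, row in enumerate(rows):
        neighbour = rows[i + 1] if i + 1 < len(rows) else rows[i - 1] if i else None
        stable = neighbour is not None and neighbour["n_lines_hf"] == row["n_lines_hf"]
        row["resolved_hf"] = bool(
            row["n_lines_hf"] >= 2
            and stable
            and np.isfinite(row["spacing_cv_hf"])
            and row["spacing_cv_hf"] <= cv_resolved
        )
        row["resolved_shf"] = bool(
            row["n_lines_shf"] >= 3
            and np.isfinite(row["spacing_cv_shf"])
            and row["spacing_cv_shf"] <= 0.4 * cv_resolved
        )
    return pd.DataFrame(rows)


def suggest_level(
    spec: Spectrum,
    wavelet: str = "db6",
    boundary: str = "periodic",
    min_prominence: float = 0.02,
) -> int:
    """Line-count-stability heuristic for the working level.

    Emulates the iterative practice of subtracting Details level by level
    and watching the resulting spectrum: as j grows, the line count of the
    level-j Approximation falls while fine structure is being stripped,
    then sits on a plateau once only the coarse multiplet remains, and
    finally collapses when the multiplet itself merges.  The suggestion is
    the middle of the longest plateau (count >= 2 lines).  Intended as a
    starting point next to :func:`level_scan`, not a replacement for
    inspecting it.
    """
    scan = level_scan(
        spec, wavelet=wavelet, boundary=boundary, min_prominence=min_prominence
    )
    counts = scan["n_lines_hf"].to_numpy()
    plateaus = []  # (count, start, end) runs of equal line count
    i = 0
    while i < counts.size:
        j = i
        while j + 1 < counts.size and counts[j + 1] == counts[i]:
            j += 1
        if counts[i] >= 2:
            plateaus.append((int(counts[i]), i, j))
        i = j + 1
    if not plateaus:
        return 1
    # the coarse multiplet is the *smallest* stable line count still >= 2;
    # prefer genuine plateaus (length >= 2) over one-level accidents
    stable = [p for p in plateaus if p[2] > p[1]]
    count_min = min(p[0] for p in (stable or plateaus))
    cand = [p for p in (stable or plateaus) if p[0] == count_min]
    _, lo, hi = cand[-1]
    return int((lo + hi) // 2) + 1  # 1-based level


def denoise(
    spec: Spectrum,
    noise_levels: Iterable[int],
    wavelet: str = "db6",
    boundary: str = "periodic",
) -> Spectrum:
    """Remove the listed Detail levels (typically the fine, noisy ones).

    Reconstructs from everything except ``noise_levels``; an empty set is
    the identity.  Repeating the operation with the same level set changes
    the result only through the small transition-band overlap of the level
    filters (see the methods note), not through any stored state.
    """
    levels = sorted({int(j) for j in noise_levels})
    if not levels:
        return spec.with_intensity(spec.intensity.copy(), denoised_levels=())
    n_max = max_levels(spec.p)
    if levels[0] < 1 or levels[-1] > n_max:
        raise LevelOverflowError(
            f"noise levels {levels} outside 1..{n_max} for a {spec.p}-point spectrum"
        )
    decomp = udwt(spec.intensity, wavelet=wavelet, levels=n_max, boundary=boundary)
    removed = iudwt(decomp, keep_details=levels, keep_approx=False)
    return spec.with_intensity(
        spec.intensity - removed, denoised_levels=tuple(levels)
    )
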