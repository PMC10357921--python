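"""Turn decoupled spectral components into reported numbers.

A resonance "line" in a first-derivative spectrum is a maximum/minimum pair
with the zero crossing between them; the crossing is the line center, so
couplings are estimated from crossing-to-crossing spacings, which are then
clustered into bins and mapped to hyperfine/super-hyperfine splittings.
Field positions convert to g values through the resonance condition
``h nu = g muB B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .decouple import DecoupleResult
from .errors import InsufficientLinesError, InvalidInputError
from .simulate import g_from_field
from .spectrum import Spectrum

__all__ = [
    "PeakSet",
    "Splittings",
    "SplittingBin",
    "ExtractionReport",
    "find_lines",
    "splittings",
    "pairwise_splittings",
    "bin_splittings",
    "g_from_field",
    "extract_report",
]


@dataclass
class PeakSet:
    """Detected derivative-line features of one spectral component.

    ``maxima``/``minima`` are all prominent extremum fields (Gauss), with
    ``maxima_prominences``/``minima_prominences`` their prominences as a
    fraction of the component's maximum amplitude; ``crossings`` holds one
    zero-crossing field per matched max->min pair (the line centers) and
    ``prominences`` the paired line prominence.
    """

    maxima: np.ndarray
    minima: np.ndarray
    crossings: np.ndarray
    prominences: np.ndarray
    maxima_prominences: np.ndarray = None  # type: ignore[assignment]
    minima_prominences: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.maxima_prominences is None:
            self.maxima_prominences = np.zeros_like(np.asarray(self.maxima))
        if self.minima_prominences is None:
            self.minima_prominences = np.zeros_like(np.asarray(self.minima))

    @property
    def n_lines(self) -> int:
        return self.crossings.size


@dataclass
class Splittings:
    """Peak-to-peak splittings of a component, labeled by kind.

    ``spacings`` are consecutive crossing-to-crossing distances (the
    estimator used for coupling constants); ``widths`` are the within-line
    max-to-min distances (the derivative peak-to-peak linewidths).
    """

    spacings: np.ndarray
    widths: np.ndarray


@dataclass
class SplittingBin:
    mean_splitting: float
    members: list[float]
    count: int


@dataclass
class ExtractionReport:
    """g values and coupling constants traced back to detected features."""

    g_values: list[tuple[str, float, float]]  # (label, g, field G)
    A_values: list[tuple[str, float, str, SplittingBin]]  # (label, G, component, bin)
    j_star: int | None = None
    warnings: list[str] = _dcfield(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "g_values": [
                {"label": lab, "g": g, "field_G": b} for lab, g, b in self.g_values
            ],
            "A_values": [
                {
                    "label": lab,
                    "A_G": a,
                    "component": comp,
                    "bin": {
                        "mean_G": bin_.mean_splitting,
                        "count": bin_.count,
                        "members_G": list(bin_.members),
                    },
                }
                for lab, a, comp, bin_ in self.A_values
            ],
            "j_star": self.j_star,
            "warnings": list(self.warnings),
        }


def _interp_crossing(field: np.ndarray, y: np.ndarray, i0: int, i1: int) -> float:
    """Zero-crossing field between sample indices i0 < i1 (linear interp)."""
    seg = y[i0 : i1 + 1]
    sign = np.sign(seg)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        # no sign change (component rides on an offset): closest approach to zero
        k = i0 + int(np.argmin(np.abs(seg)))
        return float(field[k])
    k = i0 + int(idx[idx.size // 2])  # central crossing of the segment
    y0, y1 = y[k], y[k + 1]
    frac = y0 / (y0 - y1)
    return float(field[k] + frac * (field[k + 1] - field[k]))


def find_lines(component: Spectrum, min_prominence: float = 0.02) -> PeakSet:
    """Detect derivative lines: prominent extrema paired into max->min lines.

    ``min_prominence`` is a fraction of the component's maximum absolute
    amplitude; an all-zero component yields an empty PeakSet.
    """
    if not 0 < min_prominence < 1:
        raise InvalidInputError(f"min_prominence must be in (0, 1): {min_prominence}")
    y = component.intensity
    if y.size == 0:
        raise InvalidInputError("component is empty")
    amp = float(np.max(np.abs(y)))
    empty = PeakSet(
        np.array([]), np.array([]), np.array([]), np.array([]), np.array([]), np.array([])
    )
    if amp == 0.0:
        return empty
    prom = min_prominence * amp
    imax, pmax = find_peaks(y, prominence=prom)
    imin, pmin = find_peaks(-y, prominence=prom)

    # merge extrema in field order, then pair each maximum with the minimum
    # that immediately follows it (a first-derivative absorption line)
    tagged = sorted(
        [(i, +1, pr) for i, pr in zip(imax, pmax["prominences"])]
        + [(i, -1, pr) for i, pr in zip(imin, pmin["prominences"])]
    )
    crossings: list[float] = []
    line_prom: list[float] = []
    k = 0
    while k < len(tagged) - 1:
        i0, kind0, pr0 = tagged[k]
        i1, kind1, pr1 = tagged[k + 1]
        if kind0 == +1 and kind1 == -1:
            crossings.append(_interp_crossing(component.field, y, i0, i1))
            line_prom.append(min(pr0, pr1) / amp)
            k += 2
        else:
            k += 1
    return PeakSet(
        maxima=component.field[imax],
        minima=component.field[imin],
        crossings=np.asarray(crossings),
        prominences=np.asarray(line_prom),
        maxima_prominences=pmax["prominences"] / amp,
        minima_prominences=pmin["prominences"] / amp,
    )


def splittings(peaks: PeakSet) -> Splittings:
    """All peak-to-peak splittings of a detected line set."""
    if peaks.n_lines < 2:
        raise InsufficientLinesError(
            f"need at least 2 lines to measure splittings, got {peaks.n_lines}"
        )
    spac = np.diff(np.sort(peaks.crossings))
    # widths: pair each crossing's flanking max/min (same ordering as pairing)
    mx = np.sort(peaks.maxima)
    mn = np.sort(peaks.minima)
    widths = []
    for c in np.sort(peaks.crossings):
        left = mx[mx < c]
        right = mn[mn > c]
        if left.size and right.size:
            widths.append(float(right[0] - left[-1]))
    return Splittings(spacings=spac, widths=np.asarray(widths))


def pairwise_splittings(peaks: PeakSet, max_lag: int = 2) -> np.ndarray:
    """Distances between line centers up to ``max_lag`` neighbours apart.

    When two couplings are nearly commensurate (one close to an integer
    multiple of the other) their combined comb collapses onto a
    quasi-uniform line sequence and adjacent spacings alone report only the
    smaller value; distances between next-nearest (and further) pairs
    recover the larger one, and the binning step keeps the scales separate.
    The mapping of bins to nuclei remains the analyst's step.
    """
    if peaks.n_lines < 2:
        raise InsufficientLinesError(
            f"need at least 2 lines to measure splittings, got {peaks.n_lines}"
        )
    if max_lag < 1:
        raise InvalidInputError(f"max_lag must be >= 1: {max_lag}")
    c = np.sort(peaks.crossings)
    out = [c[lag:] - c[:-lag] for lag in range(1, min(max_lag, c.size - 1) + 1)]
    return np.concatenate(out)


def bin_splittings(values, tol: float = 0.3) -> list[SplittingBin]:
    """Cluster splittings into bins of "the same or very similar" value.

    Single-linkage on the sorted values with gap threshold ``tol``; chains
    whose total spread exceeds ``2 * tol`` are split recursively at their
    largest internal gap, so every bin satisfies ``max - min <= 2 * tol``.
    Bins are sorted by descending mean.  Deterministic: input is sorted
    ascending before clustering.
    """
    if tol <= 0:
        raise InvalidInputError(f"tol must be positive: {tol}")
    vals = np.sort(np.asarray(list(values), dtype=float))
    if vals.size == 0:
        return []

    def _split(chunk: np.ndarray) -> list[np.ndarray]:
        if chunk.size == 1 or chunk[-1] - chunk[0] <= 2 * tol:
            return [chunk]
        gaps = np.diff(chunk)
        k = int(np.argmax(gaps)) + 1
        return _split(chunk[:k]) + _split(chunk[k:])

    chunks: list[np.ndarray] = []
    start = 0
    gap_idx = np.nonzero(np.diff(vals) > tol)[0]
    for end in list(gap_idx + 1) + [vals.size]:
        chunks.extend(_split(vals[start:end]))
        start = end
    bins = [
        SplittingBin(
            mean_splitting=float(c.mean()), members=[float(v) for v in c], count=c.size
        )
        for c in chunks
    ]
    bins.sort(key=lambda b: b.mean_splitting, reverse=True)
    return bins


def _dominant_crossing(component: Spectrum, peaks: PeakSet) -> float | None:
    """Crossing of the maximum-amplitude line (None if no lines)."""
    if peaks.n_lines == 0:
        return None
    return float(peaks.crossings[int(np.argmax(peaks.prominences))])


def _absorption_max_field(component: Spectrum) -> float:
    """Field of the absorption maximum (integral of the derivative spectrum)."""
    absorb = cumulative_trapezoid(component.intensity, component.field, initial=0.0)
    return float(component.field[int(np.argmax(absorb))])


def _parallel_progression(
    maxima: np.ndarray,
    prominences: np.ndarray,
    upper_limit: float,
    rel_tol: float = 0.15,
    spacing_range: tuple[float, float] = (40.0, 350.0),
) -> np.ndarray | None:
    """Leading members of an equally spaced metal-quartet progression.

    Scans the derivative maxima below ``upper_limit`` (i.e. clear of the
    perpendicular powder envelope that swallows the upper quartet lines)
    for runs of near-equal spacings in ``spacing_range`` and returns the
    run with the largest summed prominence, so residual baseline ripples
    cannot outvote the genuine quartet features.
    """
    order = np.argsort(maxima)
    pos_all, prom_all = np.asarray(maxima)[order], np.asarray(prominences)[order]
    keep = pos_all < upper_limit
    pos_all, prom_all = pos_all[keep], prom_all[keep]
    best, best_score = None, 0.0
    for i in range(pos_all.size - 1):
        for j in range(i + 1, pos_all.size):
            a0 = pos_all[j] - pos_all[i]
            if not spacing_range[0] <= a0 <= spacing_range[1]:
                continue
            members = [i, j]
            for k in range(j + 1, pos_all.size):
                if abs(pos_all[k] - pos_all[members[-1]] - a0) <= rel_tol * a0:
                    members.append(k)
            prom = prom_all[members]
            if prom.min() < 0.3 * prom.max():
                continue  # genuine quartet members have comparable prominence
            score = float(prom.sum())
            if score > best_score:
                best, best_score = pos_all[members], score
    return best


def _window_splitting(
    shf: Spectrum,
    lo: float,
    hi: float,
    min_prominence: float,
    tol: float,
) -> tuple[float | None, SplittingBin | None]:
    """Splitting of the most populated spacing bin inside a field window."""
    mask = (shf.field >= lo) & (shf.field <= hi)
    if mask.sum() < 8:
        return None, None
    sub = Spectrum(shf.field[mask], shf.intensity[mask], shf.mw_freq_GHz, dict(shf.meta))
    peaks = find_lines(sub, min_prominence=min_prominence)
    if peaks.n_lines < 2:
        return None, None
    # sub-cluster at a third of the nominal tolerance: powder windows mix
    # spacings from adjacent orientation regions, and the tight sub-cluster
    # is stable when single lines drift across the window edge
    bins = bin_splittings(splittings(peaks).spacings, tol=tol / 3.0)
    if not bins:
        return None, None
    top = max(bins, key=lambda b: (b.count, b.mean_splitting))
    refined = _autocorr_refine(sub, top.mean_splitting)
    return (refined if refined is not None else top.mean_splitting), top


def _autocorr_refine(
    component: Spectrum, candidate_G: float, search: float = 0.3
) -> float | None:
    """Refine a splitting estimate to the autocorrelation peak near it.

    The lag of the autocorrelation maximum pools every sample in the window,
    so it is far less sensitive to the position jitter of individual zero
    crossings than the spacing of any one line pair.  Searches within
    ``±search`` (fractional) of the candidate lag; parabolic sub-sample
    interpolation.  Returns None when no interior local maximum exists.
    """
    y = component.intensity - component.intensity.mean()
    n = y.size
    lag0 = candidate_G / component.step
    k_lo = max(1, int(np.floor(lag0 * (1.0 - search))))
    k_hi = min(n - 2, int(np.ceil(lag0 * (1.0 + search))))
    if k_hi - k_lo < 2:
        return None
    ac = np.correlate(y, y, mode="full")[n - 1 :]
    seg = ac[k_lo : k_hi + 1]
    k = k_lo + int(np.argmax(seg))
    if k <= k_lo or k >= k_hi:
        return None  # ran into the search edge: no genuine local maximum
    denom = ac[k - 1] - 2.0 * ac[k] + ac[k + 1]
    delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
    return float((k + delta) * component.step)


def extract_report(
    result: DecoupleResult,
    mode: str = "isotropic",
    min_prominence: float = 0.02,
    tol_radical: float = 0.3,
    tol_metal: float = 3.0,
    window_halfwidth_G: float = 45.0,
    min_bin_members: int = 2,
    shf_max_lag: int = 2,
    n_parallel_lines: int = 4,
    parallel_clearance_G: float = 100.0,
) -> ExtractionReport:
    """Full spectral-analysis report from a pseudo-decoupling result.

    Isotropic mode: the primary coupling is the largest spacing bin of the
    hyperfine component; super-hyperfine couplings are the spacing bins of
    the super-hyperfine component (singleton bins are reported in warnings
    only).  Axial mode: g_par and A_par(metal) come from the low-field
    parallel quartet of the hyperfine component, g_perp from its dominant
    zero crossing, and the ligand splittings from the super-hyperfine
    component inside two field windows — around the perpendicular feature
    ("low-field") and around the highest-field quartet line ("high-field").
    Whatever cannot be found is recorded in ``warnings``; nothing is
    invented.
    """
    report = ExtractionReport(g_values=[], A_values=[], j_star=result.j_star)
    hf, shf = result.hyperfine, result.superhyperfine
    nu = hf.mw_freq_GHz

    hf_peaks = find_lines(hf, min_prominence=min_prominence)
    shf_peaks = find_lines(shf, min_prominence=min_prominence)

    if mode == "isotropic":
        if hf_peaks.n_lines >= 2:
            # the hyperfine component is a single multiplet whose individual
            # spacings are distorted by line overlap; the robust estimator of
            # the primary coupling is the mean spacing over the multiplet
            spac = splittings(hf_peaks).spacings
            med = float(np.median(spac))
            keep = spac[(spac > 0.5 * med) & (spac < 2.0 * med)]
            primary = SplittingBin(float(keep.mean()), [float(v) for v in keep], keep.size)
            report.A_values.append(("A_primary", primary.mean_splitting, "hyperfine", primary))
        else:
            report.warnings.append(
                f"hyperfine component has {hf_peaks.n_lines} line(s); no primary splitting"
            )
        center = _dominant_crossing(hf, hf_peaks)
        if center is not None and nu:
            report.g_values.append(("g_iso", g_from_field(center, nu), center))
        elif nu is None:
            report.warnings.append("microwave frequency unknown; g values skipped")
        if shf_peaks.n_lines >= 2:
            for i, b in enumerate(
                bin_splittings(
                    pairwise_splittings(shf_peaks, max_lag=shf_max_lag),
                    tol=tol_radical,
                ),
                1,
            ):
                if b.count >= min_bin_members:
                    report.A_values.append((f"A_shf{i}", b.mean_splitting, "superhyperfine", b))
                else:
                    report.warnings.append(
                        f"singleton super-hyperfine bin at {b.mean_splitting:.2f} G ignored"
                    )
        else:
            report.warnings.append("super-hyperfine component has <2 lines")
        return report

    if mode != "axial":
        raise InvalidInputError(f"mode must be 'isotropic' or 'axial': {mode}")

    # the perpendicular feature: the zero crossing nearest the absorption
    # maximum (the integral of the derivative peaks at the g_perp singularity)
    b_abs = _absorption_max_field(hf)
    if hf_peaks.n_lines:
        k = int(np.argmin(np.abs(hf_peaks.crossings - b_abs)))
        b_perp = float(hf_peaks.crossings[k])
        if abs(b_perp - b_abs) > window_halfwidth_G:
            b_perp = b_abs  # no crossing near the singularity; use it directly
    else:
        b_perp = b_abs
    if nu:
        report.g_values.append(("g_perp", g_from_field(b_perp, nu), b_perp))
    else:
        report.warnings.append("microwave frequency unknown; g values skipped")

    # parallel metal quartet: equally spaced progression of derivative maxima
    # on the low-field side, clear of the perpendicular envelope; the upper
    # members may be buried, so the quartet center is extrapolated from the
    # observed spacing (n_parallel_lines = 2I+1 of the metal nucleus)
    prog = _parallel_progression(
        hf_peaks.maxima,
        hf_peaks.maxima_prominences,
        b_abs - parallel_clearance_G,
    )
    b_q_top = None
    if prog is not None:
        a_par = float(np.diff(prog).mean())
        b_par = float(prog[0] + (n_parallel_lines - 1) / 2.0 * a_par)
        b_q_top = float(prog[0] + (n_parallel_lines - 1) * a_par)
        if nu:
            report.g_values.append(("g_par", g_from_field(b_par, nu), b_par))
        qbin = SplittingBin(
            a_par, [float(d) for d in np.diff(prog)], len(prog) - 1
        )
        report.A_values.append(("A_par_metal", a_par, "hyperfine", qbin))
    else:
        report.warnings.append("parallel quartet progression not found")

    if shf_peaks.n_lines >= 2:
        # low-field window: around the perpendicular feature; high-field
        # window: everything above it (the ligand multiplet on the isolated
        # highest-field metal line lives there).  Both windows are anchored
        # on the perpendicular feature, the most stable landmark.
        windows = (
            ("A_N_lowfield", b_perp - window_halfwidth_G, b_perp + window_halfwidth_G),
            ("A_N_highfield", b_perp + 0.5 * window_halfwidth_G, float(shf.field[-1])),
        )
        for label, lo, hi in windows:
            val, b = _window_splitting(shf, lo, hi, min_prominence, tol_metal)
            if val is None:
                report.warnings.append(f"no splitting resolved in the {label} window")
            else:
                report.A_values.append((label, val, "superhyperfine", b))
    else:
        report.warnings.append("super-hyperfine component has <2 lines")
    return report
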