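"""Independent reference implementations used only to cross-check the package.

The UDWT oracle works entirely in the time domain (explicit circular
convolution with à-trous-upsampled, zero-phase autocorrelation kernels),
while the package computes the same transform through FFT transfer
functions — two disjoint numerical routes to the same definition.
"""

import numpy as np
import pywt
from scipy.ndimage import convolve1d


def _filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(pywt.Wavelet(name).rec_lo)
    L = h.size
    g = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
    return h, g


def _upsample(f: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return f
    out = np.zeros((f.size - 1) * factor + 1)
    out[::factor] = f
    return out


def udwt_reference(signal: np.ndarray, wavelet: str = "db6", levels: int = 4):
    """Time-domain additive à-trous UDWT (periodic boundary).

    Per level the zero-phase kernels are the autocorrelations of the
    upsampled low-/high-pass filters divided by two; Details and
    Approximations are produced by circular convolution of the running
    approximation with them.
    """
    h, g = _filters(wavelet)
    a = np.asarray(signal, float).copy()
    details, approximations = [], []
    for j in range(1, levels + 1):
        up = 1 << (j - 1)
        hj = _upsample(h, up)
        gj = _upsample(g, up)
        kh = np.convolve(hj, hj[::-1]) / 2.0  # odd length, symmetric -> zero phase
        kg = np.convolve(gj, gj[::-1]) / 2.0
        d = convolve1d(a, kg, mode="wrap")
        a = convolve1d(a, kh, mode="wrap")
        details.append(d)
        approximations.append(a.copy())
    return details, approximations


def multiplet_weights(n: int, two_i_plus_1: int) -> np.ndarray:
    """Intensity pattern of n equivalent nuclei by repeated self-convolution."""
    w = np.ones(two_i_plus_1)
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, w)
    return out
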