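# Copper phthalocyanine-type Cu(2+)-N4 adduct. The reference regime is
# slow-motional (rotational correlation time ~10^-7.5 s), which first-order
# simulation cannot represent; this definition is a SYNTHETIC frozen
# axial-powder stand-in with the published tensors, for demonstrating the
# workflow only -- not for quantitative comparison with slow-motional data.
name: M-I
kind: axial_powder
g: [2.05, 2.20]
nuclei:
  - {label: Cu, A: [18.82, 197.46], I: 1.5, n: 1}
  - {label: N, A: [14.64, 16.89], I: 1, n: 4}
lineshape: gaussian
linewidth_convention: gaussian-fwhm-of-absorption
j_star: 4
bands:
  L:
    mw_freq_GHz: 1.4
    linewidth_G: 2.5
    grid: {start_G: 55.0, stop_G: 855.0, points: 1160}
  S:
    mw_freq_GHz: 3.3
    linewidth_G: 2.6
    grid: {start_G: 675.0, stop_G: 1475.0, points: 1160}
  X:
    mw_freq_GHz: 9.8
    linewidth_G: 3.0
    grid: {start_G: 2780.0, stop_G: 3620.0, points: 1160}
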