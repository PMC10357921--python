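# 9,10-dimethylanthracene cation radical: isotropic, 7 x 5 x 5 = 175 lines.
# Couplings and g from the reference simulation table; Gaussian linewidths
# (FWHM of the absorption) narrow toward lower band. Grids are chosen so the
# ortho/meta super-hyperfine band (1.2-2.6 G) falls in the level-7 detail
# octave, the working level of the reference analysis.
name: R-I
kind: isotropic
g: 2.0316
nuclei:
  - {label: methyl-H, A: 7.91, I: 0.5, n: 6}
  - {label: ortho-H, A: -2.49, I: 0.5, n: 4}
  - {label: meta-H, A: -1.20, I: 0.5, n: 4}
lineshape: gaussian
linewidth_convention: gaussian-fwhm-of-absorption
j_star: 7
bands:
  L:
    mw_freq_GHz: 1.4
    linewidth_G: 0.17
    grid: {start_G: 452.35, stop_G: 532.35, points: 8192}
  S:
    mw_freq_GHz: 3.3
    linewidth_G: 0.18
    grid: {start_G: 1120.58, stop_G: 1200.58, points: 8192}
  X:
    mw_freq_GHz: 9.8
    linewidth_G: 0.2
    grid: {start_G: 3406.41, stop_G: 3486.41, points: 8192}
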