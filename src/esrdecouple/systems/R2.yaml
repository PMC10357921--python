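# Bridged biaryl (6-hydrodipyridoimidazole-type) cation radical.
# RECONSTRUCTED parameters: the published simulation table for this system
# is internally inconsistent (duplicated triple, missing CH2/N couplings),
# so the couplings below are taken from the extracted-value summary:
# CH2 pair 24.2 G, two 14N 4.35 G, ring-proton pairs 2.6 / 2.4 / 0.65 G.
# Level-5 detail resolves the small ring couplings; full separation at 7.
name: R-II
kind: isotropic
g: 2.0316
nuclei:
  - {label: CH2, A: 24.2, I: 0.5, n: 2}
  - {label: N, A: 4.35, I: 1, n: 2}
  - {label: ring-H-3, A: 2.6, I: 0.5, n: 2}
  - {label: ring-H-5, A: 2.4, I: 0.5, n: 2}
  - {label: ring-H-4, A: 0.65, I: 0.5, n: 2}
lineshape: lorentzian
linewidth_convention: peak-to-peak
j_star: 5
bands:
  L:
    mw_freq_GHz: 1.4
    linewidth_G: 0.05
    grid: {start_G: 447.35, stop_G: 537.35, points: 6656}
  S:
    mw_freq_GHz: 3.3
    linewidth_G: 0.05
    grid: {start_G: 1115.58, stop_G: 1205.58, points: 6656}
  X:
    mw_freq_GHz: 9.8
    linewidth_G: 0.06
    grid: {start_G: 3401.41, stop_G: 3491.41, points: 6656}
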