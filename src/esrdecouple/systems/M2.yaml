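# Axial frozen-powder Cu(2+)-N4 adduct: 63Cu (I=3/2) parallel quartet,
# four equivalent 14N ligands. First-order powder average; Lorentzian
# peak-to-peak linewidths per band. Working level 4 (details 1-3 removed).
name: M-II
kind: axial_powder
g: [2.05, 2.19]
nuclei:
  - {label: Cu, A: [18.60, 198.68], I: 1.5, n: 1}
  - {label: N, A: [14.99, 17.78], I: 1, n: 4}
lineshape: lorentzian
linewidth_convention: peak-to-peak
j_star: 4
bands:
  L:
    mw_freq_GHz: 1.4
    linewidth_G: 5.5
    grid: {start_G: 25.0, stop_G: 905.0, points: 1160}
  S:
    mw_freq_GHz: 3.3
    linewidth_G: 6.0
    grid: {start_G: 640.0, stop_G: 1520.0, points: 1160}
  X:
    mw_freq_GHz: 9.8
    linewidth_G: 6.5
    grid: {start_G: 2755.0, stop_G: 3635.0, points: 1160}
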