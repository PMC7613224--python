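{
  "description": "Default plasma 1H resonance library for the synthetic cohort generator. Positions (ppm) follow standard plasma assignments quoted at 0.005-ppm resolution; relative_amplitudes are per-position area shares (normalized to sum 1) so that typical_concentration is the metabolite's total spectral area in relative units; linewidth is the Lorentzian FWHM in ppm (broad for CPMG-attenuated lipoprotein envelopes, narrow for small molecules). principal_ppm marks the reporting resonance used for quantification when it is not the largest-amplitude one (e.g. threonine, whose CH3 doublet is buried under lactate). Abundances preserve the plasma signal hierarchy (lipid envelopes and glucose largest, then lactate, then amino acids) while compressing the full concentration dynamic range so that every modelled discriminator carries a quantifiable resonance.",
  "metabolites": [
    {"name": "lipoprotein_ch3", "positions": [0.855], "relative_amplitudes": [1.0], "linewidth": 0.04, "typical_concentration": 3.0},
    {"name": "lipid_ch2", "positions": [1.255], "relative_amplitudes": [1.0], "linewidth": 0.05, "typical_concentration": 3.5},
    {"name": "saturated_lipid", "positions": [1.575], "relative_amplitudes": [1.0], "linewidth": 0.04, "typical_concentration": 1.5},
    {"name": "unsaturated_lipid", "positions": [5.305], "relative_amplitudes": [1.0], "linewidth": 0.04, "typical_concentration": 1.5},
    {"name": "lipid_allylic", "positions": [2.005], "relative_amplitudes": [1.0], "linewidth": 0.03, "typical_concentration": 1.0},
    {"name": "lactate", "positions": [1.33, 1.34, 4.115, 4.125, 4.135, 4.145], "relative_amplitudes": [0.41, 0.34, 0.0625, 0.0625, 0.0625, 0.0625], "linewidth": 0.004, "typical_concentration": 2.5},
    {"name": "threonine", "positions": [1.325, 1.335, 3.585, 4.255], "relative_amplitudes": [0.2778, 0.2778, 0.2222, 0.2222], "linewidth": 0.004, "typical_concentration": 0.45, "principal_ppm": 3.585},
    {"name": "beta_hydroxybutyrate", "positions": [1.195, 1.205, 2.295, 2.395], "relative_amplitudes": [0.375, 0.375, 0.125, 0.125], "linewidth": 0.004, "typical_concentration": 0.20, "principal_ppm": 1.195},
    {"name": "nac1", "positions": [2.045], "relative_amplitudes": [1.0], "linewidth": 0.012, "typical_concentration": 0.60},
    {"name": "nac2", "positions": [2.075], "relative_amplitudes": [1.0], "linewidth": 0.012, "typical_concentration": 0.35},
    {"name": "glucose", "positions": [3.245, 3.405, 3.465, 3.485, 3.525, 3.725, 3.845, 3.885, 5.235], "relative_amplitudes": [0.1124, 0.1124, 0.1124, 0.1124, 0.1124, 0.1685, 0.1348, 0.0899, 0.0449], "linewidth": 0.005, "typical_concentration": 5.0},
    {"name": "alanine", "positions": [1.475, 1.485], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.004, "typical_concentration": 0.35},
    {"name": "valine", "positions": [0.985, 0.995, 1.035, 1.045], "relative_amplitudes": [0.25, 0.25, 0.25, 0.25], "linewidth": 0.004, "typical_concentration": 0.22},
    {"name": "leucine", "positions": [0.955, 0.965], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.004, "typical_concentration": 0.12},
    {"name": "isoleucine", "positions": [0.935, 1.005], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.004, "typical_concentration": 0.06},
    {"name": "glutamine", "positions": [2.135, 2.455], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.006, "typical_concentration": 0.55},
    {"name": "glutamate", "positions": [2.355], "relative_amplitudes": [1.0], "linewidth": 0.006, "typical_concentration": 0.08},
    {"name": "citrate", "positions": [2.535, 2.665], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.005, "typical_concentration": 0.11},
    {"name": "creatinine", "positions": [3.045, 4.065], "relative_amplitudes": [0.6, 0.4], "linewidth": 0.004, "typical_concentration": 0.07},
    {"name": "choline", "positions": [3.205], "relative_amplitudes": [1.0], "linewidth": 0.005, "typical_concentration": 0.20},
    {"name": "glycine", "positions": [3.565], "relative_amplitudes": [1.0], "linewidth": 0.004, "typical_concentration": 0.25},
    {"name": "histidine", "positions": [7.065, 7.785], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.005, "typical_concentration": 0.08},
    {"name": "phenylalanine", "positions": [7.335, 7.385, 7.435], "relative_amplitudes": [0.4, 0.2, 0.4], "linewidth": 0.005, "typical_concentration": 0.06},
    {"name": "tyrosine", "positions": [6.905, 7.195], "relative_amplitudes": [0.5, 0.5], "linewidth": 0.005, "typical_concentration": 0.06},
    {"name": "formate", "positions": [8.465], "relative_amplitudes": [1.0], "linewidth": 0.004, "typical_concentration": 0.03},
    {"name": "acetate", "positions": [1.925], "relative_amplitudes": [1.0], "linewidth": 0.004, "typical_concentration": 0.04},
    {"name": "pyruvate", "positions": [2.375], "relative_amplitudes": [1.0], "linewidth": 0.004, "typical_concentration": 0.07},
    {"name": "acetone", "positions": [2.235], "relative_amplitudes": [1.0], "linewidth": 0.004, "typical_concentration": 0.03}
  ]
}
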