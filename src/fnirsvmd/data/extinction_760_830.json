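{
  "comment": "Default molar extinction coefficients for HbO/HbR at 760 and 830 nm in uM^-1 mm^-1 (tabulated compendium values, converted from cm^-1 M^-1 by a factor of 1e-7), and a default differential path length factor for adult prefrontal recordings. All values are overridable per call.",
  "wavelengths_nm": [760.0, 830.0],
  "alpha_uM_mm": {
    "hbo": [5.86e-05, 9.74e-05],
    "hbr": [0.000154852, 6.9304e-05]
  },
  "dpf": 6.0,
  "emitter_detector_distance_mm": 30.0
}
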