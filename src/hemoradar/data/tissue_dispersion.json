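{
  "schema": {
    "description": "Multi-term Cole-Cole dispersion parameters per material. Complex relative permittivity at angular frequency w is eps_inf + sum_k delta_eps[k] / (1 + (j*w*tau[k])**(1 - alpha[k])) + sigma_static / (j*w*eps0). Materials with an empty term list are non-dispersive.",
    "fields": {
      "eps_inf": "high-frequency relative permittivity, dimensionless, >= 1",
      "terms": "list of [delta_eps (dimensionless), tau (seconds), alpha (dimensionless, in [0,1))]",
      "sigma_static": "static ionic conductivity, S/m"
    },
    "provenance": "Gabriel-family parametric literature values for biological tissues in the RF range (the same parameterization used by public tissue-property databases); skull uses cortical-bone parameters. Substrate is a generic RF laminate (eps_r 3.38, lossless). Validated range 10 MHz - 3 GHz.",
    "version": "1.0"
  },
  "materials": {
    "blood": {
      "eps_inf": 4.0,
      "terms": [[56.0, 8.377e-12, 0.10], [5200.0, 1.32629e-07, 0.10], [0.0, 1.59155e-04, 0.20], [0.0, 1.5915e-02, 0.00]],
      "sigma_static": 0.700
    },
    "white_matter": {
      "eps_inf": 4.0,
      "terms": [[32.0, 7.958e-12, 0.10], [100.0, 7.958e-09, 0.10], [40000.0, 5.3052e-05, 0.30], [35000000.0, 7.958e-03, 0.02]],
      "sigma_static": 0.020
    },
    "gray_matter": {
      "eps_inf": 4.0,
      "terms": [[45.0, 7.958e-12, 0.10], [400.0, 1.5915e-08, 0.15], [200000.0, 1.06103e-04, 0.22], [45000000.0, 5.305e-03, 0.00]],
      "sigma_static": 0.020
    },
    "csf": {
      "eps_inf": 4.0,
      "terms": [[65.0, 7.958e-12, 0.10], [40.0, 1.592e-09, 0.00], [0.0, 1.59155e-04, 0.00], [0.0, 1.5915e-02, 0.00]],
      "sigma_static": 2.000
    },
    "skull": {
      "eps_inf": 2.5,
      "terms": [[10.0, 1.3263e-11, 0.20], [180.0, 7.9577e-08, 0.20], [5000.0, 1.59155e-04, 0.20], [100000.0, 1.5915e-02, 0.00]],
      "sigma_static": 0.020
    },
    "air": {
      "eps_inf": 1.0,
      "terms": [],
      "sigma_static": 0.0
    },
    "substrate": {
      "eps_inf": 3.38,
      "terms": [],
      "sigma_static": 0.0
    }
  }
}
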