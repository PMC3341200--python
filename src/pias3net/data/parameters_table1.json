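{
  "k_Mp73E_plus": 0.00015,
  "k_Mp73_minus": 0.03,
  "k_Mp73a_plus": 0.025,
  "k_Mp409_plus": 0.0001,
  "k_Mp409_minus": 0.04,
  "k_Mass": 0.01,
  "k_Mdiss": 1.0,
  "k_Mp73ass": 0.03,
  "k_Mp73diss": 0.5,
  "k_Mp409ass": 0.0001,
  "k_Mp409diss": 1.0,
  "k_Mppass": 0.01,
  "k_Mppdiss": 1.0,
  "k_Sp_plus": 0.0002,
  "k_Sp_minus": 0.04,
  "k_Spass": 0.005,
  "k_Spdiss": 0.2,
  "p_MITF": 1.0,
  "gamma_MITF": 0.0012,
  "gamma_MITFp73": 0.02,
  "gamma_MITFp409": 0.01,
  "p_PIAS3": 0.262,
  "gamma_PIAS3": 0.008,
  "p_STAT3": 0.211,
  "gamma_STAT3": 0.002,
  "k_Rp_plus": 0.0004,
  "k_Rp_minus": 0.04,
  "ERKp_baseline": 10.0,
  "JAKp_baseline": 10.0,
  "k_u": 0.0001,
  "RSK1_total": 500.0
}
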