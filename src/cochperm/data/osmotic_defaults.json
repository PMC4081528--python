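{
  "v_e_ul": 1.2,
  "delta_c_mol_l": 0.094,
  "duration_min": 20.0,
  "si_area_pct": 22.1,
  "si_movement_pct": 12.29,
  "shunt_radial_width_um": 57.53,
  "shunt_longitudinal_length_um": 804.31,
  "rate_constants_per_min": {
    "SV/SM": {"p_prime": 0.691, "p_doubleprime": 0.938, "alpha": 0.504},
    "ST/SM": {"p_prime": 0.499, "p_doubleprime": 0.940, "alpha": 0.435},
    "SV+ST/SM": {"p_prime": 0.869, "p_doubleprime": 0.898, "alpha": 0.549},
    "in_vivo_SV+ST/SM": {"p_prime": 0.85, "p_doubleprime": 0.9, "alpha": 0.4}
  },
  "single_channel_pf_cm3_s": 5e-14,
  "printed_channel_density_per_um2": 34500.0
}
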