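# Both perilymphatic scalae perfused with tracer; endolymph probed in SM.
species: guinea pig
tracer: THO
diffusion_coeff_cm2_s: 2.3004e-5
geometry: default
perfusion:
  scalae:
    SV: {rate_ul_min: 8.0, inlet_conc_pct: 100.0, entry_mm: 0.1, exit_mm: 15.5}
    ST: {rate_ul_min: 8.0, inlet_conc_pct: 100.0, entry_mm: 0.1, exit_mm: 16.2}
communications:
  sv_sm_min: 2.2
  st_sv_min: 9999.0
  st_sm_min: 4.6
  sv_blood_min: 1.6
  st_blood_min: 1.6
  sm_blood_min: 15.0
sim:
  dx_mm: 0.1
  dt_s: 0.5
  duration_min: 120.0
  output_dt_min: 0.25
  probes:
    - {scala: SM, x_mm: 1.0}
    - {scala: SV, x_mm: 1.0}
    - {scala: ST, x_mm: 1.0}
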