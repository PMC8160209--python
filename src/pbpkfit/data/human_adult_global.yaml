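# Human adult reference physiology: whole-body scalars plus the plasma and
# erythrocyte composition needed by the tissue-composition partition equations.
cardiac_output_L_per_h: 336.0
hematocrit: 0.45
plasma_ph: 7.4
blood_volume_L: 5.6
body_weight_kg: 70.0
plasma_composition:
  f_nl: 0.0023
  f_np: 0.0013
blood_cell_composition:
  f_ew: 0.0
  f_iw: 0.603
  f_nl: 0.0017
  f_np: 0.0029
  ap_mg_per_g: 0.5
  ph_iw: 7.22
  protein_ratio: 0.0
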