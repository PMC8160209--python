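tissue,volume_L,flow_L_per_h,f_ew,f_iw,f_nl,f_np,ap_mg_per_g,ph_iw,protein_ratio
venous_blood,3.90,336.0,0,0,0,0,0,7.4,0
arterial_blood,1.70,336.0,0,0,0,0,0,7.4,0
lung,0.55,336.0,0.336,0.446,0.022,0.0128,3.91,7.0,0.212
adipose,14.00,16.80,0.135,0.017,0.844,0.0016,0.40,7.0,0.049
bone,10.50,16.80,0.100,0.346,0.017,0.0017,0.67,7.0,0.100
brain,1.45,40.32,0.162,0.620,0.039,0.0015,0.40,7.0,0.048
gut,1.65,50.40,0.282,0.475,0.038,0.0125,2.41,7.0,0.158
heart,0.33,13.44,0.320,0.456,0.014,0.0111,2.25,7.0,0.157
kidney,0.31,63.84,0.273,0.483,0.012,0.0240,5.03,7.0,0.130
liver,1.80,21.84,0.161,0.573,0.014,0.0240,4.56,7.0,0.086
muscle,29.00,57.12,0.118,0.630,0.010,0.0072,1.53,7.0,0.064
skin,3.30,16.80,0.382,0.291,0.060,0.0044,1.32,7.0,0.277
spleen,0.15,6.72,0.207,0.579,0.0077,0.0113,3.18,7.0,0.097
rest_of_body,1.36,31.92,0.200,0.550,0.020,0.0080,1.50,7.0,0.100
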