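# Measured and reference-simulated bioyield force and deformation for Exotica papaya
# puncture tests: 3 storage days (0, 4, 7 d at 12 C) x 3 probe velocities (1.5, 2, 2.5 mm/s),
# 2 mm flat-end probe. The "level" column indexes the velocity within each storage day.
# se columns are standard errors over replicates. Relative errors are |measured-simulated|/measured*100.
storage_day,velocity_mm_s,level,force_meas_N,force_meas_se,force_sim_N,force_sim_se,force_err_pct,def_meas_mm,def_meas_se,def_sim_mm,def_sim_se,def_err_pct
0,1.5,1,17.81,0.64,17.30,0.091,2.86,1.5,0.29,2,0.15,33.33
0,2,2,17.87,2.22,17.35,0.11,2.91,1.67,0.27,2.15,0.16,28.74
0,2.5,3,18.36,0.08,17.57,0.14,4.30,1.8,0.12,2.2,0.15,22.22
4,1.5,1,14.87,0.87,14.76,0.27,0.74,1.21,0.07,2,0.20,65.28
4,2,2,15.31,2.11,15.81,0.19,3.26,1.35,0.09,2.1,0.21,55.55
4,2.5,3,16.42,0.91,16.81,0.22,2.37,1.45,0.17,2.35,0.29,62.06
7,1.5,1,13.20,2.13,11.29,0.19,14.46,1.22,0.16,1.8,0.15,47.54
7,2,2,13.43,0.89,12.22,0.20,9.00,1.38,0.05,1.85,0.18,34.05
7,2.5,3,13.55,1.33,14.29,0.20,5.46,1.43,0.44,1.9,0.16,32.86
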