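role,cohort,n_cases,n_samples,mean,median,sd,unit
mda_carotid,1,251,28,27.7,27.5,6.6,min
mda_carotid,2,105,39,24.1,20.0,9.2,min
mda_carotid,3,99,74,35.3,35.0,8.7,min
mda_other_oar,1,251,63,6.9,6.00,2.9,hr
mda_other_oar,2,105,72,7.1,7.00,0.6,hr
mda_other_oar,3,99,77,7.4,7.50,0.6,hr
mda_other_oar,hold_out,35,35,6.6,6.75,0.8,hr
physician,hold_out,35,34,4.0,4.25,1.6,hr
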