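name,mean,low,high,family,sd
growth_rate_small,0.026,0.017,0.04,beta,0.004
rupture_rate_nongrowing,0.005,0.003,0.009,beta,0.001
rupture_rate_growing,0.063,0.01,0.22,beta,0.035
rr_growth_mia,3.47,1.87,6.45,lognormal,1.15
rr_rupture_mia,2.08,1.46,2.96,lognormal,0.25
de_novo_rate,0.003,0.002,0.004,beta,0.0004
rr_de_novo_mia,3.92,1.95,7.87,lognormal,0.99
mild_after_one,0.016,0,0.037,beta,0.011
modsev_after_one,0.047,0.01,0.083,beta,0.019
mortality_after_one,0,0,0.005,beta,0.001
mild_after_two,0.032,0,0.067,beta,0.018
modsev_after_two,0.053,0.008,0.098,beta,0.023
mortality_after_two,0.011,0,0.031,beta,0.01
mild_after_sah,0.15,0.13,0.17,beta,0.007
modsev_after_sah,0.09,0.07,0.11,beta,0.007
mortality_after_sah,0.35,0.25,0.45,beta,0.033
rr_death_mild,2.02,1.7,2.4,lognormal,0.109
rr_death_modsev,4.46,4.05,4.91,lognormal,0.128
utility_mild,0.72,0.65,0.8,triangular,
utility_modsev,0.41,0.25,0.65,triangular,
utility_sah,0.64,0.52,0.71,triangular,
utility_full_recovery,1,1,1,fixed,
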