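index,bp_r,bp_se,ev_r,ev_se
RA,0.615,76.02092616,0.754,9.64037899
ABC,0.678,70.83996637,0.786,9.06843885
M1,0.524,82.10335013,0.692,10.5989982
M2,0.451,86.03267444,0.634,11.34996569
SCI,0.443,86.40526283,0.63,11.40039383
F,0.693,69.49911131,0.787,9.0606885
GA,0.657,72.63612711,0.774,9.30315409
H,0.436,86.75378512,0.625,11.45839242
HM,0.628,75.03459712,0.755,9.62001605
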