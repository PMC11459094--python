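drug,ABC,RA,M1,M2,HM,H,SCI,F,GA
Prednisone,21.41348,12.52244,154,191,860,11.49048,12.82616,478,26.90294
Methylprednisolone,22.18954,12.93312,160,199,896,11.82381,13.2344,498,27.76896
Prednisolone,23.2506,13.27244,178,239,1052,12.24048,13.88682,574,29.90294
Epinephrine,9.439677,6.147066,60,67,286,5.833333,6.129915,152,12.43986
Salbutamol,12.63547,7.831517,82,90,406,7.266667,7.827018,226,15.89644
Levosalbutamol,11.2617,7.089935,71,75,345,6.533333,6.971556,195,13.91665
Fluticasone,24.68887,14.23589,186,246,1076,13.16429,14.85257,584,31.87819
Salmeterol,22.05821,14.70271,136,148,610,14.43333,14.91877,314,30.49302
Flunisolide,23.42047,14.21554,164,202,876,13.11905,14.39246,472,30.02918
Ciclesonide,33.0791,19.26968,237,293,1307,17.84048,19.93245,721,42.06883
Mometasone,28.53709,16.54184,217,291,1251,15.65952,17.56746,669,38.16604
Vilanterol,19.37961,13.31373,114,118,490,13,13.22167,254,26.43986
Formoterol,18.63207,12.02841,120,135,568,11.6,12.23219,298,25.20084
Beclometasone,29.7222,17.54151,220,288,1258,16.29286,18.13098,682,38.53254
Montelukast,15.50434,10.01164,95,99,441,9.5,9.960813,243,19.97726
Zileuton,12.29661,7.592224,82,96,406,7.233333,7.816275,214,16.34288
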