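region,measure,median,mad
G,fa,0.80,0.06
B1,fa,0.69,0.07
B2,fa,0.65,0.08
B3,fa,0.67,0.07
ISTH,fa,0.74,0.08
S,fa,0.81,0.06
G,fr,0.37,0.09
B1,fr,0.33,0.05
B2,fr,0.32,0.06
B3,fr,0.35,0.06
ISTH,fr,0.36,0.10
S,fr,0.38,0.12
G,da,3.17,0.69
B1,da,3.37,0.62
B2,da,3.23,0.75
B3,da,3.10,0.72
ISTH,da,2.87,0.75
S,da,2.35,0.62
G,cv,22.7,5.0
B1,cv,23.6,4.7
B2,cv,22.0,4.6
B3,cv,20.4,4.9
ISTH,cv,19.0,4.8
S,cv,15.6,4.3
G,od,0.04,0.005
B1,od,0.05,0.015
B2,od,0.06,0.017
B3,od,0.06,0.014
ISTH,od,0.04,0.004
S,od,0.04,0.005
G,vic,0.68,0.05
B1,vic,0.65,0.05
B2,vic,0.63,0.05
B3,vic,0.65,0.06
ISTH,vic,0.66,0.06
S,vic,0.73,0.06
G,mtsat,3.86,0.46
B1,mtsat,3.63,0.42
B2,mtsat,3.54,0.39
B3,mtsat,3.32,0.42
ISTH,mtsat,3.38,0.49
S,mtsat,3.80,0.43
G,g,0.67,0.04
B1,g,0.67,0.03
B2,g,0.68,0.04
B3,g,0.71,0.04
ISTH,g,0.69,0.04
S,g,0.69,0.04
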