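measure,region,beta_age,beta_sex,beta_sex_pdsa
da,G,0.08,0.00,0.00
da,B1,0.04,-0.38,0.21
da,B2,0.04,0.19,-0.50
da,B3,0.04,-0.20,-0.26
da,ISTH,0.04,-0.12,-0.83
da,S,0.04,0.70,-0.64
mtsat,G,-0.14,0.00,0.00
mtsat,B1,-0.14,-0.09,0.10
mtsat,B2,-0.14,0.01,-0.13
mtsat,B3,-0.14,-0.44,0.23
mtsat,ISTH,-0.14,0.12,-0.91
mtsat,S,-0.14,0.69,-0.96
fr,G,0.05,0.00,0.00
fr,B1,0.05,0.00,0.00
fr,B2,0.05,0.00,0.00
fr,B3,0.05,0.00,0.00
fr,ISTH,0.05,0.00,0.00
fr,S,0.05,0.00,0.00
fa,G,0.03,0.00,0.00
fa,B1,0.03,0.00,0.00
fa,B2,0.03,0.00,0.00
fa,B3,0.03,0.00,0.00
fa,ISTH,0.03,0.00,0.00
fa,S,0.03,0.00,0.00
vic,G,0.03,0.00,0.00
vic,B1,0.03,0.00,0.00
vic,B2,0.03,0.00,0.00
vic,B3,0.03,0.00,0.00
vic,ISTH,0.03,0.00,0.00
vic,S,0.03,0.00,0.00
od,G,0.00,0.00,0.00
od,B1,0.00,0.00,0.00
od,B2,0.00,0.00,0.00
od,B3,0.00,0.00,0.00
od,ISTH,0.00,0.00,0.00
od,S,0.00,0.00,0.00
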