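behaviour,prev_agesex,prev_psa1,prev_psa2,prev_psa3,prev_psa4,prev_psa5,prev_reference,or_printed_agesex,or_printed_psa5,bias_printed_agesex,bias_printed_psa5
Binge drinks once a week or more,0.170,0.168,0.163,0.167,0.162,0.165,0.214,0.75,0.73,moderate,moderate
Both equally willing at first sex,0.882,0.886,0.888,0.890,0.901,0.899,0.911,0.73,0.87,moderate,small
Contraception used at first sex,0.864,0.864,0.872,0.868,0.872,0.864,0.820,1.39,1.39,moderate,moderate
First sex at about the right time,0.608,0.623,0.622,0.633,0.648,0.641,0.743,0.54,0.62,large,moderate
Experience not all with opposite sex,0.162,0.155,0.119,0.119,0.110,0.089,0.072,2.49,1.26,large,moderate
Had heterosexual oral sex in last year,0.715,0.727,0.742,0.747,0.746,0.747,0.793,0.65,0.77,moderate,moderate
Had heterosexual anal sex in last year,0.204,0.203,0.202,0.211,0.197,0.202,0.176,1.20,1.19,small,small
Sex without condom in last 4 weeks,0.769,0.779,0.781,0.776,0.791,0.790,0.749,1.12,1.26,small,moderate
1+ same gender partners last 5 years,0.079,0.076,0.046,0.050,0.045,0.036,0.030,2.77,1.21,large,small
Attended STI clinic in last 5 years,0.143,0.141,0.128,0.128,0.125,0.134,0.187,0.73,0.67,moderate,moderate
Attended STI clinic in last year,0.058,0.055,0.046,0.046,0.046,0.049,0.069,0.83,0.70,small,moderate
Ever STI diagnosis,0.123,0.126,0.119,0.116,0.105,0.113,0.133,0.91,0.83,small,small
Ever taken illicit drugs,0.446,0.459,0.456,0.451,0.448,0.446,0.523,0.73,0.73,moderate,moderate
Ever taken cannabis,0.407,0.419,0.416,0.410,0.410,0.409,0.491,0.71,0.72,moderate,moderate
1+ new heterosexual partners last year,0.247,0.236,0.232,0.238,0.222,0.222,0.274,0.87,0.76,small,moderate
0 heterosexual partners lifetime,0.116,0.099,0.088,0.087,0.086,0.089,0.060,2.06,1.53,large,moderate
0 heterosexual partners last 5 years,0.143,0.124,0.107,0.107,0.106,0.109,0.077,2.00,1.47,large,moderate
0 heterosexual partners last year,0.200,0.183,0.165,0.167,0.157,0.161,0.112,1.98,1.52,large,moderate
Heterosexual sex 5+ occasions last 4 weeks,0.511,0.520,0.519,0.528,0.546,0.550,0.464,1.21,1.41,small,moderate
Ever paid for heterosexual sex,0.132,0.129,0.128,0.125,0.117,0.117,0.104,1.31,1.14,moderate,small
Had a sexual function problem in last year,0.437,0.433,0.423,0.411,0.397,0.396,0.395,1.19,1.00,small,small
Easy to talk to parent(s) about sex at age 14,0.161,0.153,0.151,0.160,0.162,0.167,0.184,0.85,0.89,small,small
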