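behaviour,prev_agesex,prev_psa1,prev_psa2,prev_psa3,prev_psa4,prev_psa5,prev_reference,or_printed_agesex,or_printed_psa5,bias_printed_agesex,bias_printed_psa5
Binge drinks once a week or more,0.098,0.099,0.095,0.098,0.090,0.092,0.118,0.81,0.76,small,moderate
Both equally willing at first sex,0.791,0.789,0.788,0.794,0.800,0.805,0.821,0.83,0.90,small,small
Contraception used at first sex,0.876,0.870,0.868,0.868,0.871,0.875,0.856,1.19,1.18,small,small
First sex at about the right time,0.566,0.554,0.554,0.563,0.567,0.577,0.644,0.72,0.75,moderate,moderate
Experience not all with opposite sex,0.245,0.233,0.223,0.218,0.207,0.192,0.159,1.72,1.26,large,moderate
Had heterosexual oral sex in last year,0.705,0.714,0.717,0.720,0.739,0.745,0.770,0.71,0.87,moderate,small
Had heterosexual anal sex in last year,0.166,0.168,0.168,0.164,0.172,0.169,0.154,1.09,1.12,small,small
Sex without condom in last 4 weeks,0.789,0.797,0.799,0.798,0.794,0.793,0.800,0.93,0.96,small,small
1+ same gender partners last 5 years,0.064,0.062,0.055,0.052,0.052,0.047,0.049,1.33,0.96,moderate,small
Attended STI clinic in last 5 years,0.184,0.179,0.178,0.179,0.177,0.174,0.203,0.89,0.83,small,small
Attended STI clinic in last year,0.060,0.057,0.056,0.056,0.058,0.056,0.085,0.69,0.64,moderate,moderate
Ever STI diagnosis,0.172,0.176,0.175,0.173,0.163,0.158,0.188,0.90,0.81,small,small
Ever taken illicit drugs,0.406,0.392,0.388,0.380,0.373,0.360,0.385,1.09,0.90,small,small
Ever taken cannabis,0.368,0.353,0.351,0.344,0.339,0.327,0.355,1.06,0.88,small,small
1+ new heterosexual partners last year,0.174,0.168,0.169,0.170,0.166,0.167,0.218,0.76,0.72,moderate,moderate
0 heterosexual partners lifetime,0.059,0.058,0.055,0.057,0.053,0.054,0.045,1.33,1.21,moderate,small
0 heterosexual partners last 5 years,0.099,0.094,0.090,0.090,0.084,0.082,0.064,1.61,1.31,moderate,moderate
0 heterosexual partners last year,0.177,0.168,0.163,0.161,0.148,0.144,0.107,1.79,1.40,large,moderate
Heterosexual sex 5+ occasions last 4 weeks,0.527,0.526,0.524,0.523,0.540,0.542,0.452,1.35,1.43,moderate,moderate
Ever paid for heterosexual sex,0.147,0.155,0.157,0.152,0.150,0.146,0.148,0.99,0.98,small,small
Had a sexual function problem in last year,0.506,0.496,0.492,0.485,0.460,0.449,0.483,1.10,0.87,small,small
Easy to talk to parent(s) about sex at age 14,0.149,0.148,0.145,0.146,0.154,0.154,0.252,0.52,0.54,large,large
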