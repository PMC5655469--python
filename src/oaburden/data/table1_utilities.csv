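age_band,level,value,value_set
40–44,none,0.959,vas
40–44,moderate,0.652,vas
40–44,severe,0.314,vas
45–49,none,0.959,vas
45–49,moderate,0.642,vas
45–49,severe,0.285,vas
50–54,none,0.951,vas
50–54,moderate,0.646,vas
50–54,severe,0.239,vas
55–59,none,0.946,vas
55–59,moderate,0.649,vas
55–59,severe,0.122,vas
60–64,none,0.968,vas
60–64,moderate,0.643,vas
60–64,severe,0.160,vas
65–69,none,0.947,vas
65–69,moderate,0.627,vas
65–69,severe,0.280,vas
70–74,none,0.974,vas
70–74,moderate,0.623,vas
70–74,severe,0.239,vas
75–79,none,0.950,vas
75–79,moderate,0.635,vas
75–79,severe,0.165,vas
80–84,none,0.916,vas
80–84,moderate,0.609,vas
80–84,severe,0.107,vas
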