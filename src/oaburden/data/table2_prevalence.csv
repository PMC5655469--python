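ethnicity,sex,age_band,prevalence
non_maori,male,40–44,0.0119
non_maori,male,45–49,0.0482
non_maori,male,50–54,0.0479
non_maori,male,55–59,0.0627
non_maori,male,60–64,0.0630
non_maori,male,65–69,0.1140
non_maori,male,70–74,0.1144
non_maori,male,75–79,0.1275
non_maori,male,80–84,0.1285
non_maori,female,40–44,0.0080
non_maori,female,45–49,0.0447
non_maori,female,50–54,0.0447
non_maori,female,55–59,0.1045
non_maori,female,60–64,0.1041
non_maori,female,65–69,0.1698
non_maori,female,70–74,0.1692
non_maori,female,75–79,0.2155
non_maori,female,80–84,0.2150
maori,male,40–44,0.0086
maori,male,45–49,0.0288
maori,male,50–54,0.0288
maori,male,55–59,0.0972
maori,male,60–64,0.0972
maori,male,65–69,0.1443
maori,male,70–74,0.1443
maori,male,75–79,0.2084
maori,male,80–84,0.2084
maori,female,40–44,0.0129
maori,female,45–49,0.0483
maori,female,50–54,0.0483
maori,female,55–59,0.0698
maori,female,60–64,0.0698
maori,female,65–69,0.1310
maori,female,70–74,0.1310
maori,female,75–79,0.1834
maori,female,80–84,0.1834
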