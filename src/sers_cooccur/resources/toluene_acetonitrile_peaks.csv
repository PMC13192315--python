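shift_cm1,species
521.7,toluene
786.5,toluene
918.6,acetonitrile
1003.6,toluene
1030.6,toluene
1211.4,toluene
1376.4,acetonitrile
1605.1,toluene
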