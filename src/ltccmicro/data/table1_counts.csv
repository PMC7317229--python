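group,microdomain,n_seals,n_active,total_area_um2,total_channels,printed_occurrence_pct,printed_mean_channels,printed_density
Control,TT,31,8,3.30,13,25.8,1.63,3.94
Control,Crest,29,3,5.14,11,10.3,3.66,2.14
ICM,TT,35,7,4.92,9,20,1.29,1.83
ICM,Crest,20,5,3.34,9,25,1.8,2.7
ICM+LVAD,TT,32,8,3.75,12,25,1.5,3.20
ICM+LVAD,Crest,24,8,3.83,11,33.3,1.37,2.87
DCM,TT,31,7,2.93,10,22.6,1.43,3.42
DCM,Crest,40,11,6.39,15,27.5,1.36,2.35
DCM+LVAD,TT,31,6,3.21,9,19.3,1.5,2.8
DCM+LVAD,Crest,31,9,6.75,13,29,1.44,1.93
BayK,TT,13,4,1.58,16,30.7,4,10.11
BayK,Crest,16,3,2.58,13,18.8,4.3,5.05
Myo+LVAD,TT,14,3,2.44,4,21.4,1,1.64
Myo+LVAD,Crest,13,3,1.36,3,23.1,1.33,2.21
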