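quantity,group,microdomain,value,sem,n,units
po,Control,TT,0.057,0.0065,13,
po,ICM,TT,0.102,0.0046,9,
po,ICM+LVAD,TT,0.062,0.082,15,
po,DCM,Crest,0.113,0.0161,13,
po,DCM+LVAD,Crest,0.03,0.079,13,
po,DCM+KN93,Crest,0.025,0.0031,13,
po,DCM+H89,Crest,0.112,0.0045,10,
po,ICM+KN93,TT,0.101,0.025,5,
po,ICM+H89,TT,0.047,0.0057,6,
conductance,Control,TT,13.74,1.13,,pS
conductance,Control,Crest,16.05,1.08,,pS
conductance,BayK,TT,24.94,0.4,,pS
conductance,BayK,Crest,23.72,0.95,,pS
tt_density_decrease_pct,ICM,,36.3,,,percent
tt_density_decrease_pct,DCM,,31.3,,,percent
tt_regularity_decrease_pct,ICM,,68.6,,,percent
tt_regularity_decrease_pct,DCM,,61.77,,,percent
zgroove_reduction_pct_range_low,all_failing,,27,,,percent
zgroove_reduction_pct_range_high,all_failing,,41,,,percent
tt_openings,Control,,6.5,0.3,96,count
tt_openings,ICM,,5.3,0.3,68,count
tt_openings,ICM+LVAD,,4,0.2,70,count
tt_openings,DCM,,4,0.2,116,count
tt_openings,DCM+LVAD,,4.4,0.2,80,count
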