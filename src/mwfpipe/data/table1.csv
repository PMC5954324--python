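subject_id,age,sex,edss,tug_day1_s,tug_day10_s,lesion_volume_mm3,lesion_mwf,nawm_mwf,mwf_ratio
01,51,F,6.0,21.0,14.0,1024,,,
02,39,F,2.5,13.5,10.0,5803,,,
03,34,M,4.5,13.0,13.5,9741,,,
04,54,F,1.0,10.0,8.5,4833,,,
05,66,F,4.0,14.5,13.0,13291,,,
06,48,F,4.5,13.0,9.5,7231,,,
07,68,F,3.5,10.0,10.0,7315,,,
08,44,F,4.5,14.0,11.5,3791,,,
09,22,F,0.0,7.0,7.0,2699,,,
10,56,F,6.5,18.0,25.0,6391,,,
11,53,F,1.0,13.5,10.0,11941,,,
12,53,F,4.0,8.0,7.0,11904,,,
13,34,F,5.5,17.5,17.5,6140,,,
14,47,F,3.5,10.5,11.5,8442,,,
15,51,F,4.5,12.0,11.0,9406,,,
16,33,F,4.0,8.5,,6478,,,
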