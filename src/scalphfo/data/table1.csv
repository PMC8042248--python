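patient_id,age_years,sex,classification,aetiology,csws,seizures_per_month,n_intervals,n_events,rate_per_min,frequency_hz,duration_ms,amplitude_uv,snr,rba_uv,top_channel,reliability_10min_pct
1,5.6,F,focal,structural,1,150,6,397,13.2,126,36,7.7,9.4,1.3,P3-O1,100
2,1.6,F,generalized,genetic,0,60,4,137,6.8,97,55,10.5,6.7,1.6,T6-P4,100
3,4.8,M,focal,structural,1,0.01,17,545,6.4,122,37,10.3,8.1,1.9,T6-P4,100
4,12.4,F,generalized,genetic,1,0.01,3,86,5.7,85,49,15.0,10.0,1.5,T5-P3,
5,6.6,M,focal,structural,1,0.01,3,69,4.6,121,40,10.0,12.3,1.5,T3-F3,
6,3.8,F,focal,structural,0,15,5,104,4.2,121,55,10.0,9.1,1.6,F8-F4,100
7,4.9,M,focal,structural,0,4410,9,153,3.4,118,48,7.6,9.4,1.2,P3-O1,100
8,5.7,F,generalized,genetic,0,18000,5,77,3.1,109,54,11.9,14.8,1.3,T6-O2,100
9,2.2,M,focal,structural,0,0.01,9,122,2.7,115,52,6.6,7.1,1.1,T5-C3,100
10,11.5,M,focal,structural,0,2,17,213,2.5,106,45,9.6,14.9,1.5,F3-C3,100
11,4.7,F,focal,structural,0,240,11,114,2.1,113,53,8.3,9.8,1.2,Pz-O2,60
12,4.1,M,focal,structural,0,780,8,58,1.4,110,37,9.3,8.4,1.5,F8-F4,100
13,0.7,M,generalized,unknown,0,0.01,2,10,1.0,174,24,8.3,4.4,2.2,F7-T3,
14,7.1,F,generalized,genetic,0,60,3,15,1.0,107,35,9.5,8.2,1.7,F3-Cz,100
15,12.1,M,focal,structural,0,90,3,12,0.8,87,51,7.9,7.0,1.2,P4-Cz,
16,15.8,F,generalized,unknown,0,300,4,15,0.7,119,51,7.9,6.0,1.5,P4-Cz,0
17,11.6,F,generalized,unknown,0,1.5,9,32,0.7,97,43,15.3,13.6,1.3,F8-T4,100
18,7.8,F,focal,structural,0,90,10,34,0.7,120,85,13.5,8.6,1.1,Fp1-F3,100
19,1.5,F,focal,structural,0,360,4,13,0.6,129,46,16.0,11.7,1.6,F7-T3,100
20,17.4,M,focal,structural,0,0.3,5,15,0.6,106,45,13.4,14.1,1.0,Fp1-Fp2,100
21,0.8,F,generalized,genetic,0,180,12,32,0.5,114,43,14.1,9.3,1.8,Fp1-Fp2,87
22,7.7,F,focal,unknown,0,270,5,13,0.5,109,43,15.9,12.4,1.3,Fp1-F3,100
23,15.3,F,focal,unknown,0,210,4,10,0.5,92,42,11.9,18.4,1.0,F7-T3,100
24,4.8,M,focal,structural,0,0.01,13,31,0.5,137,30,6.6,6.2,1.2,P3-Pz,43
25,6.1,M,focal,structural,0,300,12,24,0.4,96,37,17.0,19.9,1.1,F3-C3,27
26,2.0,F,focal,structural,0,60,7,12,0.3,116,38,13.9,14.0,1.5,T3-F3,83
27,8.9,M,focal,structural,0,750,3,4,0.3,79,37,9.5,12.1,1.1,T5-O1,0
28,7.6,M,focal,structural,0,150,7,9,0.3,115,70,17.4,8.2,1.8,Fp2-F8,50
29,15.8,M,focal,structural,0,0.17,7,9,0.3,93,39,13.8,17.2,1.3,Fp1-F3,17
30,15.7,F,generalized,unknown,0,4,4,2,0.1,149,30,21.0,4.3,2.0,Fp1-F3,0
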