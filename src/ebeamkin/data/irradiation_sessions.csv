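session_id,time_s,current_nA,charge_nC,dose_Gy
1-3,32.3,,5375,103.4
4-6,122.3,,52356.7,1007
7-9,73.7,,157733.3,3033.3
10-12,150,,365666.7,7032.1
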