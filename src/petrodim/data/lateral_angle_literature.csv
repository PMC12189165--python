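population,period,method,n,female_mean_deg,female_sd_deg,male_mean_deg,male_sd_deg,accuracy_pct
Germany,archaeological (last 1200 years),cast,70,68,10,54,9,
Germany,modern,cast,269,57,12,46,11,67.4
Germany and Sweden (combined),modern and archaeological (late Viking age to early medieval),cast,133,48,7,39,6,82.8
Turkey,modern,CT,92,46,7,42,7,
Egypt,modern,CT,120,50,6,42,6,80.8
Italy,modern (cremated),cast,160,35,9,32,6,58.1
Denmark,modern,CT,77,47,7,43,8,62.3
Portugal,modern (cremated),cast,54,50,13,50,17,
Greece,modern,CT,102,42,5,41,5,53.4
Italy,modern,CT,100,44,10,40,9,
Brazil,modern,CT,150,46,8,40,9,62.7
Poland,Bronze Age to Iron Age (cremated),CT,6,49,1,33,6,
Austria,Late Bronze Age,CT,25,38,5,28,2,80.0
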