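zone,travel_time,n_villages,settlement_area_km2,population
green,<=30 minutes,78,18.68,104477
yellow,30-50 minutes,111,25.23,123110
red,50+ minutes,131,38.02,195112
excluded,excluded from intervention and analysis,18,3.06,19545
total,printed grand total,338,84.99,442550
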