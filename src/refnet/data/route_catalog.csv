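route_id,route_name,mode,distance_km,time_min,catchment_population,active,effective_speed_kmh,single_mode_consistent
01,Shetu Bazar to Bhuapur UHC,Tempo,12.04,57.14,27214,1,12.64,1
02,Gobindasi to Bhuapur UHC,Tempo,5.64,26.77,27829,1,12.64,1
03,Nikrail Bazar to Bhuapur UHC via Shinguria,Tempo,11.92,56.59,14497,1,12.64,1
04,"Falda to Bhuapur UHC via Dighulia, Jhanjania",CNG,8.12,38.56,17070,1,12.64,1
05,"Falda to Gopalpur UHC via Alamnagar, Daulatpur, Suti Bazar",CNG,7.73,36.67,6236,1,12.64,1
06,Sanak Boyra Bazar to Bhuapur UHC via Dobalia Bazar,CNG,10.10,47.94,16791,1,12.64,1
07,Nalin Bazar to Bhuapur UHC,CNG,16.13,47.43,33387,1,20.40,1
08,"Nalin Bazar to Gopalpur UHC via Banglabazar, Hemnagar",Tempo,15.08,71.60,13520,1,12.64,1
09,Belua Bazar to Gopalpur UHC via Nabagram,Nasiman,8.34,39.61,7547,0,12.63,1
10,Jhawail to Gopalpur UHC via Nabagram,Tempo,10.69,50.73,34051,1,12.64,1
11,"Bhengula to Gopalpur UHC via Chatutia Bazar Mod, Nagda Simla",Tempo,14.52,68.94,37771,1,12.64,1
12,Konabari Bazar to Gopalpur UHC via Saydpur,Tempo,7.54,35.78,9318,1,12.64,1
13,"Konabari Bazar to Gopalpur UHC via Bhutia Bazar, Sajanpur Bazar, Madhupur upazila sadar",Tempo,6.26,29.70,17983,1,12.64,1
14,"Konabari Bazar to Gopalpur UHC via Pichuria, Dhopakandi, Dhanbari upazila sadar",Tempo,6.05,28.74,6208,1,12.64,1
15,"Konabari Bazar to Gopalpur UHC via Bara Shila, Suti Para, Mirzapur",Tempo,9.09,35.21,21754,1,,0
16,Ruli Para Trawler Ghat to Bhuapur UHC via Gobindasi Ghat,Boat and Tempo,17.35,80.38,7120,1,,0
17,Pungle Para to Bhuapur UHC via Gobindasi Ghat,Boat and Tempo,18.01,85.31,8130,1,,0
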