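id,sex,total_length_m,day_rom_m_per_h,night_rom_m_per_h,total_distance_km,kud95_km2,kud50_km2,max_dist_centroid_km,strategy
M1,male,3.2,301,352,824,34.2,6.6,73.2,nomadic
M2,male,3.7,153,428,1054,42.1,6.4,69.2,nomadic
M3,male,3.9,245,373,1269,72.5,4.7,165.4,nomadic
M4,male,4.3,290,589,1179,9.0,4.2,19.2,site_fidelic
M5,male,3.9,67,118,173,7.3,3.5,12.2,site_fidelic
M6,male,3.7,84,248,197,8.7,3.6,27.9,site_fidelic
M7,male,4.1,166,447,964,11.2,5.1,9.6,site_fidelic
M8,male,4.5,200,270,324,7.1,4.2,8.07,site_fidelic
F1,female,3.0,123,56,258,12.8,3.9,54.3,
F2,female,2.9,17,39,127,7.2,2.2,54.8,
F3,female,3.2,34,92,165,4.9,0.8,33.1,
F4,female,2.6,27,23,154,1.1,0.5,22.5,
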