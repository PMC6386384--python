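area_name,urban_rural_class,clinic_positivity,online_positivity
SE London,Urban,0.075,0.041
Area A,Mixed - urban with cities and towns and significant rural areas,0.079,0.058
Area B,Urban with cities,0.073,0.072
Area C,Rural with hub towns,0.055,0.055
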