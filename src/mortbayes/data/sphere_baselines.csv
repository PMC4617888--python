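region,cdr_baseline,cdr_threshold,u5dr_baseline,u5dr_threshold
sub_saharan_africa,0.41,0.8,1.07,2.1
middle_east_north_africa,0.16,0.3,0.27,0.5
south_asia,0.22,0.4,0.46,0.9
east_asia_pacific,0.19,0.4,0.15,0.3
latin_america_caribbean,0.16,0.3,0.15,0.3
cee_cis_baltic,0.33,0.7,0.14,0.3
industrialized_countries,0.25,0.5,0.03,0.1
developing_countries,0.22,0.4,0.44,0.9
least_developed_countries,0.33,0.7,0.82,1.7
world,0.25,0.5,0.4,0.8
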