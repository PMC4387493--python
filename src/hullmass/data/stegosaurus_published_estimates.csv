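method,kind,mean,lower,upper
cvol_min,volumetric,1311,916,1884
cvol_pref,volumetric,1560,1082,2256
cvol_max,volumetric,1894,1303,2760
cvol_ce,volumetric,3745,,
CE2012_b,limb,3752,2790,4713
CE2012_m,limb,3329,2499,4159
An1985,limb,3632,2089,6316
M2004,limb,2355,971,5717
DME_YPM1853,dme,1823,1356,2290
DME_YPM1856,dme,2158,1605,2712
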