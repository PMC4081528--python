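segment,label,w_RM_um,w_OC_um,l_um
0,hook,,,800.0
1,I,499.6574,356.2481,3800.0
2,II,535.3472,395.8312,3200.0
3,III,571.0371,455.2059,2700.0
4,IV,618.6235,514.5806,2300.0
5,V,666.2099,593.7468,1900.0
6,VI,713.7963,672.9131,1600.0
7,VII,761.3827,752.0793,1300.0
8,VIII,808.9692,831.2456,900.0
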