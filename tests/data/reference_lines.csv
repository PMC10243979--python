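element,transition,energy_keV
Cl,KL3,2.6224
K,KL3,3.3138
Ca,KL3,3.6917
Ti,KL3,4.5108
V,KL3,4.9522
Cr,KL3,5.4147
Mn,KL3,5.8988
Fe,KL3,6.4038
Co,KL3,6.9303
Ni,KL3,7.4782
Cu,KL3,8.0478
Zn,KL3,8.6389
Ti,KM3,4.9318
Cr,KM3,5.9467
Fe,KM3,7.0580
Zn,KM3,9.5720
La,L3M5,4.6510
Ce,L3M5,4.8402
Pr,L3M5,5.0337
Nd,L3M5,5.2304
Sm,L3M5,5.6361
Eu,L3M5,5.8457
Gd,L3M5,6.0572
Tb,L3M5,6.2728
Dy,L3M5,6.4952
Ho,L3M5,6.7198
Er,L3M5,6.9487
Tm,L3M5,7.1799
Yb,L3M5,7.4156
Lu,L3M5,7.6555
Sm,L2M4,6.2051
Eu,L2M4,6.4564
Gd,L2M4,6.7126
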